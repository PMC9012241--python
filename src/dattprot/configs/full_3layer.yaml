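# Full-scale configuration, 3-layer variant (higher pre-training peak rate).
model:
  l: 512
  f: 512
  emb_dim: 16
  n_layers: 3
  h: 8
  dropout: 0.1
  kernel_sizes: [5, 10, 20]
  channel_mult: 16
pretrain:
  mask_fraction: 0.15
  batch_size: 32
  max_epochs: 300
  warmup_steps: 50000
  peak_lr: 0.0001
  weight_decay: 0.0001
finetune:
  batch_size: 128
  max_epochs: 100
  initial_lr: 0.00001
  decay_factor: 0.95
  decay_every: 100
  weight_decay: 0.0001
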