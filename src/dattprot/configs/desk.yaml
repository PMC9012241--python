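# Desk-scale configuration: small enough to pre-train and fine-tune on a
# single CPU in minutes while exercising every mechanism of the architecture.
model:
  l: 128
  f: 64
  emb_dim: null        # embed directly at f, no projection
  n_layers: 2
  h: 2
  dropout: 0.1
  kernel_sizes: [5, 10, 20]
  channel_mult: 16
pretrain:
  mask_fraction: 0.15
  batch_size: 32
  max_epochs: 3
  warmup_steps: 100
  peak_lr: 0.001
  weight_decay: 0.0001
finetune:
  batch_size: 32
  max_epochs: 8
  initial_lr: 0.001
  decay_factor: 0.95
  decay_every: 100
  weight_decay: 0.0001
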