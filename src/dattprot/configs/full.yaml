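# Full-scale configuration (6-layer variant).
# Matches the published training setup: 512-token windows, 8-headed encoders
# with 512-dimensional hidden states over a 16-dimensional initial embedding,
# kernel scales {5, 10, 20} with 16x-kernel conv channels, AdamW with 1e-4
# weight decay, 50k-step warm-up to a 5e-5 peak (1e-4 for the 3-layer
# variant), fine-tuning from 1e-5 with x0.95 decay per 100 iterations.
model:
  l: 512
  f: 512
  emb_dim: 16
  n_layers: 6
  h: 8
  dropout: 0.1
  kernel_sizes: [5, 10, 20]
  channel_mult: 16
pretrain:
  mask_fraction: 0.15
  batch_size: 32
  max_epochs: 300
  warmup_steps: 50000
  peak_lr: 0.00005
  weight_decay: 0.0001
finetune:
  batch_size: 128
  max_epochs: 100     # 50 for sub-subclass (level-2) tasks
  initial_lr: 0.00001
  decay_factor: 0.95
  decay_every: 100
  weight_decay: 0.0001
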