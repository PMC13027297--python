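# Desk-scale training configuration for the tiny profile.
train:
  epochs: 30        # cosine anneal 1e-3 -> 1e-6 over this budget
  batch_size: 16
  label_smoothing: 0.1
  patience: 10
  augment: true     # dihedral symmetry + translation + brightness jitter
model:
  profile: tiny
  use_gcsa: true
  hybrid: true
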