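# Canonical configuration for `sdamll train` / `sdamll cv`.
# All fields are optional; omitted values take the documented defaults.
seed: 0                 # root seed; split into named streams per stage

sdamll:
  layer_sizes: null     # null -> [d, 200] when d > 200, else [d, ceil(d/2)];
                        # [d] disables the stack (plain BP-MLL on raw features)
  dae:
    epochs: 5
    learning_rate: 0.1
    loss_kind: cross_entropy   # or squared_error
    v: 0.25                    # fraction of inputs zeroed per instance
  bpmll:
    alpha: 0.05         # learning rate, must lie in (0, 1)
    max_epochs: 30
    patience: 3         # epochs of non-decreasing global error before stopping
    M: 20               # hidden units

knn:
  k: 10

dt:
  depth: null           # null = grow to purity with min leaf size 2
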