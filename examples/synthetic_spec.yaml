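# Canonical generator spec for `sdamll simulate`.
n_instances: 500
n_labels: 8
n_terms: 2000
signature_terms_per_label: 25
labels_per_instance: {1: 0.3333333333, 2: 0.3333333333, 3: 0.3333333334}
signal_strength: 5.0
background_rate: 0.05
signature_overlap: 0.0
seed: 0
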