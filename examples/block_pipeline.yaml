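# Simulate one experiment-like block, apply inclusion criteria, fit the
# SR and modulated-SR models, select the latent dimensionality, and
# compute unit statistics:  modlabel run examples/block_pipeline.yaml --out runs/block
experiment: block-pipeline
seed: 7
n_units: 30
n_trials: 60
D_range: [0, 1, 2]
folds: 5
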