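# Decoding accuracy of the optimal / modulator-guided / sign-only decoders
# as a function of relative modulator strength.
experiment: strength-sweep
seed: 3
n_informative: 10
n_uninformative: 190
n_seeds: 10
n_train: 2000
n_test: 1000
strength_grid: [0.0, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0]
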