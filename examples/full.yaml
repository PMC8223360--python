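# Full protocol settings (identical to the built-in defaults; listed for reference).
identity_threshold: 0.8
n_subsets: 6
k_min: 1
k_max: 6
feature_mode: frequency
cv_folds: 5
repeats: 3
n_lambda: 100
tuning_fraction: 0.5
ntree: 500
n_members: 5
threshold: 0.5
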