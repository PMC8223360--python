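# Reduced-scale settings for quick demonstration runs.
# The library defaults (RunConfig) are the full protocol: k 1..6,
# alpha tuned over 0.1..1.0, 100-point lambda grid, ntree 500.
k_max: 4
alpha: 0.5
n_lambda: 15
cv_folds: 3
ntree: 100
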