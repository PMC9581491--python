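# Population of G functions with randomized coefficients: one record per
# simulated model with its (k_t, k_s), order-wise index sums and CV.
# NOTE: the k range is an assumption of this example, not a fixed convention;
# pick the range that brackets your models' dimensionalities.
experiment: g-random
seed: 42
n_sims: 200
N: 1024
k_range: [3, 4, 5, 6, 7, 8, 9, 10]
output_dir: effdim-g-random
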