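# Random-metafunction sweep at fixed dimensionality: how the output CV grows
# as interactions up to order n are activated.
experiment: metamodel
seed: 42
mode: fixed-k-vary-n
k_fixed: 15
n_grid: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
reps: 30
N: 512
output_dir: effdim-metamodel
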