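# Per-compartment, per-time effective-dimension audit of the SIR(S) template
# with waning immunity (synthetic parameter marginals).
experiment: audit-sirs
seed: 42
variant: SIR(S)
N: 64
output_dir: effdim-sirs-audit
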