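# Continuous strong-excitation transient with the canonical three phases;
# analyze with `photocyt analyze-phases --input continuous_rvx.csv`.
command: make-synthetic
kind: continuous
label: continuous_rvx
preset: rvx_wt
seed: 1
k_L: 1.5e4
duration_s: 2.0e-2
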