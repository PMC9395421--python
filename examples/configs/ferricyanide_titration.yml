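# Slow chemical oxidation of the donor pool: one flash experiment per
# incubation time.  Recover K_D(t_inc) with
# `photocyt titrate --input titration.manifest.json --clip-tol 0.02`.
command: make-synthetic
kind: titration
label: titration
preset: rvx_wt
seed: 1
incubation_times_s: [0.0, 900.0, 1800.0, 3600.0, 5400.0, 7200.0]
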