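# Interquinone block: mechanistic trajectory saturating at 1 cyt3+/RC.
command: simulate
kind: continuous
label: terbutryne
preset: rvx_wt
treatment: terbutryne
k_L: 1.5e4
duration_s: 2.0e-2
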