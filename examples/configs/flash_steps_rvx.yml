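# Three-flash staircase of a wild-type Rvx culture: generate the synthetic
# trace, then run `photocyt analyze-steps --input flash_rvx.csv` on it.
command: make-synthetic
kind: flash
label: flash_rvx
preset: rvx_wt
treatment: none
seed: 1
sigma_delta_a: 1.0e-4
n_averages: 32
n_flashes: 3
flash_spacing_s: 4.0e-4
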