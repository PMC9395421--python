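# photocyt

Kinetic analysis of light-induced cytochrome oxidation in intact
photosynthetic bacteria.

In purple non-sulfur bacteria (e.g. *Rhodobacter sphaeroides*,
*Rubrivivax gelatinosus*) a photon closes the reaction center (RC) by charge
separation, P Q_A → P⁺ Q_A⁻; the RC re-opens only after the electron moves
to the secondary quinone Q_B *and* a periplasmic cytochrome re-reduces P⁺.
Difference-absorbance spectroscopy on whole cells (551−540 nm for
cytochromes, 790−750 nm for P/P⁺) turns this into measurable staircases:
each saturating flash oxidizes up to one cytochrome per RC, and the steps
Δ1 ≥ Δ2 ≥ Δ3 shrink as reduced donors become scarce.  `photocyt` is for
biophysicists who want to reduce such transients to the quantities that
characterize the donor side of intact cells — something classical
isolated-RC "cytochrome assays" cannot provide.

The package contains:

* **`kinetic_core`** — a mean-field ODE over the full 48-state cross product
  (P/P⁺ × Q_A⁰/Q_A⁻ × {Q_B, Q_B⁻, Q_BH₂, empty} × docking site
  {vacant, cyt²⁺, cyt³⁺}), with instantaneous saturating-flash operators,
  continuous excitation at rate k_L, quinol exchange, a finite donor pool
  re-supplied by the bc₁ complex, and inhibitor flags (terbutryne,
  myxothiazol, dithionite, ferrocene).  The closed-form re-opening law

      [PQ_A](t) = (1 − e^{−k_A t})(1 − e^{−k_D t})

  is provided and verified against the ODE.
* **`damping`** — the step model and its inversion.  With donor-side
  constants K_Di and acceptor-side constants K_Ai,

      Δ1 = K_D1/(1+K_D1)
      Δ2 = [K_A1/(1+K_A1)] · Δ1 · K_D2/(1+K_D2)
      Δ3 = [K_A1/(1+K_A1)][K_A2/(1+K_A2)] · Δ1 · [K_D2/(1+K_D2)][K_D3/(1+K_D3)]

  and, since K_A ≫ 1 in vivo, K_D1 = Δ1/(1−Δ1), K_D2 = r₂/(1−r₂),
  K_D3 = r₃/(1−r₃) with r₂ = Δ2/Δ1, r₃ = Δ3/Δ2 (an exact finite-K_A
  variant is available).  Varying the interflash delay T gives
  ratio(T) = R_∞(1−e^{−k_A T})(1−e^{−k_D T}), whose fit separates the
  interquinone transfer rate from the donor side.
* **`traces`** — Beer–Lambert conversion with the published Δε values
  (21.1 mM⁻¹cm⁻¹ for cytochrome at 551−540 nm, 70 for P/P⁺, 12.2 for TMPD),
  plateau-window step extraction, three-segment piecewise-linear fitting of
  continuous-illumination kinetics, sweep averaging and per-RC
  normalization against the cytochrome-less *cycA* calibration signal.
* **`synthetic`** — a spectrometer stand-in: strain presets whose donor
  parameters are back-solved so the standard three-flash protocol
  reproduces published damping constants (K_D2 = 49, K_D3 = 3.7 for
  *Rvx.* wild type; 3.5, 1.4 for *Rba.* wild type; 0.75, 0.3 for the PufC
  mutant), seeded Gaussian noise with 32-sweep averaging, ferricyanide
  titrations and continuous-light experiments, all with ground-truth
  sidecars.
* **`pipeline` / CLI** — declarative config-driven runs
  (`photocyt run config.yml`, or subcommands `make-synthetic`, `simulate`,
  `analyze-steps`, `analyze-phases`, `fit-damping`, `titrate`) writing JSON
  results with full provenance.

## Worked example

```python
from photocyt import (NoiseModel, absorbance_to_concentration, extract_steps,
                      generate_flash_experiment, invert_steps, strain_preset)

preset = strain_preset("rvx_wt")
trace, truth = generate_flash_experiment(preset, noise=NoiseModel(seed=7))
conc  = absorbance_to_concentration(trace)   # dA -> oxidized cyt per RC
steps = extract_steps(conc, trace.protocol)  # plateau differences per flash
kd    = invert_steps(steps, clip_tol=0.01)   # damping -> K_D
```

Running this (it is `examples/02_flash_steps_and_kd.py`) prints

```
steps (cyt3+/RC): D1 = 0.9992, D2 = 0.9802, D3 = 0.7712
recovered:  K_D2 =  51.65   K_D3 =  3.69
truth:      K_D2 =  49.00   K_D3 =  3.70
```

The first flash oxidizes essentially one cytochrome per RC; the second step
is barely damped (K_D2 ≈ 50: reduced donors still abundant), while the
third is visibly smaller (K_D3 ≈ 3.7: the proximal pool is running low).
The recovered constants differ from the generator's truth only through the
simulated instrument noise.  The other scripts in `examples/` walk through
the re-opening law, delay-dependence fitting of the interquinone rates,
the three-phase continuous transient, the ferricyanide titration and P⁺ /
external-donor experiments; `examples/configs/` holds the equivalent
declarative configs for the CLI.

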