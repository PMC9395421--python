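# Methods

## The chain model of reaction-center turnover

The reaction center (RC) is described by the cross product of four discrete
coordinates — special pair (P, P⁺), primary quinone electron count (0, 1),
Q_B site (Q_B, Q_B⁻, Q_BH₂, empty) and cytochrome docking site (vacant,
cyt²⁺-bound, cyt³⁺-bound) — 48 states in total, none excluded.  Mean-field
occupancies evolve under first-order transitions:

| process | transition | rate (default) |
|---|---|---|
| photochemistry | P,Q_A⁰ → P⁺,Q_A⁻ | k_L (protocol) |
| 1st interquinone transfer | Q_A⁻Q_B → Q_A Q_B⁻ | k_AB1 (10⁴ s⁻¹) |
| 2nd interquinone transfer | Q_A⁻Q_B⁻ → Q_A Q_BH₂ | k_AB2 (6·10³ s⁻¹) |
| quinol release / quinone rebinding | Q_BH₂ → empty → Q_B | k_Qex ((1 ms)⁻¹ each) |
| donor electron transfer | P⁺·cyt²⁺ ⇌ P·cyt³⁺ | k_ET (10⁶ s⁻¹) forward; back rate k_ET/K_e(link) |
| donor exchange | bound ⇌ pool | k_unbind (10⁵ s⁻¹), k_bind·(pool fraction) (k_bind = 10⁶ s⁻¹) |
| pool re-reduction (bc₁) | pool holes → reduced | k_bc1 ((10 ms)⁻¹; (100 ms)⁻¹ under myxothiazol) |
| external donor (ferrocene) | P⁺ → P | k_ext (5·10³ s⁻¹ at 0.5 mM) |

Three bookkeeping scalars ride along: total oxidized cytochrome per RC (the
observable), exported quinol electrons, and external-donor electrons.
Electron conservation — oxidized cytochrome + external electrons + P⁺
equals acceptor-side electrons plus exported electrons — holds identically
whenever bc₁ resupply is inactive and is asserted in the tests.

A saturating flash is an instantaneous projection: all occupancy in open
states (P reduced, Q_A oxidized) moves to the corresponding P⁺Q_A⁻ state.
The 3 µs flash width is far below the 50 µs sampling, so no finite pulse is
modelled.  Inhibitors: terbutryne zeroes both interquinone rates;
myxothiazol divides k_bc1 by ten; dithionite pre-reduces Q_A, which closes
the RC to photochemistry altogether.

**bc₁ substrate coupling.**  The bc₁ complex re-reduces the cytochrome pool
from quinol, so its flux is k_bc1 · (pool holes) · E/(E + K_m), where E is
the exported-electron count and K_m = 10 electrons/RC represents dilution
of the released quinol into the membrane quinone pool (tens of quinones per
RC).  Consequences: with terbutryne no quinol is ever exported and the
single oxidized cytochrome is *not* re-reduced (the observed stable
1 cyt³⁺/RC plateau); during a 1.2 ms flash train the resupply is marginal
(re-reduction is a ~10 ms process); under sustained illumination it closes
the cycle.

**Donor-side generalized equilibrium.**  The paper-level quantity K_D
lumps docking-site exchange and electron transfer into one per-flash
availability.  Microscopically we make the bound-donor electron transfer
reversible with a per-link constant K_e(i).  Fast exchange against a pool
of reduced fraction r then gives a true coupled equilibrium with effective

    K_D(i) = K_e(i) · r/(1 − r),

which is why the post-flash plateaus are stable rather than draining to
complete oxidation.  The active link follows the number of *productive*
flashes (a flash that excites essentially no RC — e.g. under terbutryne —
does not advance the chain); under continuous light the link constant is
log-interpolated against cumulative turnover at anchors 0.5, 1.5, 2.5
turnovers.  Before the first flash the dark-adapted state is treated as
equilibrated (no back-reaction), so chemically pre-oxidized samples do not
drift in the dark.  With all links set to None (the default RateSet) the
transfer is irreversible and the classical saturation limits are exact:
1 cyt³⁺/RC under an interquinone block, 3 cyt³⁺/RC for a three-flash train
without quinol exchange — these hold for any positive rate values and are
tested as equalities.

**Numerics.**  LSODA with an analytic Jacobian (including the nonlinear
pool-coupling terms), rtol 10⁻¹⁰ / atol 10⁻¹³, sampled on the protocol
grid (50 µs default).  Samples falling exactly on a flash time carry the
pre-flash left limit.  Occupancy conservation is ~10⁻¹² over the horizons
used.  Non-finite solutions raise an integration error naming the rate
regime.

## Damping algebra

`forward_steps` evaluates the bracketed products for Δ1..Δ3 from
(K_D1..3, K_A1..2); `invert_steps` applies Δ1/(1−Δ1) and the ratio forms,
exactly inverse at K_A = ∞ (property-tested over K ∈ [10⁻³, 10³]³ and
asserted to machine precision in the acceptance suite).  Supplying finite
acceptor constants divides each ratio by K_Ai/(1+K_Ai) first, making the
inversion exact and quantifying how much the usual K_A ≫ 1 shortcut
underestimates K_D.  Step ratios ≥ 1 mean the constant is unidentifiable
and raise by default; an explicit `clip_tol` maps small noise overshoots to
just below 1 instead (silent clipping would hide unidentifiable data).

`fit_damping_curve` fits R_∞(1−e^{−k₁T})(1−e^{−k₂T}) by least squares
(lmfit), unweighted unless per-point σ are given (no instrument error model
is assumed).  The free asymptote R_∞ is required because measured ratios
saturate below 1.  The law is symmetric in the rates, so the fit returns
{slow, fast}; identifying the slow rate with the acceptor side is a
biological interpretation left to the caller.  Flat curves (span < 5% of
the maximum) raise an identifiability error rather than returning garbage.
Because published "half times" follow the 1/k convention while the strict
exponential half-time is ln2/k, the fit summary reports both, labelled.

## Trace reduction

Beer–Lambert: c(µM) = sign·ΔA/(Δε·l)·10³ with Δε(551−540) = 21.1
mM⁻¹cm⁻¹ (the alternative literature value 20 is exposed as a constant),
Δε(P/P⁺) = 70, Δε(TMPD) = 12.2.  The sign lives in wavelength-pair
metadata (oxidation bleaches the reduced band at both monitored pairs), so
oxidation is always reported positive and never inferred from noisy data.

Step extraction averages a plateau window 100–350 µs after each flash
(inside the 400 µs spacing, beyond the 50 µs instrument resolution, where
the plateau is stable) and subtracts the same-width window ending at the
flash.  Windows that would overlap the next flash raise a protocol error.

The three-phase fit is a continuous piecewise-linear least-squares model
(hinge basis) with exhaustive search over candidate breakpoint pairs taken
from the sample times (normal-equation scan, final refit by QR); exhaustive
search is cheap and deterministic on these short traces.  Slopes are
reported in time order with per-segment residual RMS; adjacent slopes
within a factor of 2 set a degeneracy flag in the diagnostics instead of
raising, and a straight line yields one slope three times.  The fit is
scale-equivariant by construction.

## Synthetic experiments

The generator emulates: step-like cytochrome oxidation under the standard
train (3 saturating flashes, 400 µs apart, 50 µs sampling, 32-sweep
averaging), three-phase accumulation under continuous strong excitation,
ferricyanide titrations, and P⁺ observables, at [RC] = 1 µM and 1 cm path
so ΔA magnitudes (~10⁻²) match what whole-cell spectroscopy resolves.
Noise is Gaussian per sample with per-sweep σ = 10⁻⁴ absorbance units
divided by √n_averages; the instrument's true noise amplitude is not
published, so σ is a package choice (exposed as a parameter) sized to make
the staircases statistically recoverable, and the 1/√n averaging law is
itself tested.  A single integer seed drives all randomness; identical
inputs give identical bytes.

**Preset calibration.**  Published damping constants pin each wild-type /
mutant preset: K_D2 = 49, K_D3 = 3.7 (*Rvx.* WT, pool 10/RC, k_AB = 10⁴ /
7.2·10³ s⁻¹), K_D2 = 3.5, K_D3 = 1.4 (*Rba.* WT, pool 5/RC, 1.2·10⁴ /
6·10³ s⁻¹), K_D2 = 0.75, K_D3 = 0.3 (PufC mutant).  K_D1 is not published
(absolute normalization rests on the cycA calibration), so each preset
carries a documented choice: 1999 for *Rvx.* WT (the first step of the
tetraheme-bearing strain is essentially complete, and a large K_D1 keeps
the microscopic link constants non-increasing so that carry-over closed
RCs are never re-oxidized by a later, larger constant), 9 for *Rba.* WT,
1.5 for the PufC mutant (its reduced steps are modelled phenomenologically
as lowered K_D, since altered binding vs altered transfer cannot be
distinguished from step data).  The microscopic link constants are
back-solved at generation time by a secant iteration in log-odds space:
simulate the standard protocol noiselessly, push the trace through the same
extraction and inversion the analysis uses, and adjust K_e until the
recovered constants equal the targets (tolerance 10⁻⁵, cached per preset).
The iteration tolerates the flat response near the acceptor-imposed ceiling
r₂ ≤ 1 − e^{−k_AB1·400µs} ≈ 0.982, which is why K_D2 = 49 (r₂ = 0.98) is
intrinsically the most noise-sensitive recovered quantity.

**Continuous-light experiments.**  The published three-phase transient
(slopes 1.5·10⁴, 3.0·10³, 50 cyt³⁺/RC/s; breakpoints near 1 and 10 ms)
accumulates far more than 3 oxidations before its first breakpoint, which a
chain with acceptor capacity 3 and millisecond quinol exchange cannot
sustain at these rates.  The generator therefore has two modes: *designed*
(default for untreated donor-competent strains) composes the three-phase
shape directly from configured slopes and breakpoints — phase 1 slope is
k_L, the light-limited rate — and records them as ground truth for the
segmented fit; *mechanistic* integrates the chain model and is the default
wherever the saturation behaviour is the point (terbutryne, dithionite,
donor-less cycA).  The stationary-phase rate is thus an independent design
parameter, not an emergent constant of the chain.

**Ferricyanide.**  Uptake and redox equilibration are slow and
progressive; the simplest monotone emulation is single-exponential pool
oxidation r(t_inc) = e^{−k_ox·t_inc} with default half-time 30 min (inside
the 2 h monitored window), applied to the dark-adapted reduced fraction.
Ground-truth K_D at each incubation time is recomputed by the noiseless
pipeline and declines monotonically.

## What the synthetic data do and do not show

Passing the end-to-end tests shows the *analysis* is correct and unbiased
under the generator's assumptions: Gaussian sampling noise, perfectly
uniform grids, instantaneous saturating flashes, no baseline drift, no
scattered-light artifacts, no flash-lamp afterglow, and a donor side whose
generalized equilibria are exactly realizable.  Real whole-cell traces add
baseline drift, correlated noise, partial flash saturation and spectral
cross-talk; none of these failure modes is emulated, so performance there
is a separate question.  The acceptance checks on real-data figures are
therefore structural (staircase shape, strain ordering of the damping,
monotone K_D decline under oxidation) rather than numeric.

## Problem sizes

Default runs are small by design: 48-state ODEs over 1.7 ms (flash trains)
or 20 ms (continuous), 400-point traces, 12-point damping curves, 100-fit
noise ensembles.  The full test suite runs in well under a minute on one
core.

## Known limitations

No stochastic (per-RC) simulation; sub-µs photophysics treated as
instantaneous; no intra-tetraheme hopping (the four hemes enter only
through the lumped K_D); no proton uptake or membrane potential; the
flash-number dependence of the collisional ferrocene rate is not modelled
(k_ext is constant); mixed finite/irreversible donor links are not allowed
under continuous light; step extraction supports up to three flashes.
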