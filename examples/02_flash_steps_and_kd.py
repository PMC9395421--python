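"""From a flash-train absorbance trace to donor equilibrium constants.

Three saturating flashes 400 us apart oxidize cytochromes in damped steps
Delta1 >= Delta2 >= Delta3.  The step ratios measure the availability of
reduced cytochrome to P+ after each flash, expressed as generalized
equilibrium constants K_D2 = r2/(1-r2), K_D3 = r3/(1-r3).  This script
generates a synthetic wild-type trace (with instrument-like noise), reduces
it, and compares the recovered constants with the generator's ground truth.
"""

from photocyt import (NoiseModel, absorbance_to_concentration, extract_steps,
                      generate_flash_experiment, invert_steps, strain_preset)

preset = strain_preset("rvx_wt")
trace, truth = generate_flash_experiment(preset, noise=NoiseModel(seed=7))

conc = absorbance_to_concentration(trace)          # Beer-Lambert, per RC
steps = extract_steps(conc, trace.protocol)        # plateau differences
kd = invert_steps(steps, clip_tol=0.01)            # damping -> K_D

print(f"trace: {trace.wavelength_pair} nm, de = {trace.delta_epsilon} /mM/cm, "
      f"{trace.n_averages}-sweep average")
print(f"steps (cyt3+/RC): D1 = {steps.delta1:.4f}, D2 = {steps.delta2:.4f}, "
      f"D3 = {steps.delta3:.4f}")
print(f"recovered:  K_D2 = {kd.kd2:6.2f}   K_D3 = {kd.kd3:5.2f}")
t = truth["kd_true"]
print(f"truth:      K_D2 = {t['kd2']:6.2f}   K_D3 = {t['kd3']:5.2f}")
print("\nK_D2 near 49 means reduced cytochrome is still almost freely")
print("available at the second flash; K_D3 ~ 3.7 signals the pool beginning")
print("to limit the third turnover.")
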