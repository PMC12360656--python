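"""Sensitivity of the closed-loop spectra to the model's key parameters.

Sweeps sensory-noise scale (sigma_s), control-cost exponent (re) and the
visual delay, and prints gain/phase at a low (0.26 Hz) and a high
(1.93 Hz) perturbation frequency for both feedback conditions.
"""

import numpy as np

from steerlqg import (ModelConfig, PerturbationSpec, VISUAL, VISUOINERTIAL,
                      build_joint, build_model, solve_gains, unwrapped_response)

freqs = np.asarray(PerturbationSpec().frequencies_hz)
I_LO, I_HI = 1, 11     # 0.26 Hz and 1.93 Hz


def report(cfg):
    ss = build_model(cfg)
    g, p = unwrapped_response(build_joint(ss, solve_gains(ss)), freqs)
    return g[I_LO], np.degrees(p[I_LO]), g[I_HI], np.degrees(p[I_HI])


print("sigma_s sweep (visuoinertial, re=-1):")
for s in (0.2, 1.0, 5.0, 20.0):
    glo, plo, ghi, phi = report(ModelConfig().with_theta(sigma_s=s))
    print(f"  sigma_s={s:5.1f}  gain {glo:.3f}/{ghi:.4f}  phase {plo:7.1f}/{phi:7.1f} deg")

print("\ncontrol-cost sweep (visuoinertial, sigma_s=1):")
for re in (-2.0, -1.5, -1.0, -0.5):
    glo, plo, ghi, phi = report(ModelConfig().with_theta(r_exponent=re))
    print(f"  re={re:5.1f}      gain {glo:.3f}/{ghi:.4f}  phase {plo:7.1f}/{phi:7.1f} deg")

print("\nvisual-delay sweep (0-10 steps of 1/60 s):")
for d in (0, 4, 7, 10):
    for cond in (VISUAL, VISUOINERTIAL):
        glo, plo, ghi, phi = report(ModelConfig(condition=cond,
                                                visual_delay_steps=d))
        print(f"  delay={d:2d} {cond:13s} gain {glo:.3f}/{ghi:.4f} "
              f"phase {plo:7.1f}/{phi:7.1f} deg")

print("\nLower sensory noise and lower control cost both raise the "
      "compensatory gain (the loop approaches a pass-through); the visual "
      "delay mostly moves the visual-only condition's phase, with minimal "
      "effect on gain or on the visuoinertial condition, whose vestibular "
      "channel supplies low-latency feedback.")
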