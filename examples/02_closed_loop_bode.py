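"""Analytic Bode spectra of the closed-loop steering model.

Builds the delay-augmented LQG model for the visuoinertial condition
(delayed visual position/velocity plus a 1-step-delayed acceleration
channel) and the visual-only condition, and prints the compensatory gain
and relative phase at the 12 perturbation frequencies.  Ideal rejection
would be gain 1 at -180 deg.
"""

import numpy as np

from steerlqg import (ModelConfig, PerturbationSpec, VISUAL, VISUOINERTIAL,
                      build_joint, build_model, solve_gains,
                      frequency_response, unwrapped_response)

freqs = np.asarray(PerturbationSpec().frequencies_hz)
rows = {}
for cond in (VISUOINERTIAL, VISUAL):
    ss = build_model(ModelConfig(condition=cond))
    joint = build_joint(ss, solve_gains(ss))
    gain, phase = unwrapped_response(joint, freqs)
    rows[cond] = (gain, np.degrees(phase))

print("  f (Hz)   gain VI   gain V    phase VI (deg)  phase V (deg)")
for i, f in enumerate(freqs):
    print(f"  {f:5.2f}   {rows[VISUOINERTIAL][0][i]:7.3f}  {rows[VISUAL][0][i]:7.3f}"
          f"      {rows[VISUOINERTIAL][1][i]:9.1f}      {rows[VISUAL][1][i]:9.1f}")
print("\nBoth loops are low-pass: gain falls with frequency. Gains are "
      "nearly identical, but the visual-only loop lags progressively more "
      "(phase farther below -180 deg) because its only self-motion channel "
      "is delayed ~117 ms; in the visuoinertial loop the 1-step vestibular "
      "acceleration channel offsets the visual delay.")
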