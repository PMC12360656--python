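"""Generate a small synthetic study and analyze the condition contrast.

A scaled-down version of the full design (22 participants x 2 conditions
x 11 trials): here 4 participants with shorter trials, written to disk as
CSV + JSON and read back through the package's I/O layer before analysis.
"""

import tempfile
from pathlib import Path

import numpy as np

from steerlqg import (PerturbationSpec, StudyConfig, VISUAL, VISUOINERTIAL,
                      compensation_spectrum, generate_study, read_trial,
                      rmse_position)

spec = PerturbationSpec(main_s=60.0, ramp_down_s=5.0)
study = StudyConfig(n_participants=4, trials_per_condition=3,
                    perturbation=spec)

with tempfile.TemporaryDirectory() as tmp:
    manifest = generate_study(study, seed=11, out_dir=Path(tmp) / "study")
    print(f"generated {sum(len(p['trials']) for p in manifest.participants)} "
          f"trials for {manifest.n_participants} participants "
          f"(config hash {manifest.config_hash})")
    rmse = {VISUAL: [], VISUOINERTIAL: []}
    hf_gain = {VISUAL: [], VISUOINERTIAL: []}
    for p in manifest.participants:
        th = p["theta"]
        print(f"  {p['id']}: sigma_s={th['sigma_s']:.2f} "
              f"re_vis={th['re_vis']:.2f} re_visuo={th['re_visuo']:.2f} "
              f"order={'->'.join(p['condition_order'])}")
        for t in p["trials"]:
            if t["practice"]:
                continue
            tr = read_trial(Path(tmp) / "study" / t["file"])
            rmse[t["condition"]].append(rmse_position(tr))
            sp = compensation_spectrum(tr, spec)
            hf_gain[t["condition"]].append(float(np.mean(sp.gain[6:])))

    for cond in (VISUOINERTIAL, VISUAL):
        print(f"{cond}: mean RMSE {np.mean(rmse[cond]):.3f} m, "
              f"mean high-frequency gain {np.mean(hf_gain[cond]):.4f}")
print("\nBecause each participant's visual-condition control cost is drawn "
      "higher (re_vis >= re_visuo), the study reproduces the qualitative "
      "contrast: better perturbation rejection (lower RMSE, higher "
      "high-frequency gain) with visuoinertial feedback.")
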