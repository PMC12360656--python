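"""Synthetic study emulation with known ground truth, plus trial file I/O.

Emulates the study design end to end: 22 participants, two conditions
(visuoinertial and visual) run blockwise with the order counterbalanced by
participant parity, 1 practice + 10 experimental trials per condition,
145-s trials at 60 Hz.  Each synthetic participant has its own true
theta = (sigma_s, re_vis, re_visuo) drawn from configured ranges; every
trial is a fresh sum-of-sines perturbation driven through the closed-loop
model with all noise sources on.  Everything — parameter draws,
perturbation phases, simulation noise — derives deterministically from one
global seed, and the per-participant/per-trial seeds are derived
hierarchically so a smaller study with the same global seed reproduces the
first participants of a larger one byte for byte.

Trial files are CSV (one row per sample, unit-tagged column names) with a
JSON sidecar carrying all metadata needed for exact replay; a manifest at
the study root lists participants, true parameters, seeds and files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import (VISUAL, VISUOINERTIAL, CostSpec, ModelConfig, NoiseSpec,
                    build_joint, build_model, solve_gains)
from .perturbation import PerturbationSpec, generate_perturbation
from .simulate import TrialRecord, simulate_trial

__all__ = ["StudyConfig", "StudyManifest", "generate_study",
           "read_trial", "write_trial"]

#: Columns of a trial CSV, in order, with units in the names.
TRIAL_COLUMNS = ("t_s", "pert_vel_mps", "pert_pos_m", "car_pos_m",
                 "car_vel_mps", "car_acc_mps2", "wheel_deg", "wheel_vel_dps", "u")


class TrialFormatError(ValueError):
    """A trial file is missing a required column, marker or unit tag."""


@dataclass(frozen=True)
class StudyConfig:
    """Design of the synthetic study.

    True-parameter ranges: sigma_s log-uniform on [0.5, 2]; re_visuo
    uniform on [-2, -0.5]; re_vis = re_visuo + delta with delta uniform on
    [0, 1], so the visual condition carries the higher control cost (the
    larger r), matching the direction of the fitted exponents.
    """

    n_participants: int = 22
    trials_per_condition: int = 10       # experimental trials
    practice_trials: int = 1
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    base_model: ModelConfig = field(default_factory=ModelConfig)
    sigma_s_range: Tuple[float, float] = (0.5, 2.0)
    re_visuo_range: Tuple[float, float] = (-2.0, -0.5)
    re_delta_range: Tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_per_condition < 1:
            raise ValueError("need at least one participant and one trial")
        if self.practice_trials < 0:
            raise ValueError("practice_trials must be >= 0")


@dataclass
class StudyManifest:
    """Provenance of one generated study."""

    seed: int
    config_hash: str
    n_participants: int
    trials_per_condition: int
    practice_trials: int
    participants: List[Dict]             # id, theta, condition order, files

    def to_dict(self) -> Dict:
        return asdict(self)


def _config_hash(study: StudyConfig) -> str:
    blob = json.dumps(_jsonable(asdict(study)), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _trial_seed(global_seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2**31, independent of study size."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _draw_theta(study: StudyConfig, global_seed: int, p: int) -> Dict[str, float]:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=global_seed, spawn_key=(p, 999)))
    lo, hi = study.sigma_s_range
    sigma_s = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    re_visuo = float(rng.uniform(*study.re_visuo_range))
    re_vis = re_visuo + float(rng.uniform(*study.re_delta_range))
    return {"sigma_s": sigma_s, "re_vis": re_vis, "re_visuo": re_visuo}


def generate_study(study: StudyConfig, seed: int, out_dir,
                   overwrite: bool = False) -> StudyManifest:
    """Generate all trials and the manifest under ``out_dir``.

    Layout: ``P{id:02d}/{condition}/trial{k:02d}.csv`` (+ ``.json``
    sidecar), trial 0 being the practice trial; ``manifest.json`` at the
    root.  Fully reproducible from ``seed``.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    participants = []
    n_trials = study.practice_trials + study.trials_per_condition
    for p in range(study.n_participants):
        theta = _draw_theta(study, seed, p)
        # counterbalance block order by parity
        order = ([VISUOINERTIAL, VISUAL] if p % 2 == 0 else [VISUAL, VISUOINERTIAL])
        entry = {"id": f"P{p:02d}", "theta": theta, "condition_order": order,
                 "trials": []}
        for ci, cond in enumerate(order):
            re = theta["re_vis"] if cond == VISUAL else theta["re_visuo"]
            cfg = study.base_model.with_theta(sigma_s=theta["sigma_s"],
                                              r_exponent=re, condition=cond)
            ss = build_model(cfg)
            joint = build_joint(ss, solve_gains(ss))
            for k in range(n_trials):
                pert_seed = _trial_seed(seed, p, ci, k, 0)
                sim_seed = _trial_seed(seed, p, ci, k, 1)
                pert = generate_perturbation(study.perturbation, pert_seed)
                trial = simulate_trial(joint, pert, seed=sim_seed, noise_on=True)
                trial.participant = entry["id"]
                trial.practice = k < study.practice_trials
                rel = Path(entry["id"]) / cond / f"trial{k:02d}.csv"
                write_trial(trial, out / rel)
                entry["trials"].append({
                    "condition": cond, "practice": trial.practice,
                    "pert_seed": pert_seed, "sim_seed": sim_seed,
                    "file": str(rel)})
        participants.append(entry)

    manifest = StudyManifest(seed=seed, config_hash=_config_hash(study),
                             n_participants=study.n_participants,
                             trials_per_condition=study.trials_per_condition,
                             practice_trials=study.practice_trials,
                             participants=participants)
    manifest_path.write_text(
        json.dumps(_jsonable(manifest.to_dict()), sort_keys=True, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# Trial file I/O

def write_trial(trial: TrialRecord, path) -> None:
    """Write one trial as CSV plus a JSON metadata sidecar (lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series = {
        "t_s": trial.time_s, "pert_vel_mps": trial.pert_vel_mps,
        "pert_pos_m": trial.pert_pos_m, "car_pos_m": trial.car_pos_m,
        "car_vel_mps": trial.car_vel_mps, "car_acc_mps2": trial.car_acc_mps2,
        "wheel_deg": trial.wheel_deg, "wheel_vel_dps": trial.wheel_vel_dps,
        "u": trial.u,
    }
    df = pd.DataFrame(series, columns=list(TRIAL_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "condition": trial.condition, "seed": trial.seed,
        "participant": trial.participant, "practice": trial.practice,
        "pert_seed": trial.pert_seed,
        "pert_phases": _jsonable(trial.pert_phases),
        "markers": {"i_countdown_end": trial.i_countdown_end,
                    "i_main_start": trial.i_main_start,
                    "i_main_end": trial.i_main_end},
        "units": {"position": "m", "velocity": "m/s", "acceleration": "m/s^2",
                  "wheel": "deg", "time": "s"},
        "config": _jsonable(asdict(trial.config)),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True, indent=1))


def _config_from_dict(d: Dict) -> ModelConfig:
    d = dict(d)
    d["noise"] = NoiseSpec(**d["noise"])
    d["cost"] = CostSpec(**d["cost"])
    return ModelConfig(**d)


def read_trial(path) -> TrialRecord:
    """Read a trial written by :func:`write_trial`; lossless round trip."""
    path = Path(path)
    meta_path = path.with_suffix(".json")
    if not meta_path.exists():
        raise TrialFormatError(f"missing metadata sidecar {meta_path.name}")
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"trial file {path.name} missing column(s) {missing}")
    units = meta.get("units", {})
    expected_units = {"position": "m", "wheel": "deg"}
    for kind, unit in expected_units.items():
        if units.get(kind) != unit:
            raise TrialFormatError(
                f"unit mismatch for {kind!r}: expected {unit!r}, got {units.get(kind)!r}")
    markers = meta.get("markers") or {}
    for key in ("i_countdown_end", "i_main_start", "i_main_end"):
        if key not in markers:
            raise TrialFormatError(f"missing timeline marker {key!r}")
    phases = meta.get("pert_phases")
    return TrialRecord(
        time_s=df["t_s"].to_numpy(),
        pert_vel_mps=df["pert_vel_mps"].to_numpy(),
        pert_pos_m=df["pert_pos_m"].to_numpy(),
        car_pos_m=df["car_pos_m"].to_numpy(),
        car_vel_mps=df["car_vel_mps"].to_numpy(),
        car_acc_mps2=df["car_acc_mps2"].to_numpy(),
        wheel_deg=df["wheel_deg"].to_numpy(),
        wheel_vel_dps=df["wheel_vel_dps"].to_numpy(),
        u=df["u"].to_numpy(),
        condition=meta["condition"], seed=meta["seed"],
        config=_config_from_dict(meta["config"]),
        i_countdown_end=markers["i_countdown_end"],
        i_main_start=markers["i_main_start"],
        i_main_end=markers["i_main_end"],
        participant=meta.get("participant"),
        practice=bool(meta.get("practice", False)),
        pert_seed=meta.get("pert_seed"),
        pert_phases=None if phases is None else np.asarray(phases),
    )
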