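"""Pseudorandom sum-of-sines velocity perturbation.

The perturbation used for closed-loop system identification is a zero-mean
sum of sinusoids at 12 fixed, incommensurate frequencies (0.1-1.93 Hz), each
with a velocity amplitude of 0.1 m/s and a phase drawn uniformly on
[0, 2*pi).  Phase sets whose summed signal exceeds a peak-speed cap
(0.6 m/s) are rejected and redrawn, so every accepted trial is guaranteed to
stay within the motion-platform safety envelope while keeping the
per-component amplitudes exactly at their design value.

A trial timeline consists of a countdown (zero perturbation), a linear
ramp-up, the main analysis window, and a linear ramp-down; only the main
window is ever analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "DEFAULT_FREQUENCIES_HZ",
    "PerturbationSpec",
    "PerturbationTrial",
    "generate_perturbation",
    "extract_analysis_window",
]

#: Temporal frequencies (Hz) of the 12 perturbation components.
DEFAULT_FREQUENCIES_HZ: Tuple[float, ...] = (
    0.1, 0.26, 0.43, 0.60, 0.76, 0.93, 1.10, 1.26, 1.43, 1.60, 1.76, 1.93,
)


class InfeasiblePerturbationError(RuntimeError):
    """Rejection sampling exhausted its draw budget (cap likely too tight)."""


@dataclass(frozen=True)
class PerturbationSpec:
    """Design of the sum-of-sines perturbation and its trial timeline.

    Parameters
    ----------
    frequencies_hz
        Strictly increasing component frequencies in Hz.
    amplitude_mps
        Velocity amplitude of every component, m/s.
    vmax_mps
        Peak-speed cap applied to the summed (un-enveloped) signal, m/s.
    countdown_s, ramp_up_s, main_s, ramp_down_s
        Phase durations in seconds.  The main window is the only part used
        for analysis.
    rate_hz
        Sample rate in Hz; must exceed twice the highest component frequency.
    max_draws
        Budget for the phase rejection loop.
    """

    frequencies_hz: Tuple[float, ...] = DEFAULT_FREQUENCIES_HZ
    amplitude_mps: float = 0.1
    vmax_mps: float = 0.6
    countdown_s: float = 5.0
    ramp_up_s: float = 5.0
    main_s: float = 120.0
    ramp_down_s: float = 15.0
    rate_hz: float = 60.0
    max_draws: int = 10_000

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequencies_hz must be a non-empty 1-D sequence")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        if self.amplitude_mps <= 0:
            raise ValueError("amplitude_mps must be > 0")
        if self.vmax_mps <= self.amplitude_mps:
            raise ValueError("vmax_mps must exceed the per-component amplitude")
        for name in ("countdown_s", "ramp_up_s", "main_s", "ramp_down_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rate_hz <= 2.0 * f[-1]:
            raise ValueError("rate_hz must exceed twice the highest frequency")
        if self.max_draws < 1:
            raise ValueError("max_draws must be >= 1")

    # -- timeline ----------------------------------------------------------
    @property
    def total_s(self) -> float:
        return self.countdown_s + self.ramp_up_s + self.main_s + self.ramp_down_s

    @property
    def n_samples(self) -> int:
        return int(round(self.total_s * self.rate_hz))

    @property
    def i_countdown_end(self) -> int:
        return int(round(self.countdown_s * self.rate_hz))

    @property
    def i_main_start(self) -> int:
        return int(round((self.countdown_s + self.ramp_up_s) * self.rate_hz))

    @property
    def i_main_end(self) -> int:
        return self.i_main_start + int(round(self.main_s * self.rate_hz))

    def time(self) -> np.ndarray:
        """Sample times in seconds, t = 0 at trial start."""
        return np.arange(self.n_samples) / self.rate_hz

    def envelope(self) -> np.ndarray:
        """Piecewise-linear amplitude envelope: 0 in countdown, 1 in the
        main window, linear ramps in between."""
        t = self.time()
        t0, t1 = self.countdown_s, self.countdown_s + self.ramp_up_s
        t2 = t1 + self.main_s
        env = np.zeros_like(t)
        if self.ramp_up_s > 0:
            env = np.where((t >= t0) & (t < t1), (t - t0) / self.ramp_up_s, env)
        env = np.where((t >= t1) & (t < t2), 1.0, env)
        if self.ramp_down_s > 0:
            env = np.where(t >= t2, np.clip((self.total_s - t) / self.ramp_down_s, 0.0, 1.0), env)
        return env


@dataclass
class PerturbationTrial:
    """One realized perturbation: phases, sampled velocity and position."""

    spec: PerturbationSpec
    seed: int
    phases: np.ndarray          # radians, one per component, in [0, 2*pi)
    velocity: np.ndarray        # m/s, full timeline (envelope applied)
    position: np.ndarray        # m, cumulative integral of velocity
    n_draws: int = 1            # phase sets drawn until the cap was met
    i_countdown_end: int = field(default=0)
    i_main_start: int = field(default=0)
    i_main_end: int = field(default=0)
    i_offset: int = 0           # absolute index of sample 0 (nonzero after windowing)

    @property
    def time(self) -> np.ndarray:
        """Absolute trial time of each stored sample (t = 0 at trial start)."""
        return (np.arange(len(self.velocity)) + self.i_offset) / self.spec.rate_hz

    def analysis_slice(self) -> slice:
        if not (0 <= self.i_main_start < self.i_main_end <= len(self.velocity)):
            raise ValueError("trial timeline markers are missing or inconsistent")
        return slice(self.i_main_start, self.i_main_end)


def _raw_sum_of_sines(spec: PerturbationSpec, phases: np.ndarray,
                      t: np.ndarray) -> np.ndarray:
    arg = 2.0 * np.pi * np.outer(t, np.asarray(spec.frequencies_hz))
    return spec.amplitude_mps * np.sin(arg + phases).sum(axis=1)


def generate_perturbation(spec: PerturbationSpec, seed: int) -> PerturbationTrial:
    """Draw phases, enforce the peak-speed cap by rejection, and sample the
    enveloped perturbation over the full trial timeline.

    The cap is checked on the un-enveloped sum-of-sines over the whole
    active region (ramp-up through ramp-down); since the envelope never
    exceeds 1 this bounds the emitted velocity everywhere.  Deterministic
    for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    t = spec.time()
    active = t >= spec.countdown_s
    t_active = t[active]
    # Basis evaluated once; each draw is then two small mat-vecs.
    arg = 2.0 * np.pi * np.outer(t_active, np.asarray(spec.frequencies_hz))
    sin_b, cos_b = np.sin(arg), np.cos(arg)

    for draw in range(1, spec.max_draws + 1):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(spec.frequencies_hz))
        raw = spec.amplitude_mps * (sin_b @ np.cos(phases) + cos_b @ np.sin(phases))
        if np.max(np.abs(raw)) <= spec.vmax_mps:
            break
    else:
        raise InfeasiblePerturbationError(
            f"no phase set met the {spec.vmax_mps} m/s cap in {spec.max_draws} draws"
        )

    velocity = np.zeros_like(t)
    velocity[active] = raw
    velocity *= spec.envelope()
    # Left-rectangle integration: position[k] = sum(velocity[:k]) * dt,
    # matching the velocity-controlled discrete plant.
    dt = 1.0 / spec.rate_hz
    position = np.concatenate(([0.0], np.cumsum(velocity[:-1]))) * dt
    return PerturbationTrial(
        spec=spec, seed=seed, phases=phases,
        velocity=velocity, position=position, n_draws=draw,
        i_countdown_end=spec.i_countdown_end,
        i_main_start=spec.i_main_start, i_main_end=spec.i_main_end,
    )


def extract_analysis_window(trial):
    """Return a copy of a trial restricted to the central analysis window.

    Works for :class:`PerturbationTrial` and for the closed-loop
    ``TrialRecord`` (anything exposing ``analysis_slice`` and per-sample
    series).  The returned samples are bitwise-equal to the corresponding
    slice of the input.
    """
    sl = trial.analysis_slice()
    if isinstance(trial, PerturbationTrial):
        out = replace(
            trial,
            velocity=trial.velocity[sl].copy(),
            position=trial.position[sl].copy(),
        )
        out.i_countdown_end = 0
        out.i_main_start = 0
        out.i_main_end = sl.stop - sl.start
        out.i_offset = trial.i_offset + sl.start
        return out
    if hasattr(trial, "window"):  # TrialRecord implements its own slicing
        return trial.window(sl)
    raise TypeError(f"cannot extract analysis window from {type(trial)!r}")
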