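"""Closed-loop trial simulation and analytic frequency response.

A trial iterates the joint [x; x_hat] system at the sample rate over the
full trial timeline, injecting the perturbation velocity and (optionally)
fresh Gaussian draws for motor noise, observation noise and estimator
prediction noise.  The analytic counterpart evaluates the same closed loop's
transfer function from perturbation velocity to the wheel-commanded
(compensatory) velocity at arbitrary frequencies via the z-transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .freqid import Spectrum, wrap_phase
from .model import JointSystem, ModelConfig, build_joint, build_model, solve_gains
from .perturbation import PerturbationTrial

__all__ = ["TrialRecord", "simulate_trial", "frequency_response",
           "unwrapped_response", "response_for_config"]


@dataclass
class TrialRecord:
    """Time series of one closed-loop trial plus its provenance."""

    time_s: np.ndarray
    pert_vel_mps: np.ndarray
    pert_pos_m: np.ndarray
    car_pos_m: np.ndarray
    car_vel_mps: np.ndarray
    car_acc_mps2: np.ndarray
    wheel_deg: np.ndarray
    wheel_vel_dps: np.ndarray
    u: np.ndarray
    condition: str
    seed: int
    config: ModelConfig
    i_countdown_end: int = 0
    i_main_start: int = 0
    i_main_end: int = 0
    participant: Optional[str] = None
    practice: bool = False
    pert_seed: Optional[int] = None
    pert_phases: Optional[np.ndarray] = None

    _SERIES = ("time_s", "pert_vel_mps", "pert_pos_m", "car_pos_m",
               "car_vel_mps", "car_acc_mps2", "wheel_deg", "wheel_vel_dps", "u")

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in self._SERIES:
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name} length differs from time axis")

    @property
    def time(self) -> np.ndarray:
        return self.time_s

    def analysis_slice(self) -> slice:
        if not (0 <= self.i_main_start < self.i_main_end <= len(self.time_s)):
            raise ValueError("trial timeline markers are missing or inconsistent")
        return slice(self.i_main_start, self.i_main_end)

    def window(self, sl: slice) -> "TrialRecord":
        """Copy restricted to ``sl``; timeline markers shift accordingly."""
        kw = {name: np.asarray(getattr(self, name))[sl].copy() for name in self._SERIES}
        return TrialRecord(
            **kw, condition=self.condition, seed=self.seed, config=self.config,
            i_countdown_end=max(0, self.i_countdown_end - sl.start),
            i_main_start=max(0, self.i_main_start - sl.start),
            i_main_end=min(sl.stop, self.i_main_end) - sl.start,
            participant=self.participant, practice=self.practice,
            pert_seed=self.pert_seed, pert_phases=self.pert_phases,
        )


def _iterate(F: np.ndarray, drive: np.ndarray) -> np.ndarray:
    """Run Z[t+1] = F Z[t] + drive[:, t] from Z[0] = 0; returns Z (m x T)."""
    m, T = drive.shape
    Z = np.zeros((m, T))
    z = np.zeros(m)
    for t in range(T - 1):
        z = F @ z + drive[:, t]
        Z[:, t + 1] = z
    return Z


def simulate_trial(joint: JointSystem, pert: PerturbationTrial, seed: int,
                   noise_on: bool = True) -> TrialRecord:
    """Simulate one closed-loop trial over the perturbation's full timeline.

    The true state and the estimate both start at zero (at rest on the road
    center); transients fall in the discarded ramp-up.  With ``noise_on``,
    independent standard-normal streams drive motor noise, observation noise
    and estimator prediction noise, expanded deterministically from ``seed``.
    """
    rho = joint.spectral_radius()
    if rho >= 1.0:
        raise RuntimeError(f"joint closed loop is unstable (spectral radius {rho:.4f})")
    ss = joint.ss
    eps = np.asarray(pert.velocity, dtype=float)
    T = eps.size
    drive = joint.E_pert @ eps[None, :]
    if noise_on:
        streams = np.random.SeedSequence(seed).spawn(3)
        r_eta, r_omega, r_xi = (np.random.default_rng(s) for s in streams)
        drive = drive + joint.E_eta @ r_eta.standard_normal((joint.E_eta.shape[1], T))
        drive = drive + joint.E_omega @ r_omega.standard_normal((joint.E_omega.shape[1], T))
        drive = drive + joint.E_xi @ r_xi.standard_normal((joint.E_xi.shape[1], T))
    Z = _iterate(joint.F, drive)

    x = Z[: joint.n]
    cfg = ss.config
    dt = cfg.dt
    return TrialRecord(
        time_s=pert.time.copy(),
        pert_vel_mps=eps.copy(),
        pert_pos_m=np.asarray(pert.position, dtype=float).copy(),
        car_pos_m=x[ss.idx("p_v")].copy(),
        car_vel_mps=x[ss.idx("v_v")].copy(),
        car_acc_mps2=x[ss.idx("a_v")].copy(),
        wheel_deg=x[ss.idx("p_w")].copy(),
        wheel_vel_dps=x[ss.idx("v_w")].copy(),
        u=joint.row_control() @ Z,
        condition=cfg.condition,
        seed=seed,
        config=cfg,
        i_countdown_end=pert.i_countdown_end,
        i_main_start=pert.i_main_start,
        i_main_end=pert.i_main_end,
        pert_seed=pert.seed,
        pert_phases=np.asarray(pert.phases).copy(),
    )


def frequency_response(joint: JointSystem, freqs_hz: Iterable[float]) -> Spectrum:
    """Analytic closed-loop response of the compensatory velocity to the
    perturbation velocity, evaluated at ``z = exp(i 2 pi f dt)``.

    Gain and phase follow the same conventions as the time-series analysis
    (phase wrapped to (-2*pi, 0]; ideal rejection is gain 1, phase -pi).
    """
    rho = joint.spectral_radius()
    if rho >= 1.0:
        raise RuntimeError(f"joint closed loop is unstable (spectral radius {rho:.4f})")
    cfg = joint.ss.config
    f = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    nyquist = 0.5 / cfg.dt
    if np.any(f >= nyquist) or np.any(f <= 0):
        raise ValueError(f"frequencies must lie in (0, {nyquist}) Hz")
    sel = joint.row_controlled_vel()
    m = 2 * joint.n
    resp = np.empty(f.size, dtype=complex)
    for k, fk in enumerate(f):
        z = np.exp(1j * 2.0 * np.pi * fk * cfg.dt)
        resp[k] = sel @ np.linalg.solve(z * np.eye(m) - joint.F, joint.E_pert[:, 0])
    return Spectrum(f, np.abs(resp), wrap_phase(np.angle(resp)))


def unwrapped_response(joint: JointSystem, freqs_hz: Iterable[float],
                       grid_hz: np.ndarray | None = None):
    """Gain and *unwrapped* phase (continuous in frequency, total lag) at
    ``freqs_hz``.

    The analytic phase is unwrapped along a dense frequency grid starting
    near DC, so lags beyond one turn are kept rather than wrapped; this is
    the quantity used when comparing how close two closed loops stay to the
    ideal -pi across frequency.
    """
    f = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if grid_hz is None:
        grid_hz = np.linspace(0.02, float(f.max()), 512)
    sp = frequency_response(joint, grid_hz)
    phase = np.unwrap(sp.phase_rad)
    return np.interp(f, grid_hz, sp.gain), np.interp(f, grid_hz, phase)


def response_for_config(cfg: ModelConfig, freqs_hz: Iterable[float]) -> Spectrum:
    """Convenience: build the model, synthesize gains, and return the
    analytic compensation spectrum for ``cfg`` (used for parameter sweeps)."""
    ss = build_model(cfg)
    joint = build_joint(ss, solve_gains(ss))
    return frequency_response(joint, freqs_hz)
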