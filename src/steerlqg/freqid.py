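"""Frequency-domain system identification and scalar performance metrics.

Compensatory steering is quantified per perturbation frequency by the gain
(amplitude ratio of the participant-generated velocity over the perturbation
velocity) and the relative phase between the two.  Ideal rejection of the
perturbation is gain 1 at phase -pi.

Amplitudes and phases are obtained by *exact-frequency least squares*: the
design frequencies are not integer multiples of the window's 1/T resolution,
so raw FFT bins would leak across components.  Projecting onto sin/cos pairs
at the exact design frequencies (jointly over the whole design grid, plus a
DC term) is leakage-free and reduces to the FFT when the frequencies are
commensurate with the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "Spectrum",
    "wrap_phase",
    "sinusoid_fit",
    "component_amplitude_phase",
    "compensation_spectrum",
    "rmse_position",
]


@dataclass
class Spectrum:
    """Per-frequency compensatory gain and relative phase.

    ``phase_rad`` is wrapped to (-2*pi, 0] so that increasing lag moves
    monotonically away from -pi without branch jumps across the design grid.
    """

    frequencies_hz: np.ndarray
    gain: np.ndarray
    phase_rad: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        self.phase_rad = np.asarray(self.phase_rad, dtype=float)
        if not (self.frequencies_hz.shape == self.gain.shape == self.phase_rad.shape):
            raise ValueError("spectrum arrays must share one shape")

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(self.phase_rad)


def wrap_phase(delta: np.ndarray | float) -> np.ndarray | float:
    """Wrap a phase difference (radians) into (-2*pi, 0]."""
    two_pi = 2.0 * np.pi
    w = np.mod(delta, two_pi)          # [0, 2*pi)
    out = np.where(w > 0, w - two_pi, 0.0)
    return float(out) if np.isscalar(delta) else out


def _design_matrix(t: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    args = 2.0 * np.pi * np.outer(t, freqs)
    return np.hstack([np.sin(args), np.cos(args), np.ones((len(t), 1))])


def sinusoid_fit(series: np.ndarray, freqs: Sequence[float], rate_hz: float,
                 t: np.ndarray | None = None) -> Tuple[np.ndarray, np.ndarray]:
    """Jointly fit ``A_k sin(2 pi f_k t + phi_k)`` (plus a DC term) for every
    frequency in ``freqs`` by least squares at the exact frequencies.

    Returns ``(amplitudes, phases)``; phases are in [0, 2*pi).  ``t`` gives
    the absolute sample times (defaults to ``arange(n)/rate_hz``), so a
    windowed series keeps the phase reference of the full trial.
    """
    y = np.asarray(series, dtype=float)
    f = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(f >= rate_hz / 2.0):
        raise ValueError("fit frequency at or above Nyquist")
    if np.any(f <= 0):
        raise ValueError("fit frequencies must be positive")
    if t is None:
        t = np.arange(y.size) / rate_hz
    if y.size <= 2 * (2 * f.size + 1):
        raise ValueError("series too short for a stable sinusoid fit")
    X = _design_matrix(np.asarray(t, dtype=float), f)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = coef[: f.size], coef[f.size: 2 * f.size]
    amplitude = np.hypot(a, b)
    phase = np.mod(np.arctan2(b, a), 2.0 * np.pi)
    return amplitude, phase


def component_amplitude_phase(series: np.ndarray, f: float, rate_hz: float,
                              t: np.ndarray | None = None,
                              design_freqs: Iterable[float] | None = None,
                              ) -> Tuple[float, float]:
    """Amplitude and phase of the component at ``f`` Hz.

    When the series is known to contain other deliberate components (e.g.
    the full sum-of-sines design), pass them as ``design_freqs`` so the fit
    is joint and leakage-free; otherwise a single-frequency fit is used.
    """
    freqs = np.atleast_1d(np.asarray(design_freqs if design_freqs is not None else [f],
                                     dtype=float))
    if not np.any(np.isclose(freqs, f)):
        freqs = np.sort(np.append(freqs, f))
    amps, phases = sinusoid_fit(series, freqs, rate_hz, t=t)
    k = int(np.argmin(np.abs(freqs - f)))
    return float(amps[k]), float(phases[k])


def controlled_velocity(trial) -> np.ndarray:
    """Participant-generated (wheel-commanded) vehicle velocity in m/s.

    This is the wheel's contribution to the next-step vehicle velocity,
    ``lambda * (p_w + dt * v_w)``, i.e. the compensatory signal that is
    compared against the perturbation velocity.
    """
    cfg = trial.config
    return cfg.lambda_gain * (trial.wheel_deg + cfg.dt * trial.wheel_vel_dps)


def compensation_spectrum(trial, spec) -> Spectrum:
    """Gain and relative phase of the compensatory velocity at each design
    frequency, over the trial's central analysis window.

    Gain is the amplitude of the controlled (wheel-commanded) velocity over
    the amplitude of the perturbation velocity; relative phase is their
    phase difference, wrapped to (-2*pi, 0].
    """
    sl = trial.analysis_slice()
    t = np.asarray(trial.time)[sl]
    freqs = np.asarray(spec.frequencies_hz, dtype=float)
    pert = np.asarray(trial.pert_vel_mps)[sl]
    ctrl = np.asarray(controlled_velocity(trial))[sl]
    amp_p, ph_p = sinusoid_fit(pert, freqs, spec.rate_hz, t=t)
    amp_c, ph_c = sinusoid_fit(ctrl, freqs, spec.rate_hz, t=t)
    if np.any(amp_p <= 0) or np.any(amp_p < 1e-12):
        bad = freqs[amp_p < 1e-12]
        raise ZeroDivisionError(f"perturbation amplitude is zero at {bad} Hz; gain undefined")
    return Spectrum(freqs, amp_c / amp_p, wrap_phase(ph_c - ph_p))


_WINDOWS = ("full120", "first60", "last60")


def rmse_position(trial, window: str = "full120", about: str = "mean") -> float:
    """Root-mean-square of the vehicle position over (part of) the analysis
    window, in meters.

    ``about="mean"`` removes the window mean first (zero-mean RMSE, the
    default performance measure); ``about="center"`` measures about the road
    center (position 0).  ``window`` selects the full central window or its
    first/last half.
    """
    if window not in _WINDOWS:
        raise ValueError(f"window must be one of {_WINDOWS}")
    if about not in ("mean", "center"):
        raise ValueError("about must be 'mean' or 'center'")
    sl = trial.analysis_slice()
    # Closed-loop trials carry the vehicle position as car_pos_m; a bare
    # perturbation trial exposes its own integrated position instead.
    series = getattr(trial, "car_pos_m", None)
    if series is None:
        series = trial.position
    pos = np.asarray(series)[sl]
    n = pos.size
    if window == "first60":
        pos = pos[: n // 2]
    elif window == "last60":
        pos = pos[n // 2:]
    if pos.size == 0:
        raise ValueError("requested window is empty")
    if about == "mean":
        pos = pos - pos.mean()
    return float(np.sqrt(np.mean(pos ** 2)))
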