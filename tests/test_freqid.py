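"""Exact-frequency least squares, compensation spectra and RMSE metrics."""

import numpy as np
import pytest

from steerlqg import (ModelConfig, PerturbationSpec, Spectrum, TrialRecord,
                      compensation_spectrum, component_amplitude_phase,
                      generate_perturbation, rmse_position, sinusoid_fit,
                      wrap_phase)

RATE = 60.0


def _trial_from_controlled(pert, ctrl_vel, cfg=None):
    """Build a TrialRecord whose wheel-commanded velocity equals ctrl_vel."""
    cfg = cfg or ModelConfig()
    n = len(pert.velocity)
    z = np.zeros(n)
    return TrialRecord(
        time_s=pert.time, pert_vel_mps=pert.velocity, pert_pos_m=pert.position,
        car_pos_m=z, car_vel_mps=z, car_acc_mps2=z,
        wheel_deg=np.asarray(ctrl_vel) / cfg.lambda_gain, wheel_vel_dps=z,
        u=z, condition=cfg.condition, seed=0, config=cfg,
        i_countdown_end=pert.i_countdown_end,
        i_main_start=pert.i_main_start, i_main_end=pert.i_main_end)


def test_exact_sinusoid_recovery():
    t = np.arange(0, 120, 1 / RATE)
    y = 0.37 * np.sin(2 * np.pi * 0.93 * t + 1.234)
    a, p = component_amplitude_phase(y, 0.93, RATE, t=t)
    assert abs(a - 0.37) < 1e-9
    assert abs(p - 1.234) < 1e-9


def test_zero_series_zero_amplitude():
    a, _ = component_amplitude_phase(np.zeros(7200), 0.5, RATE)
    assert a == pytest.approx(0.0, abs=1e-12)


def test_two_tone_joint_fit_leakage_free():
    """Two incommensurate components over 120 s are each recovered to 1e-6
    when the fit is joint over both frequencies."""
    t = np.arange(0, 120, 1 / RATE)
    y = (0.2 * np.sin(2 * np.pi * 0.26 * t + 0.7)
         + 0.05 * np.sin(2 * np.pi * 1.43 * t + 2.9))
    for f, a_true, p_true in ((0.26, 0.2, 0.7), (1.43, 0.05, 2.9)):
        a, p = component_amplitude_phase(y, f, RATE, t=t,
                                         design_freqs=(0.26, 1.43))
        assert abs(a - a_true) < 1e-6
        assert abs(p - p_true) < 1e-6


def test_nyquist_rejected():
    with pytest.raises(ValueError):
        sinusoid_fit(np.zeros(1000), [30.0], RATE)


def test_wrap_phase_convention():
    assert wrap_phase(0.0) == 0.0
    assert wrap_phase(-np.pi) == pytest.approx(-np.pi)
    assert wrap_phase(np.pi) == pytest.approx(-np.pi)
    assert wrap_phase(-0.1 - 2 * np.pi) == pytest.approx(-0.1)
    x = np.linspace(-10, 10, 101)
    w = wrap_phase(x)
    assert np.all((w > -2 * np.pi) & (w <= 0.0))


def test_exact_negative_compensation_gain_one_phase_minus_pi(default_spec):
    pert = generate_perturbation(default_spec, 21)
    tr = _trial_from_controlled(pert, -pert.velocity)
    sp = compensation_spectrum(tr, default_spec)
    assert np.allclose(sp.gain, 1.0, atol=1e-9)
    assert np.allclose(sp.phase_rad, -np.pi, atol=1e-9)


def test_zero_controlled_zero_gain(default_spec):
    pert = generate_perturbation(default_spec, 22)
    tr = _trial_from_controlled(pert, np.zeros_like(pert.velocity))
    sp = compensation_spectrum(tr, default_spec)
    assert np.allclose(sp.gain, 0.0, atol=1e-12)


def test_scaled_delayed_compensation_closed_form(default_spec):
    """ctrl = -0.5 x pert delayed by 100 ms -> gain 0.5 and phase
    -pi - 2*pi*f*0.1 (wrapped) at every design frequency."""
    from steerlqg.perturbation import _raw_sum_of_sines
    pert = generate_perturbation(default_spec, 23)
    # construct the delayed sinusoid sum analytically so the closed form is
    # exact over the analysis window (no envelope bleed at its edges)
    ctrl = -0.5 * _raw_sum_of_sines(default_spec, pert.phases,
                                    pert.time - 0.1)
    tr = _trial_from_controlled(pert, ctrl)
    sp = compensation_spectrum(tr, default_spec)
    f = np.asarray(default_spec.frequencies_hz)
    assert np.allclose(sp.gain, 0.5, atol=1e-6)
    expected = wrap_phase(-np.pi - 2 * np.pi * f * 0.1)
    assert np.allclose(sp.phase_rad, expected, atol=1e-6)


def test_spectrum_invariant_to_orthogonal_additions(default_spec):
    """Adding any component orthogonal (in the LS sense) to the design
    regressors leaves the spectrum unchanged."""
    pert = generate_perturbation(default_spec, 24)
    tr = _trial_from_controlled(pert, -0.8 * pert.velocity)
    base = compensation_spectrum(tr, default_spec)

    sl = tr.analysis_slice()
    t = tr.time_s[sl]
    rng = np.random.default_rng(0)
    extra_full = np.zeros_like(tr.wheel_deg)
    extra = (0.3 * np.sin(2 * np.pi * 0.35 * t)
             + 0.05 * rng.standard_normal(t.size))
    args = 2 * np.pi * np.outer(t, np.asarray(default_spec.frequencies_hz))
    X = np.hstack([np.sin(args), np.cos(args), np.ones((t.size, 1))])
    extra -= X @ np.linalg.lstsq(X, extra, rcond=None)[0]   # residualize
    extra_full[sl] = extra
    tr2 = _trial_from_controlled(
        pert, -0.8 * pert.velocity + extra_full * tr.config.lambda_gain)
    pert_sp = compensation_spectrum(tr2, default_spec)
    assert np.allclose(pert_sp.gain, base.gain, atol=1e-9)
    assert np.allclose(pert_sp.phase_rad, base.phase_rad, atol=1e-9)


def test_gain_scale_equivariance(default_spec):
    pert = generate_perturbation(default_spec, 25)
    t1 = _trial_from_controlled(pert, -0.4 * pert.velocity)
    t2 = _trial_from_controlled(pert, -0.4 * 2.5 * pert.velocity)
    s1, s2 = (compensation_spectrum(x, default_spec) for x in (t1, t2))
    assert np.allclose(s2.gain, 2.5 * s1.gain, rtol=1e-9)
    assert np.allclose(s2.phase_rad, s1.phase_rad, atol=1e-9)


def test_zero_amplitude_perturbation_errors(default_spec):
    pert = generate_perturbation(default_spec, 26)
    tr = _trial_from_controlled(pert, -pert.velocity)
    tr.pert_vel_mps = np.zeros_like(tr.pert_vel_mps)
    with pytest.raises(ZeroDivisionError):
        compensation_spectrum(tr, default_spec)


# -- RMSE -------------------------------------------------------------------

class _Positioned:
    """Minimal stand-in exposing a position series over a 120-s window."""

    def __init__(self, pos):
        self.car_pos_m = np.asarray(pos)
        self.i_main_start, self.i_main_end = 0, len(pos)

    def analysis_slice(self):
        return slice(self.i_main_start, self.i_main_end)


def test_rmse_zero_position():
    assert rmse_position(_Positioned(np.zeros(7200))) == 0.0


def test_rmse_sinusoid_closed_form():
    t = np.arange(0, 120, 1 / RATE)
    tr = _Positioned(0.3 * np.sin(2 * np.pi * 0.5 * t))   # integer cycles
    assert rmse_position(tr) == pytest.approx(0.3 / np.sqrt(2), rel=1e-9)


def test_rmse_constant_offset_both_conventions():
    tr = _Positioned(np.full(7200, 0.25))
    assert rmse_position(tr, about="mean") == pytest.approx(0.0, abs=1e-12)
    assert rmse_position(tr, about="center") == pytest.approx(0.25)


def test_rmse_epoch_decomposition():
    """With per-window mean removal, RMS^2 over the full window equals the
    mean of the two epoch RMS^2 when epoch means are both zero."""
    t = np.arange(0, 120, 1 / RATE)
    pos = 0.2 * np.sin(2 * np.pi * 0.2 * t) + 0.07 * np.sin(2 * np.pi * 1.1 * t)
    tr = _Positioned(pos)
    full = rmse_position(tr, "full120") ** 2
    first = rmse_position(tr, "first60") ** 2
    last = rmse_position(tr, "last60") ** 2
    # integer cycles in every sub-window -> all means are 0 -> exact split
    assert full == pytest.approx((first + last) / 2, rel=1e-9)


def test_rmse_bad_window_rejected():
    with pytest.raises(ValueError):
        rmse_position(_Positioned(np.zeros(100)), window="first30")
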