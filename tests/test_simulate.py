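"""Closed-loop simulation vs analytic frequency response, and the model's
qualitative frequency-domain signatures."""

import numpy as np
import pytest

from steerlqg import (ModelConfig, NoiseSpec, PerturbationSpec, VISUAL,
                      VISUOINERTIAL, compensation_spectrum,
                      frequency_response, generate_perturbation,
                      response_for_config, simulate_trial, unwrapped_response)
from conftest import make_joint

FREQS = np.asarray(PerturbationSpec().frequencies_hz)


def test_zero_perturbation_noise_free_stays_at_rest(vi_joint, default_spec):
    pert = generate_perturbation(default_spec, 1)
    pert.velocity = np.zeros_like(pert.velocity)
    pert.position = np.zeros_like(pert.position)
    tr = simulate_trial(vi_joint, pert, seed=0, noise_on=False)
    assert np.all(tr.car_pos_m == 0.0)
    assert np.all(tr.wheel_deg == 0.0)
    assert np.all(tr.u == 0.0)


def test_simulation_deterministic_for_fixed_seed(vi_joint, default_spec):
    pert = generate_perturbation(default_spec, 2)
    a = simulate_trial(vi_joint, pert, seed=7, noise_on=True)
    b = simulate_trial(vi_joint, pert, seed=7, noise_on=True)
    assert np.array_equal(a.wheel_deg, b.wheel_deg)
    assert np.array_equal(a.car_pos_m, b.car_pos_m)


def test_noise_free_kinematic_consistency(vi_joint, default_spec):
    """Recorded series satisfy the vehicle equations given the recorded
    wheel and perturbation (residual < 1e-9)."""
    cfg = vi_joint.ss.config
    tr = simulate_trial(vi_joint, generate_perturbation(default_spec, 3),
                        seed=0, noise_on=False)
    dt, lam = cfg.dt, cfg.lambda_gain
    res_p = tr.car_pos_m[1:] - (tr.car_pos_m[:-1] + dt * tr.car_vel_mps[:-1])
    res_v = tr.car_vel_mps[1:] - (lam * (tr.wheel_deg[:-1]
                                         + dt * tr.wheel_vel_dps[:-1])
                                  + tr.pert_vel_mps[:-1])
    assert np.max(np.abs(res_p)) < 1e-9
    assert np.max(np.abs(res_v)) < 1e-9


def test_single_sinusoid_matches_analytic_within_1pct(vi_joint):
    spec = PerturbationSpec(frequencies_hz=(0.1,))
    pert = generate_perturbation(spec, 1)
    tr = simulate_trial(vi_joint, pert, seed=0, noise_on=False)
    sp = compensation_spectrum(tr, spec)
    an = frequency_response(vi_joint, [0.1])
    assert abs(sp.gain[0] - an.gain[0]) / an.gain[0] < 0.01
    assert abs(sp.phase_rad[0] - an.phase_rad[0]) < 0.01


def test_full_design_matches_analytic_within_1pct(vi_joint):
    """Time-domain spectra agree with the analytic transfer function at all
    12 design frequencies (long ramp-up so start-up transients have decayed
    before the analysis window)."""
    spec = PerturbationSpec(ramp_up_s=30.0)
    pert = generate_perturbation(spec, 3)
    tr = simulate_trial(vi_joint, pert, seed=0, noise_on=False)
    sp = compensation_spectrum(tr, spec)
    an = frequency_response(vi_joint, FREQS)
    assert np.max(np.abs(sp.gain - an.gain) / an.gain) < 0.01
    assert np.max(np.abs(sp.phase_rad - an.phase_rad)) < 0.01


@pytest.mark.parametrize("condition", [VISUOINERTIAL, VISUAL])
def test_low_pass_gain(condition):
    sp = response_for_config(ModelConfig(condition=condition), FREQS)
    assert sp.gain[-1] < sp.gain[0]
    assert np.all(np.diff(sp.gain) <= 1e-12)      # monotone low-pass


def test_huge_control_cost_gives_no_compensation():
    sp = response_for_config(ModelConfig().with_theta(r_exponent=10.0), FREQS)
    assert np.all(sp.gain < 1e-3)


def test_visuoinertial_phase_closer_to_ideal_than_visual(vi_joint, visual_joint):
    """Above 0.1 Hz the visual-only loop lags strictly more (its unwrapped
    phase is farther below -pi) while gains barely differ."""
    g_vi, ph_vi = unwrapped_response(vi_joint, FREQS)
    g_v, ph_v = unwrapped_response(visual_joint, FREQS)
    assert np.all(ph_v[1:] < ph_vi[1:])
    assert np.all(np.abs(ph_v[1:] + np.pi) > np.abs(ph_vi[1:] + np.pi))


def test_visual_delay_sweep_moves_visual_phase_not_gain():
    """Halving/removing the visual delay mostly shifts the visual-condition
    phase; visuoinertial phase and both conditions' gains move little."""
    out = {}
    for cond in (VISUAL, VISUOINERTIAL):
        for d in (0, 7):
            cfg = ModelConfig(condition=cond, visual_delay_steps=d)
            out[cond, d] = unwrapped_response(make_joint(cfg), FREQS)
    dphase_vis = np.abs(out[VISUAL, 0][1] - out[VISUAL, 7][1])
    dphase_vi = np.abs(out[VISUOINERTIAL, 0][1] - out[VISUOINERTIAL, 7][1])
    dgain = max(np.max(np.abs(out[c, 0][0] - out[c, 7][0]))
                for c in (VISUAL, VISUOINERTIAL))
    assert dphase_vis[-1] > 1.0          # ~7 steps of lag at 1.93 Hz
    assert np.max(dphase_vi) < 0.5       # vestibular channel offsets it
    assert dgain < 0.05                  # "impact on compensatory gain is minimal"


def test_variant_without_neuromuscular_filter():
    """Removing the neuromuscular low-pass barely changes gain but moves
    the phase toward -pi (less lag)."""
    g_full, ph_full = unwrapped_response(make_joint(ModelConfig()), FREQS)
    g_nonm, ph_nonm = unwrapped_response(
        make_joint(ModelConfig(neuromuscular_filter=False)), FREQS)
    assert np.max(np.abs(g_nonm - g_full)) < 0.01
    assert np.all(np.abs(ph_nonm + np.pi) < np.abs(ph_full + np.pi))


def test_sensory_noise_monotonicity():
    """Lowering sensory noise never lowers the compensatory gain."""
    sp_lo = response_for_config(ModelConfig().with_theta(sigma_s=0.2), FREQS)
    sp_hi = response_for_config(ModelConfig().with_theta(sigma_s=20.0), FREQS)
    assert np.all(sp_lo.gain >= sp_hi.gain - 1e-12)


def test_control_cost_monotonicity():
    """Raising the control cost never raises any compensatory gain."""
    sp_cheap = response_for_config(ModelConfig().with_theta(r_exponent=-2.0), FREQS)
    sp_dear = response_for_config(ModelConfig().with_theta(r_exponent=-0.5), FREQS)
    assert np.all(sp_dear.gain <= sp_cheap.gain + 1e-12)


def test_trial_averaged_spectra_converge_to_noise_free(vi_joint):
    """With all noise magnitudes scaled down, the mean spectrum over
    repeated stochastic trials approaches the analytic (noise-free) one."""
    cfg = ModelConfig(noise=NoiseSpec(sigma_s=1e-3, sigma_pv=0.005e-3,
                                      sigma_vv=0.01e-3, sigma_av=0.1e-3,
                                      sigma_pw=0.1e-3, sigma_vw=1e-3,
                                      sigma_fw=1e-5, sigma_m=1e-5,
                                      sigma_xi=1e-5))
    # keep the estimator of the noise-free reference identical: gains from
    # the *same* config, noise only injected (or not) at simulation time
    joint = make_joint(cfg)
    spec = PerturbationSpec(ramp_up_s=30.0)
    an = frequency_response(joint, FREQS)
    gains = []
    for k in range(5):
        tr = simulate_trial(joint, generate_perturbation(spec, 40 + k),
                            seed=k, noise_on=True)
        gains.append(compensation_spectrum(tr, spec).gain)
    mean_gain = np.mean(gains, axis=0)
    assert np.max(np.abs(mean_gain - an.gain) / an.gain) < 0.02


def test_above_nyquist_rejected(vi_joint):
    with pytest.raises(ValueError):
        frequency_response(vi_joint, [31.0])


def test_unstable_joint_refused(vi_joint, default_spec):
    import copy
    bad = copy.copy(vi_joint)
    bad.F = 1.01 * np.eye(vi_joint.F.shape[0])
    pert = generate_perturbation(default_spec, 1)
    with pytest.raises(RuntimeError):
        simulate_trial(bad, pert, seed=0)
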