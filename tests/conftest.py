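"""Shared fixtures: default model joints and a synthetic participant.

The synthetic participant is generated once per session at the study's
generating parameters theta* = (sigma_s=1.0, re_vis=-1.0, re_visuo=-1.5)
with full-length 145-s trials: the inverse-control objective needs the full
120-s analysis window to average out the inference filter's lock-on
transient, so fit tests scale down trial counts and optimizer budgets
rather than trial length.
"""

import numpy as np
import pytest

from steerlqg import (ModelConfig, PerturbationSpec, VISUAL, VISUOINERTIAL,
                      build_joint, build_model, generate_perturbation,
                      simulate_trial, solve_gains)

TRUE_THETA = {"sigma_s": 1.0, "re_vis": -1.0, "re_visuo": -1.5}


def make_joint(cfg: ModelConfig):
    ss = build_model(cfg)
    return build_joint(ss, solve_gains(ss))


@pytest.fixture(scope="session")
def default_spec():
    return PerturbationSpec()


@pytest.fixture(scope="session")
def vi_joint():
    return make_joint(ModelConfig(condition=VISUOINERTIAL))


@pytest.fixture(scope="session")
def visual_joint():
    return make_joint(ModelConfig(condition=VISUAL))


@pytest.fixture(scope="session")
def participant_trials(default_spec):
    """10 noisy full-length trials per condition at theta*."""
    jv = make_joint(ModelConfig(condition=VISUAL).with_theta(
        sigma_s=TRUE_THETA["sigma_s"], r_exponent=TRUE_THETA["re_vis"]))
    jvi = make_joint(ModelConfig(condition=VISUOINERTIAL).with_theta(
        sigma_s=TRUE_THETA["sigma_s"], r_exponent=TRUE_THETA["re_visuo"]))
    vis = [simulate_trial(jv, generate_perturbation(default_spec, 1000 + k),
                          seed=1 + k, noise_on=True) for k in range(10)]
    vio = [simulate_trial(jvi, generate_perturbation(default_spec, 2000 + k),
                          seed=101 + k, noise_on=True) for k in range(10)]
    return vis, vio
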