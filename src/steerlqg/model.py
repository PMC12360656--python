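"""Discrete-time LQG model of perturbed steering with delayed multisensory
feedback.

The plant couples vehicle kinematics to a steering wheel driven through a
second-order neuromuscular low-pass (two cascaded first-order stages, time
constant ``tau_nm``).  The vehicle is velocity-controlled: the wheel angle
maps linearly (``lambda_gain`` (m/s)/deg) onto vehicle velocity, and the
experimenter's perturbation adds to that velocity.  Vehicle acceleration is
carried as an explicit state (finite difference of velocity) because the
vestibular system senses acceleration.

Core state order: ``[p_v, v_v, a_v, p_w, v_w, f_w, g_w]`` — vehicle
position/velocity/acceleration, wheel angle/velocity, then the two
neuromuscular stages (force and its driving stage).  Sensory channels
observe these states with channel-specific delays (visual: position and
velocity of the vehicle; vestibular: vehicle acceleration, visuoinertial
condition only; proprioceptive: wheel angle, velocity and force).  Delays
are realized exactly by full-state augmentation: the state is stacked with
its previous ``max delay`` copies and each channel reads its delayed copy.

Estimator and controller are the steady-state LQG pair: a filtering-form
Kalman filter and an infinite-horizon LQR feedback law ``u = -L x_hat``,
both obtained from discrete algebraic Riccati equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import List, Tuple

import numpy as np
import scipy.linalg

__all__ = [
    "NoiseSpec", "CostSpec", "ModelConfig", "StateSpace", "Gains",
    "JointSystem", "build_model", "solve_gains", "build_joint",
    "VISUAL", "VISUOINERTIAL",
]

VISUAL = "visual"
VISUOINERTIAL = "visuoinertial"

#: Per-step variance of the observer's white-noise stand-in for the
#: sum-of-sines perturbation: 12 components x (0.1 m/s)^2 / 2.
DEFAULT_PERTURBATION_VAR = 12 * 0.1 ** 2 / 2.0


class SynthesisError(RuntimeError):
    """A Riccati equation failed to produce a stabilizing solution."""


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes (all additive Gaussian).

    ``sigma_s`` scales every sensory channel jointly without changing their
    relative magnitudes; it is one of the model's free parameters.  The
    per-channel bases are fixed: visual position 0.005 m and vestibular
    acceleration 0.10 m/s^2 (the plausible-magnitude anchors), visual
    velocity 0.01 m/s, wheel angle 0.1 deg, wheel velocity 1 deg/s, wheel
    force 1 force-unit.  ``sigma_m`` is motor noise entering the second
    neuromuscular stage; ``sigma_xi`` perturbs the estimator's one-step
    state prediction.  Force-unit magnitudes (``sigma_fw``, ``sigma_m``) are
    about 1% of a typical control command, which is O(1) in the chosen
    force units (see ``ModelConfig.m_wheel``).
    """

    sigma_s: float = 1.0
    sigma_pv: float = 0.005
    sigma_vv: float = 0.01
    sigma_av: float = 0.10
    sigma_pw: float = 0.1
    sigma_vw: float = 1.0
    sigma_fw: float = 0.01
    sigma_m: float = 0.01
    sigma_xi: float = 0.01

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CostSpec:
    """Quadratic cost: vehicle position deviation (weight 1) against control
    magnitude weighted ``r = 10**r_exponent``."""

    position_weight: float = 1.0
    r_exponent: float = -1.0

    def __post_init__(self) -> None:
        if self.position_weight <= 0:
            raise ValueError("position_weight must be > 0")

    @property
    def r(self) -> float:
        return 10.0 ** self.r_exponent


@dataclass(frozen=True)
class ModelConfig:
    """All fixed and free parameters of the steering model."""

    dt: float = 1.0 / 60.0                 # s, one 60 Hz frame (~17 ms)
    lambda_gain: float = 0.008             # (m/s) per degree of wheel angle
    tau_nm: float = 0.04                   # s, neuromuscular time constant
    #: Wheel angular acceleration (deg/s^2) produced by one unit of force.
    #: The force unit is chosen so that control commands are O(1), which
    #: places the control-cost exponent regime where compensation turns on
    #: around re ~ -1 (m is not identifiable jointly with the control
    #: scale, so this is a unit convention, not a physical claim).
    m_wheel: float = 400.0
    visual_delay_steps: int = 7            # ~117 ms
    vestibular_delay_steps: int = 1        # ~17 ms
    proprio_delay_steps: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    cost: CostSpec = field(default_factory=CostSpec)
    condition: str = VISUOINERTIAL
    neuromuscular_filter: bool = True      # False: control acts on wheel force directly
    perturbation_var: float = DEFAULT_PERTURBATION_VAR

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tau_nm <= 0:
            raise ValueError("dt and tau_nm must be positive")
        for name in ("visual_delay_steps", "vestibular_delay_steps", "proprio_delay_steps"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.condition not in (VISUAL, VISUOINERTIAL):
            raise ValueError(f"condition must be {VISUAL!r} or {VISUOINERTIAL!r}")
        if self.perturbation_var < 0:
            raise ValueError("perturbation_var must be >= 0")

    @property
    def max_delay(self) -> int:
        return max(self.visual_delay_steps, self.vestibular_delay_steps,
                   self.proprio_delay_steps)

    def with_theta(self, sigma_s: float | None = None,
                   r_exponent: float | None = None,
                   condition: str | None = None) -> "ModelConfig":
        """Copy with the free parameters (and optionally condition) replaced."""
        noise = self.noise if sigma_s is None else replace(self.noise, sigma_s=sigma_s)
        cost = self.cost if r_exponent is None else replace(self.cost, r_exponent=r_exponent)
        return replace(self, noise=noise, cost=cost,
                       condition=self.condition if condition is None else condition)


@dataclass
class StateSpace:
    """Delay-augmented linear system with observation and cost matrices."""

    A: np.ndarray
    B: np.ndarray
    V: np.ndarray          # process-noise map (motor noise)
    Veps: np.ndarray       # perturbation input map
    H: np.ndarray
    G: np.ndarray          # observation-noise map (diagonal)
    Q: np.ndarray
    R: np.ndarray
    labels: List[str]      # core-state labels (pre-augmentation)
    core_dim: int
    n_delay: int           # number of stacked past copies
    obs_labels: List[str]
    config: ModelConfig

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def idx(self, label: str, delay: int = 0) -> int:
        """Index of a (possibly delayed) core state in the augmented vector."""
        return delay * self.core_dim + self.labels.index(label)


@dataclass
class Gains:
    """Steady-state Kalman gain K (filtering form) and LQR feedback gain L."""

    K: np.ndarray
    L: np.ndarray


def _core_matrices(cfg: ModelConfig):
    dt, lam, tau, m = cfg.dt, cfg.lambda_gain, cfg.tau_nm, cfg.m_wheel
    if cfg.neuromuscular_filter:
        labels = ["p_v", "v_v", "a_v", "p_w", "v_w", "f_w", "g_w"]
        nc = 7
        A = np.zeros((nc, nc))
        A[0, 0], A[0, 1] = 1.0, dt                       # p_v' = p_v + dt v_v
        A[1, 3], A[1, 4] = lam, lam * dt                 # v_v' = lam (p_w + dt v_w) + eps
        A[2, 1], A[2, 3], A[2, 4] = -1.0 / dt, lam / dt, lam   # a_v' = (v_v' - v_v)/dt
        A[3, 3], A[3, 4] = 1.0, dt                       # p_w' = p_w + dt v_w
        A[4, 4], A[4, 5] = 1.0, dt * m                   # v_w' = v_w + dt m f_w
        A[5, 5], A[5, 6] = 1.0 - dt / tau, dt / tau      # first filter stage
        A[6, 6] = 1.0 - dt / tau                         # second filter stage
        B = np.zeros((nc, 1)); B[6, 0] = dt / tau
        V = np.zeros((nc, 1)); V[6, 0] = dt / tau * cfg.noise.sigma_m
    else:
        # Variant without the neuromuscular low-pass: control is wheel force.
        labels = ["p_v", "v_v", "a_v", "p_w", "v_w"]
        nc = 5
        A = np.zeros((nc, nc))
        A[0, 0], A[0, 1] = 1.0, dt
        A[1, 3], A[1, 4] = lam, lam * dt
        A[2, 1], A[2, 3], A[2, 4] = -1.0 / dt, lam / dt, lam
        A[3, 3], A[3, 4] = 1.0, dt
        A[4, 4] = 1.0
        B = np.zeros((nc, 1)); B[4, 0] = dt * m
        V = np.zeros((nc, 1)); V[4, 0] = dt * m * cfg.noise.sigma_m
    Veps = np.zeros((nc, 1))
    Veps[labels.index("v_v"), 0] = 1.0
    Veps[labels.index("a_v"), 0] = 1.0 / dt
    return labels, A, B, V, Veps


def _observation_channels(cfg: ModelConfig) -> List[Tuple[str, float, int]]:
    ns = cfg.noise
    ch = [("p_v", ns.sigma_pv, cfg.visual_delay_steps),
          ("v_v", ns.sigma_vv, cfg.visual_delay_steps)]
    if cfg.condition == VISUOINERTIAL:
        ch.append(("a_v", ns.sigma_av, cfg.vestibular_delay_steps))
    ch += [("p_w", ns.sigma_pw, cfg.proprio_delay_steps),
           ("v_w", ns.sigma_vw, cfg.proprio_delay_steps)]
    if cfg.neuromuscular_filter:
        ch.append(("f_w", ns.sigma_fw, cfg.proprio_delay_steps))
    return ch


def build_model(cfg: ModelConfig) -> StateSpace:
    """Assemble the delay-augmented state space, observations and costs."""
    labels, Ac, Bc, Vc, Vec = _core_matrices(cfg)
    nc = len(labels)
    d = cfg.max_delay
    n = nc * (d + 1)

    A = np.zeros((n, n))
    A[:nc, :nc] = Ac
    for k in range(1, d + 1):          # block k holds the state from k steps ago
        A[k * nc:(k + 1) * nc, (k - 1) * nc:k * nc] = np.eye(nc)
    B = np.zeros((n, Bc.shape[1])); B[:nc] = Bc
    V = np.zeros((n, Vc.shape[1])); V[:nc] = Vc
    Veps = np.zeros((n, Vec.shape[1])); Veps[:nc] = Vec

    channels = _observation_channels(cfg)
    H = np.zeros((len(channels), n))
    g = np.empty(len(channels))
    obs_labels = []
    for row, (label, sigma, delay) in enumerate(channels):
        H[row, delay * nc + labels.index(label)] = 1.0
        g[row] = cfg.noise.sigma_s * sigma
        obs_labels.append(f"{label}[-{delay}]")
    G = np.diag(g)

    Q = np.zeros((n, n))
    Q[0, 0] = cfg.cost.position_weight
    R = np.array([[cfg.cost.r]])
    return StateSpace(A=A, B=B, V=V, Veps=Veps, H=H, G=G, Q=Q, R=R,
                      labels=labels, core_dim=nc, n_delay=d,
                      obs_labels=obs_labels, config=cfg)


def _prediction_noise_cov(ss: StateSpace) -> np.ndarray:
    Xi = np.zeros((ss.n, ss.n))
    s2 = ss.config.noise.sigma_xi ** 2
    for i in range(ss.core_dim):
        Xi[i, i] = s2
    return Xi


def process_noise_cov(ss: StateSpace) -> np.ndarray:
    """Process covariance seen by the filter: motor noise, the white-noise
    model of the perturbation, and estimator prediction noise."""
    return (ss.V @ ss.V.T
            + ss.config.perturbation_var * ss.Veps @ ss.Veps.T
            + _prediction_noise_cov(ss))


def solve_dare(A: np.ndarray, B: np.ndarray, Q: np.ndarray, R: np.ndarray,
               label: str = "Riccati") -> np.ndarray:
    """Stabilizing solution of the discrete algebraic Riccati equation.

    Tries scipy's QZ-based solver first; on the ill-conditioned reorderings
    that occasionally occur for strongly scaled noise models, falls back to
    the structured doubling algorithm (quadratically convergent fixed
    point), verified against the Riccati residual.
    """
    try:
        return scipy.linalg.solve_discrete_are(A, B, Q, R)
    except Exception:
        pass
    # Structured doubling: Ak -> A (I + G H)^-1 A, with G = B R^-1 B^T.
    n = A.shape[0]
    Ak = A.copy()
    Gk = B @ np.linalg.solve(R, B.T)
    Hk = Q.copy()
    for _ in range(120):
        IGH = np.eye(n) + Gk @ Hk
        W1 = np.linalg.solve(IGH, Ak)          # (I+GH)^-1 A
        W2 = np.linalg.solve(IGH.T, Hk @ Ak)   # (I+GH)^-T H A  (H symmetric)
        A_next = Ak @ W1
        G_next = Gk + Ak @ np.linalg.solve(IGH, Gk @ Ak.T)
        H_next = Hk + W2.T @ Ak
        step = np.max(np.abs(H_next - Hk)) / max(1.0, np.max(np.abs(H_next)))
        Ak, Gk, Hk = A_next, 0.5 * (G_next + G_next.T), 0.5 * (H_next + H_next.T)
        if step < 1e-14:
            break
    X = Hk
    # residual check: X = A^T X A - A^T X B (R + B^T X B)^-1 B^T X A + Q
    XB = X @ B
    res = A.T @ (X - XB @ np.linalg.solve(R + B.T @ XB, XB.T)) @ A + Q - X
    if not np.all(np.isfinite(X)) or np.max(np.abs(res)) > 1e-6 * max(1.0, np.max(np.abs(X))):
        raise SynthesisError(f"{label} equation failed to converge")
    return X


def solve_gains(ss: StateSpace, cfg: ModelConfig | None = None) -> Gains:
    """Steady-state LQR feedback gain and filtering-form Kalman gain.

    ``L`` solves the infinite-horizon discrete LQR problem for
    ``(A, B, Q, R)``; ``K`` is the steady-state filtering-form gain for
    ``(A, H)`` with the process covariance of :func:`process_noise_cov` and
    observation covariance ``G G^T``.
    """
    cfg = cfg or ss.config
    S = solve_dare(ss.A, ss.B, ss.Q, ss.R, label="control Riccati")
    L = np.linalg.solve(ss.R + ss.B.T @ S @ ss.B, ss.B.T @ S @ ss.A)

    W = process_noise_cov(ss)
    Robs = ss.G @ ss.G.T
    P = solve_dare(ss.A.T, ss.H.T, W, Robs, label="filter Riccati")
    K = np.linalg.solve(ss.H @ P @ ss.H.T + Robs, ss.H @ P.T).T
    return Gains(K=K, L=L)


@dataclass
class JointSystem:
    """Stacked dynamics of the true state x and the estimate x_hat.

    Deterministic part ``F = [[A, -B L], [K H A, A - B L - K H A]]`` for the
    filtering-form estimator under the policy ``u = -L x_hat``; the
    perturbation and each noise source enter through dedicated input maps.
    """

    F: np.ndarray
    E_pert: np.ndarray     # perturbation velocity (scalar input)
    E_eta: np.ndarray      # motor/process noise (standard normal input)
    E_omega: np.ndarray    # observation noise (standard normal input)
    E_xi: np.ndarray       # estimator prediction noise (standard normal, core states)
    ss: StateSpace
    gains: Gains

    @property
    def n(self) -> int:
        return self.ss.n

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.F))))

    # -- output selectors (rows acting on the stacked [x; x_hat] vector) ---
    def row_car_pos(self) -> np.ndarray:
        r = np.zeros(2 * self.n); r[self.ss.idx("p_v")] = 1.0
        return r

    def row_wheel(self) -> np.ndarray:
        r = np.zeros(2 * self.n); r[self.ss.idx("p_w")] = 1.0
        return r

    def row_controlled_vel(self) -> np.ndarray:
        """Wheel-commanded vehicle velocity lambda*(p_w + dt*v_w) of the
        true state — the compensatory signal analyzed against the
        perturbation."""
        cfg = self.ss.config
        r = np.zeros(2 * self.n)
        r[self.ss.idx("p_w")] = cfg.lambda_gain
        r[self.ss.idx("v_w")] = cfg.lambda_gain * cfg.dt
        return r

    def row_control(self) -> np.ndarray:
        r = np.zeros(2 * self.n)
        r[self.n:] = -self.gains.L[0]
        return r


def build_joint(ss: StateSpace, gains: Gains) -> JointSystem:
    """Assemble the joint [x; x_hat] system for the synthesized gains."""
    A, B, H = ss.A, ss.B, ss.H
    K, L = gains.K, gains.L
    n = ss.n
    if K.shape != (n, H.shape[0]) or L.shape != (B.shape[1], n):
        raise ValueError("gain dimensions do not match the state space")
    BL = B @ L
    KH = K @ H
    F = np.block([[A, -BL],
                  [KH @ A, A - BL - KH @ A]])
    E_pert = np.vstack([ss.Veps, KH @ ss.Veps])
    E_eta = np.vstack([ss.V, KH @ ss.V])
    E_omega = np.vstack([np.zeros((n, K.shape[1])), K @ ss.G])
    Sxi = np.zeros((n, ss.core_dim))
    for i in range(ss.core_dim):
        Sxi[i, i] = ss.config.noise.sigma_xi
    E_xi = np.vstack([np.zeros((n, ss.core_dim)), (np.eye(n) - KH) @ Sxi])
    return JointSystem(F=F, E_pert=E_pert, E_eta=E_eta, E_omega=E_omega,
                       E_xi=E_xi, ss=ss, gains=gains)
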