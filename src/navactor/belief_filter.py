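"""The agent's probabilistic internal representation and its EKF updates.

The belief is a joint Gaussian over pose (x, y, theta) and the allocentric
coordinates of all L landmarks/goals: mean of length 3 + 2L and full joint
covariance with pose, map, and pose-map blocks. Landmarks enter the belief
only when first observed (explicit initialization via the inverse observation
model, never a large-variance prior), and remembered locations slowly lose
precision through a random-walk representation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .env_model import (
    ControlInput,
    MotorNoise,
    Observation,
    ObservationNoise,
    _noise_cov_from_range_bearing,
    motor_noise_cov,
    wrap_angle,
)

__all__ = [
    "BeliefState",
    "RepresentationNoise",
    "ekf_predict",
    "ekf_correct",
    "initialize_landmark",
    "decay_representation",
    "pose_uncertainty",
    "map_uncertainty",
]

# Covariances are re-symmetrized after every update; an eigenvalue below this
# signals a genuinely broken update and raises instead of silently projecting.
_PSD_TOL = -1e-8


@dataclass(frozen=True)
class RepresentationNoise:
    """Memory decay of the internal map.

    Remembered landmark/goal coordinates follow a 2-D random walk with
    variance growth rate ``delta_xy`` (m^2/s) per coordinate. The belief
    covariance always grows accordingly; when ``mean_drift`` is on (the
    default) and a random stream is supplied, the remembered *means* take the
    matching random-walk steps as well — the physical world stays static,
    only the memory drifts.
    """

    delta_xy: float = 0.0
    mean_drift: bool = True

    def __post_init__(self):
        if self.delta_xy < 0:
            raise ValueError("delta_xy must be non-negative")


@dataclass(frozen=True)
class BeliefState:
    """Gaussian belief (mu, Sigma) over pose and map.

    ``mu`` has layout (x, y, theta, m1x, m1y, ..., mLx, mLy), matching the
    world state. Uninitialized landmarks carry a sentinel mean of 0 with zero
    covariance and are flagged False in ``known_mask``; they are excluded
    from correction until initialized.
    """

    mu: np.ndarray
    sigma: np.ndarray
    known_mask: np.ndarray

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float).copy()
        sigma = np.asarray(self.sigma, dtype=float)
        mask = np.asarray(self.known_mask, dtype=bool).copy()
        n = mu.size
        if sigma.shape != (n, n):
            raise ValueError("sigma shape does not match mu")
        if (n - 3) % 2 or mask.size != (n - 3) // 2:
            raise ValueError("known_mask length must equal the number of landmarks")
        sigma = 0.5 * (sigma + sigma.T)
        mu[2] = wrap_angle(mu[2])
        _check_psd(sigma)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "known_mask", mask)

    @property
    def n_landmarks(self) -> int:
        return (self.mu.size - 3) // 2

    @property
    def pose_mean(self) -> np.ndarray:
        return self.mu[:3]

    def landmark_mean(self, lid: int) -> np.ndarray:
        return self.mu[3 + 2 * lid : 5 + 2 * lid]

    def landmark_cov(self, lid: int) -> np.ndarray:
        i = 3 + 2 * lid
        return self.sigma[i : i + 2, i : i + 2]

    @classmethod
    def initial(
        cls, pose: np.ndarray, n_landmarks: int, pose_cov: np.ndarray | float = 1e-4
    ) -> "BeliefState":
        """Fresh belief: known start pose (small isotropic uncertainty), empty map."""
        n = 3 + 2 * n_landmarks
        mu = np.zeros(n)
        mu[:3] = pose
        sigma = np.zeros((n, n))
        sigma[:3, :3] = np.eye(3) * pose_cov if np.isscalar(pose_cov) else pose_cov
        return cls(mu, sigma, np.zeros(n_landmarks, dtype=bool))


def _check_psd(sigma: np.ndarray) -> None:
    if sigma.size == 0:
        return
    w = np.linalg.eigvalsh(sigma)
    if w[0] < _PSD_TOL:
        raise np.linalg.LinAlgError(
            f"belief covariance lost positive semidefiniteness (min eig {w[0]:.3e})"
        )


def _symmetrize(sigma: np.ndarray) -> np.ndarray:
    return 0.5 * (sigma + sigma.T)


def predict_mean_cov(
    mu: np.ndarray,
    sigma: np.ndarray,
    known_mask: np.ndarray,
    u: ControlInput,
    dt: float,
    alpha: MotorNoise,
    rep: RepresentationNoise,
) -> tuple[np.ndarray, np.ndarray]:
    """One EKF prediction step on raw arrays (shared with the planner).

    Mean moves through the unicycle dynamics; covariance through the
    linearization Sigma' = A Sigma A^T + G (Q/dt) G^T, with the dt-scaled
    signal-dependent motor noise, plus dt * delta_xy on every initialized
    landmark's diagonal block (memory decay).
    """
    theta = mu[2]
    c, s = np.cos(theta), np.sin(theta)
    mu_new = mu.copy()
    mu_new[0] += c * u.v * dt
    mu_new[1] += s * u.v * dt
    mu_new[2] = wrap_angle(mu_new[2] + u.w * dt)

    n = mu.size
    a_mat = np.eye(n)
    a_mat[0, 2] = -s * u.v * dt
    a_mat[1, 2] = c * u.v * dt
    g = np.zeros((n, 2))
    g[0, 0] = c * dt
    g[1, 0] = s * dt
    g[2, 1] = dt

    q_step = motor_noise_cov(u, alpha) / dt
    sigma_new = a_mat @ sigma @ a_mat.T + g @ q_step @ g.T
    if rep.delta_xy > 0:
        for lid in np.flatnonzero(known_mask):
            i = 3 + 2 * lid
            sigma_new[i, i] += rep.delta_xy * dt
            sigma_new[i + 1, i + 1] += rep.delta_xy * dt
    return mu_new, _symmetrize(sigma_new)


def ekf_predict(
    b: BeliefState,
    u: ControlInput,
    dt: float,
    alpha: MotorNoise,
    rep: RepresentationNoise,
    rng: np.random.Generator | None = None,
) -> BeliefState:
    """EKF prediction step: propagate mean and covariance through the dynamics.

    With ``rng`` given and ``rep.mean_drift`` on, the remembered landmark
    means take their random-walk step (variance delta_xy * dt per
    coordinate) alongside the matching covariance growth; without ``rng``
    the update is deterministic.
    """
    mu, sigma = predict_mean_cov(b.mu, b.sigma, b.known_mask, u, dt, alpha, rep)
    mu = _drift_means(mu, b.known_mask, rep, dt, rng)
    return replace(b, mu=mu, sigma=sigma)


def _drift_means(mu, known_mask, rep, duration, rng):
    if rng is None or not rep.mean_drift or rep.delta_xy <= 0 or duration <= 0:
        return mu
    mu = mu.copy()
    sd = np.sqrt(rep.delta_xy * duration)
    for lid in np.flatnonzero(known_mask):
        i = 3 + 2 * lid
        mu[i : i + 2] += rng.standard_normal(2) * sd
    return mu


def observation_jacobian(mu: np.ndarray, lids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stacked range/bearing Jacobian H (2k x n) and predicted h(mu) (2k,).

    Rows come in (range, bearing) pairs per landmark, in the order of ``lids``.
    """
    n = mu.size
    h_mat = np.zeros((2 * len(lids), n))
    pred = np.zeros(2 * len(lids))
    for k, lid in enumerate(lids):
        i = 3 + 2 * lid
        dx = mu[i] - mu[0]
        dy = mu[i + 1] - mu[1]
        q = dx * dx + dy * dy
        r = np.sqrt(q)
        if r == 0.0:
            raise ValueError("landmark coincides with believed position")
        pred[2 * k] = r
        pred[2 * k + 1] = wrap_angle(np.arctan2(dy, dx) - mu[2])
        h_mat[2 * k, [0, 1, i, i + 1]] = [-dx / r, -dy / r, dx / r, dy / r]
        h_mat[2 * k + 1, [0, 1, 2, i, i + 1]] = [dy / q, -dx / q, -1.0, -dy / q, dx / q]
    return h_mat, pred


def stacked_observation_cov(
    b_mu: np.ndarray, lids: np.ndarray, eps: ObservationNoise
) -> np.ndarray:
    """Block-diagonal R for a batch of landmarks, evaluated at the belief mean."""
    blocks = []
    for lid in lids:
        i = 3 + 2 * lid
        dx = b_mu[i] - b_mu[0]
        dy = b_mu[i + 1] - b_mu[1]
        r = np.hypot(dx, dy)
        bearing = wrap_angle(np.arctan2(dy, dx) - b_mu[2])
        blocks.append(_noise_cov_from_range_bearing(r, bearing, eps))
    k = len(blocks)
    out = np.zeros((2 * k, 2 * k))
    for j, blk in enumerate(blocks):
        out[2 * j : 2 * j + 2, 2 * j : 2 * j + 2] = blk
    return out


def ekf_correct(
    b: BeliefState, observations: list[Observation], eps: ObservationNoise
) -> BeliefState:
    """EKF correction with a batch of landmark observations.

    All observations are stacked into one update with block-diagonal R
    (evaluated at the predicted mean, like H). Bearing innovations are wrapped
    to (-pi, pi] before the Kalman gain is applied; the covariance is
    re-symmetrized afterwards. Observing an uninitialized landmark is an
    error — route it through :func:`initialize_landmark` first.
    """
    if not observations:
        return b
    lids = np.array([o.landmark_id for o in observations])
    unknown = [int(l) for l in lids if not b.known_mask[l]]
    if unknown:
        raise KeyError(
            f"landmarks {unknown} not initialized; call initialize_landmark first"
        )
    h_mat, pred = observation_jacobian(b.mu, lids)
    r_mat = stacked_observation_cov(b.mu, lids, eps)
    z = np.concatenate([o.as_array() for o in observations])
    innovation = z - pred
    innovation[1::2] = wrap_angle(innovation[1::2])

    s_mat = h_mat @ b.sigma @ h_mat.T + r_mat
    k_gain = np.linalg.solve(s_mat, h_mat @ b.sigma).T
    mu = b.mu + k_gain @ innovation
    mu[2] = wrap_angle(mu[2])
    sigma = _symmetrize((np.eye(b.mu.size) - k_gain @ h_mat) @ b.sigma)
    _check_psd(sigma)
    return replace(b, mu=mu, sigma=sigma)


def initialize_landmark(
    b: BeliefState, obs: Observation, eps: ObservationNoise
) -> BeliefState:
    """Enter a landmark into the belief from its first observation.

    The landmark mean is the inverse observation model applied at the believed
    pose; its covariance and cross-covariances follow from first-order
    propagation of the pose uncertainty and the observation noise R through
    the inverse-model Jacobians.
    """
    lid = obs.landmark_id
    if b.known_mask[lid]:
        raise ValueError(f"landmark {lid} already initialized")
    x, y, theta = b.mu[:3]
    ang = theta + obs.bearing
    c, s = np.cos(ang), np.sin(ang)
    m = np.array([x + obs.range * c, y + obs.range * s])

    # Jacobians of m = pose_xy + r * [cos(theta+psi), sin(theta+psi)]
    j_pose = np.array([[1.0, 0.0, -obs.range * s], [0.0, 1.0, obs.range * c]])
    j_obs = np.array([[c, -obs.range * s], [s, obs.range * c]])
    r_mat = _noise_cov_from_range_bearing(obs.range, obs.bearing, eps)

    i = 3 + 2 * lid
    mu = b.mu.copy()
    mu[i : i + 2] = m
    sigma = b.sigma.copy()
    cross = j_pose @ b.sigma[:3, :]  # (2, n) cross-covariance with the full state
    sigma[i : i + 2, :] = cross
    sigma[:, i : i + 2] = cross.T
    sigma[i : i + 2, i : i + 2] = (
        j_pose @ b.sigma[:3, :3] @ j_pose.T + j_obs @ r_mat @ j_obs.T
    )
    mask = b.known_mask.copy()
    mask[lid] = True
    return BeliefState(mu, _symmetrize(sigma), mask)


def decay_representation(
    b: BeliefState,
    duration: float,
    rep: RepresentationNoise,
    rng: np.random.Generator | None = None,
) -> BeliefState:
    """Grow map uncertainty by duration * delta_xy per stored coordinate.

    Models memory decay of remembered landmark/goal locations during waiting
    or disorientation; the physical world is static. With ``rng`` supplied
    and ``rep.mean_drift`` on, the remembered means take the matching
    random-walk step; otherwise only the covariance grows.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if duration == 0 or rep.delta_xy == 0:
        return b
    sigma = b.sigma.copy()
    for lid in np.flatnonzero(b.known_mask):
        i = 3 + 2 * lid
        sigma[i, i] += rep.delta_xy * duration
        sigma[i + 1, i + 1] += rep.delta_xy * duration
    mu = _drift_means(b.mu, b.known_mask, rep, duration, rng)
    return replace(b, mu=mu, sigma=sigma)


def pose_uncertainty(b: BeliefState) -> float:
    """Trace of the pose covariance block."""
    return float(np.trace(b.sigma[:3, :3]))


def map_uncertainty(b: BeliefState) -> float:
    """Trace of the map covariance block."""
    return float(np.trace(b.sigma[3:, 3:]))
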