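"""Ground-truth world model: unicycle dynamics and range/bearing landmark observations.

The agent lives in an allocentric, right-handed plane (x east, y north, metres;
angles in radians, counterclockwise positive, wrapped to (-pi, pi]). The world
state is the agent pose plus the fixed coordinates of all landmarks and goals.
Motor commands are linear and angular velocity, corrupted by signal-dependent
Gaussian noise; observations are egocentric range and bearing of landmarks
inside the field of view, corrupted by state-dependent Gaussian noise whose
magnitude grows with distance and retinal eccentricity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "WorldState",
    "ControlInput",
    "MotorNoise",
    "ObservationNoise",
    "Observation",
    "FieldOfView",
    "wrap_angle",
    "step_dynamics",
    "motor_noise_cov",
    "sample_noisy_control",
    "observe_landmark",
    "observation_noise_cov",
    "visible",
    "sample_observations",
]


def wrap_angle(theta):
    """Wrap an angle (scalar or array) to the interval (-pi, pi]."""
    wrapped = -((-np.asarray(theta) + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if np.ndim(theta) else float(wrapped)


@dataclass(frozen=True)
class WorldState:
    """True agent pose and the allocentric map of landmark/goal coordinates.

    ``map`` is an (L, 2) array; its length is fixed for the lifetime of a
    trial — only the *observability* of entries ever changes.
    """

    x: float
    y: float
    theta: float
    map: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "map", np.atleast_2d(np.asarray(self.map, dtype=float)))
        if not (np.isfinite(self.x) and np.isfinite(self.y) and np.isfinite(self.theta)):
            raise ValueError("non-finite pose in WorldState")
        object.__setattr__(self, "theta", wrap_angle(self.theta))

    @property
    def pose(self) -> np.ndarray:
        return np.array([self.x, self.y, self.theta])

    @property
    def n_landmarks(self) -> int:
        return self.map.shape[0]


@dataclass(frozen=True)
class ControlInput:
    """Linear velocity v (m/s) and angular velocity w (rad/s)."""

    v: float
    w: float

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.w])


@dataclass(frozen=True)
class MotorNoise:
    """Signal-dependent motor noise coefficients (dimensionless, all >= 0).

    The per-command covariance is
    Q(u) = diag(a1^2 v^2 + a2^2 w^2,  a3^2 v^2 + a4^2 w^2),
    i.e. a1/a3 scale noise driven by forward speed (step-length and veering
    variability) and a2/a4 noise driven by turning.
    """

    alpha1: float = 0.0
    alpha2: float = 0.0
    alpha3: float = 0.0
    alpha4: float = 0.0

    def __post_init__(self):
        if min(self.alpha1, self.alpha2, self.alpha3, self.alpha4) < 0:
            raise ValueError("motor noise coefficients must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.alpha3, self.alpha4])

    def scaled(self, factor: float) -> "MotorNoise":
        return MotorNoise(*(factor * self.as_array()))


@dataclass(frozen=True)
class ObservationNoise:
    """State-dependent observation noise coefficients (variance units).

    Range variance grows linearly with distance and with eccentricity beta
    (angle off the gaze direction); bearing variance grows with log-distance
    and eccentricity:

        sigma_r   = d * (sigma_r_max^2 (1 - cos beta) + sigma_r_min^2)
        sigma_psi = log(d) * (sigma_psi_max^2 (1 - cos beta) + sigma_psi_min^2)

    Both are used directly as the diagonal entries of the 2x2 observation
    covariance R. ``floor`` bounds both entries away from zero (the log term
    vanishes at d = 1 m and would go negative closer in).
    """

    sigma_r_min: float = 0.0
    sigma_r_max: float = 0.0
    sigma_psi_min: float = 0.0
    sigma_psi_max: float = 0.0
    floor: float = 1e-6

    def __post_init__(self):
        vals = (self.sigma_r_min, self.sigma_r_max, self.sigma_psi_min, self.sigma_psi_max)
        if min(vals) < 0:
            raise ValueError("observation noise coefficients must be non-negative")
        if self.sigma_r_max < self.sigma_r_min or self.sigma_psi_max < self.sigma_psi_min:
            raise ValueError("max coefficients must be >= min coefficients")

    def scaled(self, factor: float) -> "ObservationNoise":
        return ObservationNoise(
            factor * self.sigma_r_min,
            factor * self.sigma_r_max,
            factor * self.sigma_psi_min,
            factor * self.sigma_psi_max,
            floor=self.floor,
        )


@dataclass(frozen=True)
class Observation:
    """Egocentric observation of one landmark: range (m) and bearing (rad)."""

    landmark_id: int
    range: float
    bearing: float

    def as_array(self) -> np.ndarray:
        return np.array([self.range, self.bearing])


@dataclass(frozen=True)
class FieldOfView:
    """Symmetric field of view: half-angle in (0, pi] and optional max range."""

    half_angle: float = np.pi / 2
    max_range: float = np.inf

    def __post_init__(self):
        if not 0.0 < self.half_angle <= np.pi:
            raise ValueError("half_angle must lie in (0, pi]")


def step_dynamics(state: WorldState, u: ControlInput, dt: float) -> WorldState:
    """Advance the pose one step under deterministic unicycle dynamics.

    x += cos(theta) v dt, y += sin(theta) v dt, theta += w dt (then wrapped).
    The map is untouched; noise, if any, is injected upstream into ``u``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.isfinite(u.v) and np.isfinite(u.w)):
        raise ValueError("non-finite control input")
    return replace(
        state,
        x=state.x + np.cos(state.theta) * u.v * dt,
        y=state.y + np.sin(state.theta) * u.v * dt,
        theta=wrap_angle(state.theta + u.w * dt),
    )


def motor_noise_cov(u: ControlInput, alpha: MotorNoise) -> np.ndarray:
    """Signal-dependent control noise covariance Q(u, alpha) (2x2 diagonal)."""
    v2, w2 = u.v**2, u.w**2
    return np.diag(
        [
            alpha.alpha1**2 * v2 + alpha.alpha2**2 * w2,
            alpha.alpha3**2 * v2 + alpha.alpha4**2 * w2,
        ]
    )


def sample_noisy_control(
    u: ControlInput, alpha: MotorNoise, rng: np.random.Generator, dt: float | None = None
) -> ControlInput:
    """Draw the executed control u~ = u + N(0, Q).

    With ``dt`` given, the per-step covariance is Q/dt, treating Q as a noise
    intensity so that accumulated pose variance is invariant to time-step
    refinement; with ``dt`` omitted the covariance is Q itself.
    """
    q = np.diag(motor_noise_cov(u, alpha)).copy()
    if dt is not None:
        q /= dt
    noise = rng.standard_normal(2) * np.sqrt(q)
    return ControlInput(u.v + noise[0], u.w + noise[1])


def observe_landmark(state: WorldState, landmark_id: int) -> Observation:
    """Noiseless egocentric range/bearing of one landmark.

    Bearing is measured relative to the agent's heading,
    psi = wrap(atan2(m_y - y, m_x - x) - theta).
    """
    m = state.map[landmark_id]
    dx, dy = m[0] - state.x, m[1] - state.y
    r = float(np.hypot(dx, dy))
    if r == 0.0:
        raise ValueError("landmark coincides with agent position (degenerate geometry)")
    return Observation(landmark_id, r, wrap_angle(np.arctan2(dy, dx) - state.theta))


def observation_noise_cov(
    state: WorldState, landmark_id: int, eps: ObservationNoise
) -> np.ndarray:
    """State-dependent observation covariance R = diag(sigma_r, sigma_psi)."""
    obs = observe_landmark(state, landmark_id)
    return _noise_cov_from_range_bearing(obs.range, obs.bearing, eps)


def _noise_cov_from_range_bearing(r: float, bearing: float, eps: ObservationNoise) -> np.ndarray:
    """R evaluated at a given range and bearing (eccentricity beta = |bearing|)."""
    ecc = 1.0 - np.cos(abs(bearing))
    sigma_r = r * (eps.sigma_r_max**2 * ecc + eps.sigma_r_min**2)
    sigma_psi = np.log(max(r, 1.0)) * (eps.sigma_psi_max**2 * ecc + eps.sigma_psi_min**2)
    return np.diag([max(sigma_r, eps.floor), max(sigma_psi, eps.floor)])


def visible(state: WorldState, landmark_id: int, fov: FieldOfView) -> bool:
    """Hard visibility test: |bearing| <= half_angle and range <= max_range.

    Boundaries are closed. The planner uses a smooth sigmoid surrogate of this
    indicator; the generative simulation uses this exact test.
    """
    obs = observe_landmark(state, landmark_id)
    return abs(obs.bearing) <= fov.half_angle and obs.range <= fov.max_range


def sample_observations(
    state: WorldState,
    fov: FieldOfView,
    eps: ObservationNoise,
    rng: np.random.Generator,
    observable: np.ndarray | None = None,
) -> list[Observation]:
    """One noisy observation per visible landmark (known data association).

    ``observable`` optionally masks map entries that are currently present in
    the environment (e.g. landmarks removed in the self-motion condition or
    goals not yet revealed).
    """
    out = []
    for lid in range(state.n_landmarks):
        if observable is not None and not observable[lid]:
            continue
        if not visible(state, lid, fov):
            continue
        clean = observe_landmark(state, lid)
        cov = _noise_cov_from_range_bearing(clean.range, clean.bearing, eps)
        noise = rng.standard_normal(2) * np.sqrt(np.diag(cov))
        out.append(
            Observation(
                lid,
                max(clean.range + noise[0], 1e-6),  # ranges stay positive
                wrap_angle(clean.bearing + noise[1]),
            )
        )
    return out
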