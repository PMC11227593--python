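"""Belief-space receding-horizon planning and closed-loop execution.

The agent plans a control sequence over a short horizon by minimizing a
weighted cost trading off goal proximity (measured against the *believed*
goal location), pose uncertainty, map uncertainty, and control effort. The
belief is propagated deterministically under the maximum-likelihood
observation assumption: planned means follow the pure unicycle dynamics while
covariances shrink wherever landmarks are (softly) visible, via a sigmoid
relaxation of the field-of-view indicator. Covariances are propagated but are
not decision variables. The plan is executed in model-predictive-control
fashion: the first N steps run through the noisy generative world model with
EKF feedback, then the agent replans. A reorientation fallback rotates the
agent toward the nearest believed landmark when it has been lost for too
long.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .belief_filter import (
    BeliefState,
    ekf_correct,
    ekf_predict,
    initialize_landmark,
    map_uncertainty,
    pose_uncertainty,
)
from .env_model import (
    ControlInput,
    FieldOfView,
    WorldState,
    observe_landmark,
    sample_noisy_control,
    sample_observations,
    step_dynamics,
    visible,
    wrap_angle,
)
from .params import NoiseParams

__all__ = [
    "CostWeights",
    "PlannerConfig",
    "Plan",
    "TrajectoryLog",
    "soft_visibility",
    "propagate_planning_belief",
    "total_cost",
    "plan_trajectory",
    "goal_reached",
    "mpc_run",
    "reorient",
]


@dataclass(frozen=True)
class CostWeights:
    """Weights of the planning cost.

    w1..w4 weight the goal, position-uncertainty, map-uncertainty and control
    terms; Cq is the 2x2 goal-distance metric, Cr the 2x2 control metric and
    c_tr penalizes simultaneous fast translation and rotation via (v*w)^2.
    Values are non-canonical defaults chosen for near-straight legs with
    smooth turns (see docs/methods.md).
    """

    w1: float = 1.0
    w2: float = 0.1
    w3: float = 0.05
    w4: float = 0.1
    cq: np.ndarray = field(default_factory=lambda: np.eye(2))
    cr: np.ndarray = field(default_factory=lambda: np.diag([0.1, 0.1]))
    c_tr: float = 0.1

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3, self.w4) < 0 or self.c_tr < 0:
            raise ValueError("cost weights must be non-negative")
        for name in ("cq", "cr"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (2, 2) or np.linalg.eigvalsh(0.5 * (m + m.T))[0] < -1e-12:
                raise ValueError(f"{name} must be a 2x2 PSD matrix")
            object.__setattr__(self, name, m)


@dataclass(frozen=True)
class PlannerConfig:
    """Horizons, bounds, solver and execution settings.

    T is the planning horizon and N <= T the control horizon, in steps of
    ``dt`` seconds (defaults correspond to about 1.5 s and 0.5 s of motion at
    the coarse default time step; endpoint statistics are dt-robust because
    all noise terms are dt-scaled). ``visibility_schedule`` is the decreasing
    sequence of sigmoid steepness values used to anneal the soft
    field-of-view indicator across re-solves.
    """

    T: int = 6
    N: int = 2
    dt: float = 0.25
    # Slow backward stepping is allowed; a pure forward constraint creates a
    # parking deadlock when noise carries the agent just past its goal.
    v_bounds: tuple[float, float] = (-0.5, 1.5)
    w_bounds: tuple[float, float] = (-2.0, 2.0)
    visibility_schedule: tuple[float, ...] = (50.0, 20.0, 8.0, 3.0)
    solver_maxiter: int = 25
    solver_ftol: float = 1e-6
    goal_tolerance: float = 0.1
    step_budget: int = 400
    reorient_interval: float = 2.0  # s without any observation before fallback
    reorient_uncertainty: float = 0.5  # trace(Sigma_pose) threshold (m^2 + rad^2)
    reorient_speed: float = 1.0  # rad/s turn rate of the fallback sweep
    reorient_budget_turns: float = 1.25  # full rotations before giving up
    log_covariance: bool = False

    def __post_init__(self):
        if not (self.T >= self.N >= 1):
            raise ValueError("horizons must satisfy T >= N >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not all(a > 0 for a in self.visibility_schedule):
            raise ValueError("visibility steepness values must be positive")


@dataclass(frozen=True)
class Plan:
    """A planned open-loop trajectory: means mu_0:T, controls u_0:T-1,
    propagated covariances and the achieved objective value."""

    mu_sequence: np.ndarray  # (T+1, n)
    u_sequence: np.ndarray  # (T, 2)
    predicted_sigma_sequence: np.ndarray  # (T+1, n, n)
    objective_value: float

    def __post_init__(self):
        if len(self.mu_sequence) != len(self.u_sequence) + 1:
            raise ValueError("mu and u sequences have inconsistent lengths")
        if len(self.predicted_sigma_sequence) != len(self.mu_sequence):
            raise ValueError("sigma sequence length inconsistent")


class TrajectoryLog:
    """Per-timestep record of a closed-loop run (true state, belief, controls).

    Rows accumulate as plain dicts; ``to_dataframe`` yields the documented
    columnar layout (see io module). Flattened covariances are included only
    when the planner config requests them.
    """

    def __init__(self):
        self.rows: list[dict] = []
        self.truncated: bool = False

    def append(self, *, t, phase, world: WorldState, belief: BeliefState,
               u: ControlInput | None, n_obs: int, sigma_flat=None):
        row = {
            "t": t,
            "phase": phase,
            "x": world.x,
            "y": world.y,
            "theta": world.theta,
            "v": u.v if u is not None else 0.0,
            "w": u.w if u is not None else 0.0,
            "n_obs": n_obs,
            "trace_pose": pose_uncertainty(belief),
            "trace_map": map_uncertainty(belief),
        }
        for i, val in enumerate(belief.mu):
            row[f"mu_{i}"] = val
        if sigma_flat is not None:
            for i, val in enumerate(sigma_flat):
                row[f"sigma_{i}"] = val
        self.rows.append(row)

    def extend(self, other: "TrajectoryLog"):
        self.rows.extend(other.rows)
        self.truncated = self.truncated or other.truncated

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


def soft_visibility(mu: np.ndarray, landmark_id: int, fov: FieldOfView, a: float) -> float:
    """Smooth surrogate of the field-of-view indicator, in [0, 1].

    The signed distance s combines the angular and range constraints into one
    scalar: s = max(r * (|psi| - half_angle), r - max_range), with r and psi
    the believed range and egocentric bearing of the landmark. s < 0 inside
    the field of view; the weight is 1 - 1/(1 + exp(-a s)), i.e. 0.5 on the
    boundary, -> 1 well inside and -> 0 well outside as a grows.
    """
    if a <= 0:
        raise ValueError("steepness a must be positive")
    s = _signed_fov_distance(mu, landmark_id, fov)
    return float(expit(-a * s))


def _signed_fov_distance(mu: np.ndarray, landmark_id: int, fov: FieldOfView) -> float:
    i = 3 + 2 * landmark_id
    dx = mu[i] - mu[0]
    dy = mu[i + 1] - mu[1]
    r = np.hypot(dx, dy)
    psi = wrap_angle(np.arctan2(dy, dx) - mu[2])
    s = r * (abs(psi) - fov.half_angle)  # arc-length excess beyond the boundary
    if np.isfinite(fov.max_range):
        s = max(s, r - fov.max_range)
    return float(s)


def propagate_planning_belief(
    b0: BeliefState,
    u_sequence: np.ndarray,
    config: PlannerConfig,
    noise: NoiseParams,
    fov: FieldOfView,
    a: float | None = None,
    observable: np.ndarray | None = None,
    with_covariance: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic open-loop belief rollout for planning.

    Returns (mu_sequence, sigma_sequence) with length len(u_sequence) + 1.
    Means follow the pure dynamics; covariances go through EKF prediction and
    the soft-visibility correction for every initialized, observable
    landmark. This sits in the innermost loop of the NLP objective and is
    written in flat vectorized numpy (covariance prediction as rank updates,
    batched landmark Jacobians) rather than through the BeliefState API.
    """
    if a is None:
        a = config.visibility_schedule[-1]
    u_sequence = np.atleast_2d(np.asarray(u_sequence, dtype=float))
    dt = config.dt
    n = b0.mu.size
    steps = len(u_sequence)
    mus = np.empty((steps + 1, n))
    sigmas = np.zeros((steps + 1, n, n))
    mus[0] = b0.mu
    sigmas[0] = b0.sigma
    active = np.flatnonzero(
        b0.known_mask & (observable if observable is not None else True)
    )
    mu = b0.mu.copy()
    sigma = b0.sigma.copy()
    alpha = noise.motor
    eps = noise.observation
    a1s, a2s = alpha.alpha1**2, alpha.alpha2**2
    a3s, a4s = alpha.alpha3**2, alpha.alpha4**2
    delta_xy = noise.representation.delta_xy
    k_act = active.size
    if k_act:
        ii = 3 + 2 * active  # x-index of each active landmark
        lmx = mu[ii]
        lmy = mu[ii + 1]  # map means are constant along the rollout
        rows = np.arange(2 * k_act)
    known = np.flatnonzero(b0.known_mask)
    known_diag = np.concatenate([3 + 2 * known, 4 + 2 * known])

    for t in range(steps):
        v, w = u_sequence[t]
        c, s = np.cos(mu[2]), np.sin(mu[2])
        if with_covariance:
            # Sigma <- A Sigma A^T via rank updates (A = I except col 2 of
            # the position rows), + G (Q/dt) G^T on the pose block, + memory
            # decay on initialized landmark diagonals.
            a02 = -s * v * dt
            a12 = c * v * dt
            sigma = sigma.copy()
            sigma[0, :] += a02 * sigma[2, :]
            sigma[1, :] += a12 * sigma[2, :]
            sigma[:, 0] += a02 * sigma[:, 2]
            sigma[:, 1] += a12 * sigma[:, 2]
            qv = (a1s * v * v + a2s * w * w) * dt
            qw = (a3s * v * v + a4s * w * w) * dt
            sigma[0, 0] += c * c * qv
            sigma[0, 1] += c * s * qv
            sigma[1, 0] += c * s * qv
            sigma[1, 1] += s * s * qv
            sigma[2, 2] += qw
            if delta_xy > 0 and known_diag.size:
                sigma[known_diag, known_diag] += delta_xy * dt
        mu = mu.copy()
        mu[0] += c * v * dt
        mu[1] += s * v * dt
        mu[2] = wrap_angle(mu[2] + w * dt)

        if with_covariance and k_act:
            dx = lmx - mu[0]
            dy = lmy - mu[1]
            q = dx * dx + dy * dy + 1e-12  # guard rollouts crossing a landmark
            r = np.sqrt(q)
            psi = wrap_angle(np.arctan2(dy, dx) - mu[2])
            svis = r * (np.abs(psi) - fov.half_angle)
            if np.isfinite(fov.max_range):
                svis = np.maximum(svis, r - fov.max_range)
            dvec = np.repeat(expit(-a * svis), 2)
            # batched range/bearing Jacobian H (2k x n)
            h_mat = np.zeros((2 * k_act, n))
            h_mat[0::2, 0] = -dx / r
            h_mat[0::2, 1] = -dy / r
            h_mat[1::2, 0] = dy / q
            h_mat[1::2, 1] = -dx / q
            h_mat[1::2, 2] = -1.0
            h_mat[rows[0::2], ii] = dx / r
            h_mat[rows[0::2], ii + 1] = dy / r
            h_mat[rows[1::2], ii] = -dy / q
            h_mat[rows[1::2], ii + 1] = dx / q
            ecc = 1.0 - np.cos(np.abs(psi))
            r_diag = np.empty(2 * k_act)
            r_diag[0::2] = np.maximum(
                r * (eps.sigma_r_max**2 * ecc + eps.sigma_r_min**2), eps.floor
            )
            r_diag[1::2] = np.maximum(
                np.log(np.maximum(r, 1.0))
                * (eps.sigma_psi_max**2 * ecc + eps.sigma_psi_min**2),
                eps.floor,
            )
            hs = h_mat @ sigma
            s_mat = dvec[:, None] * (hs @ h_mat.T)
            s_mat[np.diag_indices_from(s_mat)] += r_diag
            k_gain = (hs.T * dvec) @ np.linalg.solve(s_mat, np.diag(dvec))
            sigma = sigma - k_gain @ hs
            sigma = 0.5 * (sigma + sigma.T)
        mus[t + 1] = mu
        sigmas[t + 1] = sigma
    return mus, sigmas


def total_cost(
    mu_sequence: np.ndarray,
    sigma_sequence: np.ndarray,
    u_sequence: np.ndarray,
    weights: CostWeights,
    goal_id: int,
) -> float:
    """Weighted planning cost over a rolled-out trajectory.

    J = w1 sum_t (p_t - g_t)^T Cq (p_t - g_t) + w2 sum_t tr(Sigma_pose,t)
      + w3 sum_t tr(Sigma_map,t) + w4 sum_t [u_t^T Cr u_t + c_tr (v_t w_t)^2],

    where g_t is the believed goal location read from the planned mean map.
    """
    mu_sequence = np.atleast_2d(mu_sequence)
    u_sequence = np.atleast_2d(u_sequence)
    gi = 3 + 2 * goal_id
    diff = mu_sequence[:, 0:2] - mu_sequence[:, gi : gi + 2]
    j_goal = float(np.einsum("ti,ij,tj->", diff, weights.cq, diff))
    j_pos = float(np.trace(sigma_sequence[:, :3, :3], axis1=1, axis2=2).sum())
    j_map = float(np.trace(sigma_sequence[:, 3:, 3:], axis1=1, axis2=2).sum())
    j_ctrl = float(
        np.einsum("ti,ij,tj->", u_sequence, weights.cr, u_sequence)
        + weights.c_tr * ((u_sequence[:, 0] * u_sequence[:, 1]) ** 2).sum()
    )
    return weights.w1 * j_goal + weights.w2 * j_pos + weights.w3 * j_map + weights.w4 * j_ctrl


class PlannerStuck(RuntimeError):
    """Raised when the NLP solver fails to return a usable plan."""


def _batch_cost(
    b0: BeliefState,
    u_batch: np.ndarray,  # (B, T, 2)
    config: PlannerConfig,
    noise: NoiseParams,
    fov: FieldOfView,
    a: float,
    observable: np.ndarray | None,
    weights: CostWeights,
    goal_id: int,
    with_covariance: bool,
) -> np.ndarray:
    """Total planning cost for a batch of control sequences at once.

    Identical rollout to :func:`propagate_planning_belief` but carried along
    a leading batch axis, so one call prices the nominal sequence and all its
    finite-difference perturbations together. Returns costs of shape (B,).
    """
    u_batch = np.asarray(u_batch, dtype=float)
    n_b, steps, _ = u_batch.shape
    dt = config.dt
    n = b0.mu.size
    mu = np.broadcast_to(b0.mu, (n_b, n)).copy()
    sigma = np.broadcast_to(b0.sigma, (n_b, n, n)).copy()
    alpha = noise.motor
    eps = noise.observation
    a1s, a2s = alpha.alpha1**2, alpha.alpha2**2
    a3s, a4s = alpha.alpha3**2, alpha.alpha4**2
    delta_xy = noise.representation.delta_xy
    active = np.flatnonzero(
        b0.known_mask & (observable if observable is not None else True)
    )
    k_act = active.size
    if k_act:
        ii = 3 + 2 * active
        lmx = b0.mu[ii]
        lmy = b0.mu[ii + 1]
        rows = np.arange(2 * k_act)
        dii = np.arange(2 * k_act)
    known = np.flatnonzero(b0.known_mask)
    known_diag = np.concatenate([3 + 2 * known, 4 + 2 * known])
    gi = 3 + 2 * goal_id
    goal_xy = b0.mu[gi : gi + 2]

    cq, cr, c_tr = weights.cq, weights.cr, weights.c_tr
    diff0 = mu[:, 0:2] - goal_xy
    j_goal = np.einsum("bi,ij,bj->b", diff0, cq, diff0)
    j_pos = np.einsum("bii->b", sigma[:, :3, :3]) * np.ones(n_b)
    j_map = np.einsum("bii->b", sigma[:, 3:, 3:]) * np.ones(n_b)
    j_ctrl = np.zeros(n_b)

    for t in range(steps):
        v = u_batch[:, t, 0]
        w = u_batch[:, t, 1]
        c, s = np.cos(mu[:, 2]), np.sin(mu[:, 2])
        if with_covariance:
            a02 = -s * v * dt
            a12 = c * v * dt
            sigma[:, 0, :] += a02[:, None] * sigma[:, 2, :]
            sigma[:, 1, :] += a12[:, None] * sigma[:, 2, :]
            sigma[:, :, 0] += a02[:, None] * sigma[:, :, 2]
            sigma[:, :, 1] += a12[:, None] * sigma[:, :, 2]
            qv = (a1s * v * v + a2s * w * w) * dt
            qw = (a3s * v * v + a4s * w * w) * dt
            sigma[:, 0, 0] += c * c * qv
            sigma[:, 0, 1] += c * s * qv
            sigma[:, 1, 0] += c * s * qv
            sigma[:, 1, 1] += s * s * qv
            sigma[:, 2, 2] += qw
            if delta_xy > 0 and known_diag.size:
                sigma[:, known_diag, known_diag] += delta_xy * dt
        mu = mu.copy()
        mu[:, 0] += c * v * dt
        mu[:, 1] += s * v * dt
        mu[:, 2] = wrap_angle(mu[:, 2] + w * dt)

        if with_covariance and k_act:
            dx = lmx[None, :] - mu[:, 0:1]
            dy = lmy[None, :] - mu[:, 1:2]
            q = dx * dx + dy * dy + 1e-12  # guard rollouts crossing a landmark
            r = np.sqrt(q)
            psi = wrap_angle(np.arctan2(dy, dx) - mu[:, 2:3])
            svis = r * (np.abs(psi) - fov.half_angle)
            if np.isfinite(fov.max_range):
                svis = np.maximum(svis, r - fov.max_range)
            dvec = np.repeat(expit(-a * svis), 2, axis=1)  # (B, 2k)
            h_mat = np.zeros((n_b, 2 * k_act, n))
            h_mat[:, 0::2, 0] = -dx / r
            h_mat[:, 0::2, 1] = -dy / r
            h_mat[:, 1::2, 0] = dy / q
            h_mat[:, 1::2, 1] = -dx / q
            h_mat[:, 1::2, 2] = -1.0
            h_mat[:, rows[0::2], ii] = dx / r
            h_mat[:, rows[0::2], ii + 1] = dy / r
            h_mat[:, rows[1::2], ii] = -dy / q
            h_mat[:, rows[1::2], ii + 1] = dx / q
            ecc = 1.0 - np.cos(np.abs(psi))
            r_diag = np.empty((n_b, 2 * k_act))
            r_diag[:, 0::2] = np.maximum(
                r * (eps.sigma_r_max**2 * ecc + eps.sigma_r_min**2), eps.floor
            )
            r_diag[:, 1::2] = np.maximum(
                np.log(np.maximum(r, 1.0))
                * (eps.sigma_psi_max**2 * ecc + eps.sigma_psi_min**2),
                eps.floor,
            )
            hs = h_mat @ sigma
            s_mat = dvec[:, :, None] * (hs @ h_mat.transpose(0, 2, 1))
            s_mat[:, dii, dii] += r_diag
            d_mat = np.zeros((n_b, 2 * k_act, 2 * k_act))
            d_mat[:, dii, dii] = dvec
            k_gain = (hs.transpose(0, 2, 1) * dvec[:, None, :]) @ np.linalg.solve(
                s_mat, d_mat
            )
            sigma = sigma - k_gain @ hs
            sigma = 0.5 * (sigma + sigma.transpose(0, 2, 1))

        diff = mu[:, 0:2] - goal_xy
        j_goal += np.einsum("bi,ij,bj->b", diff, cq, diff)
        if with_covariance:
            j_pos += np.einsum("bii->b", sigma[:, :3, :3])
            j_map += np.einsum("bii->b", sigma[:, 3:, 3:])
        u_t = u_batch[:, t, :]
        j_ctrl += np.einsum("bi,ij,bj->b", u_t, cr, u_t) + c_tr * (v * w) ** 2

    return (
        weights.w1 * j_goal
        + weights.w2 * j_pos
        + weights.w3 * j_map
        + weights.w4 * j_ctrl
    )


def plan_trajectory(
    b: BeliefState,
    goal_id: int,
    weights: CostWeights,
    config: PlannerConfig,
    noise: NoiseParams,
    fov: FieldOfView,
    observable: np.ndarray | None = None,
    warm_start: np.ndarray | None = None,
) -> Plan:
    """Solve the receding-horizon trajectory optimization problem.

    Single-shooting transcription: the decision variables are the T control
    pairs; means are generated by rolling the deterministic dynamics, so the
    dynamics constraint holds by construction and the control bounds are box
    constraints. Covariances are propagated inside the objective but are not
    decision variables. The soft-visibility steepness is annealed across
    re-solves with warm starts; the returned plan is the best of the solver
    solution, the warm start and the zero-control sequence, evaluated at the
    final steepness, which guarantees the zero-control objective floor.
    """
    if not b.known_mask[goal_id]:
        raise ValueError(f"goal {goal_id} not initialized in the belief")
    t_hor = config.T
    need_cov = weights.w2 > 0 or weights.w3 > 0
    n_var = 2 * t_hor
    fd_step = 1e-6

    def batch_objective(u_flats, a):
        u_batch = np.asarray(u_flats, float).reshape(-1, t_hor, 2)
        return _batch_cost(
            b, u_batch, config, noise, fov, a, observable, weights, goal_id,
            with_covariance=need_cov,
        )

    def objective_and_grad(u_flat, a):
        # nominal sequence and its forward-difference perturbations priced in
        # one vectorized rollout
        pts = np.repeat(u_flat[None, :], n_var + 1, axis=0)
        pts[1:] += fd_step * np.eye(n_var)
        costs = batch_objective(pts, a)
        return costs[0], (costs[1:] - costs[0]) / fd_step

    bounds = [(config.v_bounds[0], config.v_bounds[1]),
              (config.w_bounds[0], config.w_bounds[1])] * t_hor
    lo = np.array([bd[0] for bd in bounds])
    hi = np.array([bd[1] for bd in bounds])

    if warm_start is not None:
        x0 = np.clip(np.asarray(warm_start, dtype=float).ravel(), lo, hi)
    else:
        x0 = _heuristic_start(b, goal_id, config)
    zero = np.clip(np.zeros(2 * t_hor), lo, hi)

    # Anneal only on cold starts; warm-started replans in the MPC loop are
    # already near a solution at the final steepness.
    if not need_cov or warm_start is not None:
        schedule = config.visibility_schedule[-1:]
    else:
        schedule = config.visibility_schedule
    def solve_from(x_init, sched):
        x = x_init.copy()
        for a in sched:
            res = minimize(
                objective_and_grad,
                x,
                args=(a,),
                jac=True,
                method="SLSQP",
                bounds=bounds,
                options={"maxiter": config.solver_maxiter, "ftol": config.solver_ftol},
            )
            if np.all(np.isfinite(res.x)):
                x = np.clip(res.x, lo, hi)
        return x

    a_final = schedule[-1]
    x = solve_from(x0, schedule)
    # Standstill warm starts put gradient methods on a turn-then-go saddle;
    # re-solve from the heuristic whenever it undercuts the solved point.
    heur = np.clip(_heuristic_start(b, goal_id, config), lo, hi)
    if batch_objective(np.stack([heur]), a_final)[0] < batch_objective(
        np.stack([x]), a_final
    )[0]:
        x = solve_from(heur, schedule[-1:])
    candidates = np.stack([x, x0, zero, heur])
    costs = batch_objective(candidates, a_final)
    if not np.any(np.isfinite(costs)):
        raise PlannerStuck("trajectory optimization returned no finite objective")
    best = candidates[int(np.nanargmin(costs))]
    u_seq = best.reshape(t_hor, 2)
    mus, sigmas = propagate_planning_belief(
        b, u_seq, config, noise, fov, a=a_final, observable=observable
    )
    return Plan(mus, u_seq, sigmas, float(np.nanmin(costs)))


def _heuristic_start(b: BeliefState, goal_id: int, config: PlannerConfig) -> np.ndarray:
    """Turn-then-go initial guess toward the believed goal."""
    gi = 3 + 2 * goal_id
    dx = b.mu[gi] - b.mu[0]
    dy = b.mu[gi + 1] - b.mu[1]
    dist = np.hypot(dx, dy)
    bearing = wrap_angle(np.arctan2(dy, dx) - b.mu[2])
    u = np.zeros((config.T, 2))
    w_max = config.w_bounds[1]
    turn_steps = min(int(np.ceil(abs(bearing) / (w_max * config.dt + 1e-12))), config.T)
    if turn_steps:
        u[:turn_steps, 1] = np.clip(bearing / (turn_steps * config.dt), *config.w_bounds)
    go_steps = max(config.T - turn_steps, 1)
    v = np.clip(dist / (go_steps * config.dt), *config.v_bounds)
    u[turn_steps:, 0] = v
    return u.ravel()


def goal_reached(b: BeliefState, goal_id: int, tolerance: float) -> bool:
    """True iff the *believed* position is within tolerance of the *believed*
    goal location (closed boundary). Endpoints therefore err exactly as the
    belief errs — the mechanism behind homing errors."""
    if not b.known_mask[goal_id]:
        return False
    gi = 3 + 2 * goal_id
    d = np.hypot(b.mu[0] - b.mu[gi], b.mu[1] - b.mu[gi + 1])
    return bool(d <= tolerance)


def _observe_and_correct(world, b, fov, noise, rng, observable):
    """Sample observations, initialize first-sight landmarks, EKF-correct."""
    obs = sample_observations(world, fov, noise.observation, rng, observable)
    known_obs = []
    for o in obs:
        if b.known_mask[o.landmark_id]:
            known_obs.append(o)
        else:
            b = initialize_landmark(b, o, noise.observation)
    if known_obs:
        b = ekf_correct(b, known_obs, noise.observation)
    return b, len(obs)


def mpc_run(
    world: WorldState,
    b: BeliefState,
    goal_id: int,
    weights: CostWeights,
    config: PlannerConfig,
    noise: NoiseParams,
    rng: np.random.Generator,
    fov: FieldOfView,
    observable: np.ndarray | None = None,
    phase: str = "navigate",
    log: TrajectoryLog | None = None,
    t_start: int = 0,
) -> tuple[WorldState, BeliefState, TrajectoryLog]:
    """Closed-loop navigation toward the believed location of ``goal_id``.

    Loop: plan, execute the first N controls through the noisy world model
    (the belief is predicted with the *commanded* control, the world moves
    with the sampled noisy one), observe and correct, replan. Terminates when
    the believed position matches the believed goal or the step budget runs
    out (the log is then flagged truncated). Fully reproducible under a fixed
    seed: all stochasticity flows through ``rng``.
    """
    if log is None:
        log = TrajectoryLog()
    steps = 0
    last_obs_step = 0
    warm = None
    reorient_failed = False
    interval_steps = max(int(round(config.reorient_interval / config.dt)), 1)
    # Initial glance: observe whatever is in view before the first plan, so
    # newly revealed goals/landmarks enter the belief at first encounter.
    b, _ = _observe_and_correct(world, b, fov, noise, rng, observable)
    if not b.known_mask[goal_id]:
        # Target not yet sighted (e.g. revealed behind the agent): sweep in
        # place until it enters the field of view.
        rows_before = len(log.rows)
        world, b, log, found = _search_sweep(
            world, b, goal_id, config, noise, rng, fov,
            observable=observable, log=log, t_start=t_start,
        )
        steps = len(log.rows) - rows_before
        if not found:
            log.truncated = True
            return world, b, log
    while not goal_reached(b, goal_id, config.goal_tolerance):
        if steps >= config.step_budget:
            log.truncated = True
            break
        stuck = False
        try:
            plan = plan_trajectory(
                b, goal_id, weights, config, noise, fov,
                observable=observable, warm_start=warm,
            )
        except PlannerStuck:
            stuck = True
        lost = (
            not reorient_failed
            and steps - last_obs_step >= interval_steps
            and pose_uncertainty(b) > config.reorient_uncertainty
        )
        if stuck or lost:
            rows_before = len(log.rows)
            world, b, log, saw = reorient(
                world, b, config, noise, rng, fov,
                observable=observable, log=log, t_start=t_start + steps,
            )
            steps += len(log.rows) - rows_before  # reorientation consumed time
            last_obs_step = steps
            # A full sweep that saw nothing means there is nothing to see;
            # fall back to dead reckoning until an observation arrives.
            reorient_failed = not saw
            warm = None
            if stuck:
                continue
            plan = plan_trajectory(
                b, goal_id, weights, config, noise, fov, observable=observable
            )
        if np.abs(plan.u_sequence).max() < 1e-6:
            # Standstill plan with the goal still out of tolerance: the goal
            # lies abeam and first-order solvers sit on the turn-then-go
            # saddle. Escape by orienting toward the believed goal bearing,
            # then replan.
            gi = 3 + 2 * goal_id
            bearing = wrap_angle(
                np.arctan2(b.mu[gi + 1] - b.mu[1], b.mu[gi] - b.mu[0]) - b.mu[2]
            )
            while abs(bearing) > 0.1 and steps < config.step_budget:
                w_cmd = float(np.clip(bearing / config.dt, *config.w_bounds))
                u = ControlInput(0.0, w_cmd)
                u_noisy = sample_noisy_control(u, noise.motor, rng, dt=config.dt)
                world = step_dynamics(world, u_noisy, config.dt)
                b = ekf_predict(b, u, config.dt, noise.motor, noise.representation, rng)
                b, n_obs = _observe_and_correct(world, b, fov, noise, rng, observable)
                steps += 1
                log.append(
                    t=t_start + steps, phase=phase, world=world, belief=b, u=u,
                    n_obs=n_obs,
                    sigma_flat=b.sigma.ravel() if config.log_covariance else None,
                )
                bearing = wrap_angle(
                    np.arctan2(b.mu[gi + 1] - b.mu[1], b.mu[gi] - b.mu[0]) - b.mu[2]
                )
            if steps < config.step_budget and not goal_reached(
                b, goal_id, config.goal_tolerance
            ):
                # one forward step toward the believed goal so the escape
                # always makes progress
                d = np.hypot(b.mu[0] - b.mu[gi], b.mu[1] - b.mu[gi + 1])
                u = ControlInput(float(np.clip(d / config.dt, *config.v_bounds)), 0.0)
                u_noisy = sample_noisy_control(u, noise.motor, rng, dt=config.dt)
                world = step_dynamics(world, u_noisy, config.dt)
                b = ekf_predict(b, u, config.dt, noise.motor, noise.representation, rng)
                b, n_obs = _observe_and_correct(world, b, fov, noise, rng, observable)
                steps += 1
                log.append(
                    t=t_start + steps, phase=phase, world=world, belief=b, u=u,
                    n_obs=n_obs,
                    sigma_flat=b.sigma.ravel() if config.log_covariance else None,
                )
            warm = None
            continue
        for k in range(config.N):
            u = ControlInput(*plan.u_sequence[k])
            u_noisy = sample_noisy_control(u, noise.motor, rng, dt=config.dt)
            world = step_dynamics(world, u_noisy, config.dt)
            b = ekf_predict(b, u, config.dt, noise.motor, noise.representation, rng)
            b, n_obs = _observe_and_correct(world, b, fov, noise, rng, observable)
            if n_obs:
                last_obs_step = steps + 1
                reorient_failed = False
            steps += 1
            log.append(
                t=t_start + steps, phase=phase, world=world, belief=b, u=u,
                n_obs=n_obs,
                sigma_flat=b.sigma.ravel() if config.log_covariance else None,
            )
            if goal_reached(b, goal_id, config.goal_tolerance) or steps >= config.step_budget:
                break
        warm = np.concatenate(
            [plan.u_sequence[config.N :], np.zeros((config.N, 2))]
        ).ravel()
    return world, b, log


def _search_sweep(
    world, b, goal_id, config, noise, rng, fov, observable, log, t_start
):
    """Rotate in place until ``goal_id`` has been sighted and initialized."""
    u = ControlInput(0.0, config.reorient_speed)
    max_steps = int(np.ceil(
        config.reorient_budget_turns * 2 * np.pi / (config.reorient_speed * config.dt)
    ))
    for k in range(max_steps):
        u_noisy = sample_noisy_control(u, noise.motor, rng, dt=config.dt)
        world = step_dynamics(world, u_noisy, config.dt)
        b = ekf_predict(b, u, config.dt, noise.motor, noise.representation, rng)
        b, n_obs = _observe_and_correct(world, b, fov, noise, rng, observable)
        log.append(t=t_start + k + 1, phase="search", world=world, belief=b, u=u,
                   n_obs=n_obs,
                   sigma_flat=b.sigma.ravel() if config.log_covariance else None)
        if b.known_mask[goal_id]:
            return world, b, log, True
    return world, b, log, False


def reorient(
    world: WorldState,
    b: BeliefState,
    config: PlannerConfig,
    noise: NoiseParams,
    rng: np.random.Generator,
    fov: FieldOfView,
    observable: np.ndarray | None = None,
    log: TrajectoryLog | None = None,
    t_start: int = 0,
) -> tuple[WorldState, BeliefState, TrajectoryLog, bool]:
    """Rotate in place toward the nearest believed landmark until one is seen.

    If a landmark is already truly visible, correct immediately without
    rotating. Otherwise sweep in the direction of the believed bearing of the
    nearest initialized landmark; stop as soon as any landmark enters the
    true field of view and fuse it. If the rotation budget is exhausted with
    nothing observed (e.g. landmarks removed), return with the belief changed
    only by the predicted rotation — the agent proceeds on dead reckoning.
    Returns (world, belief, log, observed_any).
    """
    if log is None:
        log = TrajectoryLog()
    known = np.flatnonzero(b.known_mask)
    if known.size == 0:
        return world, b, log, False

    def truly_visible():
        for lid in range(world.n_landmarks):
            if observable is not None and not observable[lid]:
                continue
            if visible(world, lid, fov):
                return True
        return False

    if truly_visible():
        b, n_obs = _observe_and_correct(world, b, fov, noise, rng, observable)
        log.append(t=t_start, phase="reorient", world=world, belief=b, u=None,
                   n_obs=n_obs,
                   sigma_flat=b.sigma.ravel() if config.log_covariance else None)
        return world, b, log, n_obs > 0

    # believed bearing of the nearest believed landmark sets the sweep direction
    dists, bearings = [], []
    for lid in known:
        i = 3 + 2 * lid
        dx, dy = b.mu[i] - b.mu[0], b.mu[i + 1] - b.mu[1]
        dists.append(np.hypot(dx, dy))
        bearings.append(wrap_angle(np.arctan2(dy, dx) - b.mu[2]))
    direction = np.sign(bearings[int(np.argmin(dists))]) or 1.0
    w_cmd = float(direction * config.reorient_speed)
    max_steps = int(np.ceil(
        config.reorient_budget_turns * 2 * np.pi / (abs(w_cmd) * config.dt)
    ))
    u = ControlInput(0.0, w_cmd)
    for k in range(max_steps):
        u_noisy = sample_noisy_control(u, noise.motor, rng, dt=config.dt)
        world = step_dynamics(world, u_noisy, config.dt)
        b = ekf_predict(b, u, config.dt, noise.motor, noise.representation, rng)
        n_obs = 0
        if truly_visible():
            b, n_obs = _observe_and_correct(world, b, fov, noise, rng, observable)
        log.append(t=t_start + k + 1, phase="reorient", world=world, belief=b,
                   u=u, n_obs=n_obs,
                   sigma_flat=b.sigma.ravel() if config.log_covariance else None)
        if n_obs:
            return world, b, log, True
    return world, b, log, False
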