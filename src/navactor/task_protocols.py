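"""Triangle-completion trial and experiment orchestration.

A trial walks a three-legged outbound path through a sequence of goal
locations, applies one of four cue manipulations at the third goal
(self-motion: landmarks removed; landmark: disorientation by offset plus
noisy rotation with inflated pose uncertainty; combined: waiting only;
conflict: landmarks covertly rotated about the third goal), and then homes
toward the remembered first goal. The homing endpoint is the true stop
location when the agent believes it has reached the believed home location.

Environment templates emulate three published study families at the level of
their described constraints (landmark counts, proximal ~5.5 m vs distal
~500 m ranges in the same angular configuration, simultaneous vs sequential
goal presentation); exact layout coordinates are non-canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .belief_filter import BeliefState, decay_representation, ekf_predict
from .env_model import (
    ControlInput,
    FieldOfView,
    MotorNoise,
    ObservationNoise,
    WorldState,
    sample_noisy_control,
    step_dynamics,
)
from .belief_filter import RepresentationNoise
from .params import NoiseParams
from .planner import CostWeights, PlannerConfig, TrajectoryLog, mpc_run

__all__ = [
    "EnvironmentLayout",
    "TrialProtocol",
    "Disorientation",
    "AblationSpec",
    "EndpointRecord",
    "CONDITIONS",
    "make_environment",
    "run_outbound",
    "apply_condition",
    "run_trial",
    "run_experiment",
    "sample_noise_parameters",
    "trial_seed",
]

CONDITIONS = ("self_motion", "landmark", "combined", "conflict")


@dataclass(frozen=True)
class EnvironmentLayout:
    """Landmarks, goals, start pose and field of view of one environment.

    The joint map is landmarks first, then goals; goal k has map index
    ``n_landmarks + k``.
    """

    landmarks: np.ndarray  # (n_lm, 2)
    goals: np.ndarray  # (n_goal, 2)
    start_pose: np.ndarray  # (3,)
    fov: FieldOfView = field(default_factory=FieldOfView)
    name: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "landmarks", np.atleast_2d(np.asarray(self.landmarks, float)))
        object.__setattr__(self, "goals", np.atleast_2d(np.asarray(self.goals, float)))
        object.__setattr__(self, "start_pose", np.asarray(self.start_pose, float))
        if self.start_pose.shape != (3,):
            raise ValueError("start_pose must be (x, y, theta)")

    @property
    def n_landmarks(self) -> int:
        return self.landmarks.shape[0]

    @property
    def n_goals(self) -> int:
        return self.goals.shape[0]

    @property
    def full_map(self) -> np.ndarray:
        return np.vstack([self.landmarks, self.goals])

    def goal_index(self, k: int) -> int:
        return self.n_landmarks + k


@dataclass(frozen=True)
class Disorientation:
    """Swivel-chair disorientation parameters for the landmark condition."""

    positional_offset_sd: float = 0.3  # m, applied to world and belief alike
    turn_speed: float = 1.5  # rad/s
    turn_duration: float = 6.0  # s
    heading_inflation: float = 1.5  # rad^2 added to the heading variance
    position_inflation: float = 0.15  # m^2 added to each position variance


@dataclass(frozen=True)
class TrialProtocol:
    """Condition label and manipulation parameters of one trial."""

    condition: str = "combined"
    goal_sequence: tuple[int, ...] = (0, 1, 2)
    goals_visible_mode: str = "sequential"  # or "all_at_start"
    waiting_time: float = 10.0  # s in darkness before homing (8-20 in the studies)
    disorientation: Disorientation = field(default_factory=Disorientation)
    conflict_angle: float = np.deg2rad(15.0)
    conflict_center: int = 2  # goal-sequence position of the third goal

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.goals_visible_mode not in ("sequential", "all_at_start"):
            raise ValueError("goals_visible_mode must be 'sequential' or 'all_at_start'")
        if self.waiting_time < 0:
            raise ValueError("waiting_time must be non-negative")


@dataclass(frozen=True)
class AblationSpec:
    """Which noise sources a model variant includes (2^3 = 8 variants).

    Excluded sources are zeroed in both the generative process and the
    agent's internal uncertainties.
    """

    include_perceptual: bool = True
    include_representation: bool = True
    include_motor: bool = True

    @property
    def label(self) -> str:
        parts = [
            name
            for name, on in (
                ("perceptual", self.include_perceptual),
                ("representation", self.include_representation),
                ("motor", self.include_motor),
            )
            if on
        ]
        return "+".join(parts) if parts else "zero"

    def apply(self, params: NoiseParams) -> NoiseParams:
        return params.without(
            motor=not self.include_motor,
            perceptual=not self.include_perceptual,
            representation=not self.include_representation,
        )


@dataclass(frozen=True)
class EndpointRecord:
    """One homing response: stop location plus trial bookkeeping."""

    participant_id: int
    trial_id: int
    condition: str
    target_id: int
    stop_x: float
    stop_y: float
    truncated: bool
    seed: int
    home_x: float = np.nan
    home_y: float = np.nan
    home_lm_x: float = np.nan  # landmark-consistent home (conflict trials)
    home_lm_y: float = np.nan


_TEMPLATES = {}


def _register(name):
    def deco(fn):
        _TEMPLATES[name] = fn
        return fn

    return deco


def _landmarks_at(bearings_deg, ranges, origin=(0.0, 0.0)):
    ang = np.deg2rad(np.asarray(bearings_deg, float))
    r = np.broadcast_to(np.asarray(ranges, float), ang.shape)
    return np.column_stack(
        [origin[0] + r * np.cos(ang), origin[1] + r * np.sin(ang)]
    )


# Goal triangles sized like the original arenas: legs of a few metres.
_GOALS_SMALL = np.array([[0.0, 2.5], [2.2, 3.6], [3.2, 1.4]])
_START = np.array([0.0, 0.0, np.pi / 2])


@_register("nardini_like")
def _nardini_like():
    # Room-scale arena, three background landmarks, all goals visible at start.
    return EnvironmentLayout(
        landmarks=_landmarks_at([150.0, 90.0, 30.0], 6.0),
        goals=_GOALS_SMALL,
        start_pose=_START,
        fov=FieldOfView(half_angle=np.pi / 2),
        name="nardini_like",
    )


@_register("chen_like_3lm")
def _chen_like_3lm():
    # Immersive VR, three landmarks, sequential goals, restricted display fov.
    return EnvironmentLayout(
        landmarks=_landmarks_at([140.0, 90.0, 40.0], 7.0),
        goals=_GOALS_SMALL,
        start_pose=_START,
        fov=FieldOfView(half_angle=np.deg2rad(55.0)),
        name="chen_like_3lm",
    )


@_register("chen_like_1lm")
def _chen_like_1lm():
    return replace(
        _chen_like_3lm(),
        landmarks=_landmarks_at([90.0], 7.0),
        name="chen_like_1lm",
    )


_ZHAO_BEARINGS = [120.0, 90.0, 60.0]


@_register("zhao_proximal")
def _zhao_proximal():
    return EnvironmentLayout(
        landmarks=_landmarks_at(_ZHAO_BEARINGS, 5.5),
        goals=_GOALS_SMALL,
        start_pose=_START,
        fov=FieldOfView(half_angle=np.deg2rad(55.0)),
        name="zhao_proximal",
    )


@_register("zhao_distal")
def _zhao_distal():
    # Same angular configuration as the proximal layout, pushed to 500 m.
    return replace(
        _zhao_proximal(),
        landmarks=_landmarks_at(_ZHAO_BEARINGS, 500.0),
        name="zhao_distal",
    )


def make_environment(spec) -> EnvironmentLayout:
    """Build an environment from a template name or an explicit mapping.

    Templates: nardini_like, chen_like_1lm, chen_like_3lm, zhao_proximal,
    zhao_distal. An explicit mapping must provide 'landmarks', 'goals' and
    'start_pose', with optional 'fov_half_angle' / 'fov_max_range' (radians
    and metres) and 'name'.
    """
    if isinstance(spec, EnvironmentLayout):
        return spec
    if isinstance(spec, str):
        try:
            return _TEMPLATES[spec]()
        except KeyError:
            raise ValueError(
                f"unknown environment template {spec!r}; "
                f"available: {sorted(_TEMPLATES)}"
            ) from None
    if isinstance(spec, dict):
        try:
            fov = FieldOfView(
                half_angle=float(spec.get("fov_half_angle", np.pi / 2)),
                max_range=float(spec.get("fov_max_range", np.inf)),
            )
            return EnvironmentLayout(
                landmarks=np.asarray(spec["landmarks"], float),
                goals=np.asarray(spec["goals"], float),
                start_pose=np.asarray(spec["start_pose"], float),
                fov=fov,
                name=str(spec.get("name", "custom")),
            )
        except KeyError as exc:
            raise ValueError(f"environment spec missing required key {exc}") from None
    raise ValueError("environment spec must be a template name or a mapping")


def _observable_mask(env: EnvironmentLayout, *, landmarks: bool, goals_upto: int) -> np.ndarray:
    """Presence mask over the joint map: landmarks toggled as a group, goals
    revealed up to (and including) sequence position ``goals_upto``."""
    mask = np.zeros(env.n_landmarks + env.n_goals, dtype=bool)
    mask[: env.n_landmarks] = landmarks
    for k in range(min(goals_upto + 1, env.n_goals)):
        mask[env.goal_index(k)] = True
    return mask


def run_outbound(
    env: EnvironmentLayout,
    protocol: TrialProtocol,
    params: NoiseParams,
    rng: np.random.Generator,
    weights: CostWeights | None = None,
    config: PlannerConfig | None = None,
) -> tuple[WorldState, BeliefState, TrajectoryLog]:
    """Walk the outbound path through the goal sequence.

    The agent starts with an empty map; landmarks and goals are initialized
    into the belief when first sighted. In sequential mode each goal is
    revealed only after the previous leg is completed; in all_at_start mode
    every goal is present (hence initializable) from t = 0.
    """
    weights = weights or CostWeights()
    config = config or PlannerConfig()
    world = WorldState(*env.start_pose, map=env.full_map)
    belief = BeliefState.initial(env.start_pose, env.n_landmarks + env.n_goals)
    log = TrajectoryLog()
    for leg, seq_pos in enumerate(protocol.goal_sequence):
        if protocol.goals_visible_mode == "all_at_start":
            observable = _observable_mask(env, landmarks=True, goals_upto=env.n_goals - 1)
        else:
            observable = _observable_mask(env, landmarks=True, goals_upto=leg)
        world, belief, log = mpc_run(
            world,
            belief,
            env.goal_index(seq_pos),
            weights,
            config,
            params,
            rng,
            env.fov,
            observable=observable,
            phase=f"outbound-leg-{leg + 1}",
            log=log,
            t_start=len(log.rows),
        )
        if log.truncated:
            break
    return world, belief, log


def apply_condition(
    world: WorldState,
    belief: BeliefState,
    protocol: TrialProtocol,
    params: NoiseParams,
    rng: np.random.Generator,
    env: EnvironmentLayout,
    config: PlannerConfig | None = None,
) -> tuple[WorldState, BeliefState, TrajectoryLog, np.ndarray]:
    """Apply the cue manipulation at the end of the outbound path.

    All conditions include the waiting period in darkness, during which the
    remembered map decays. Returns the manipulated world and belief, a log of
    the manipulation phase, and the observability mask for the homing leg.
    """
    config = config or PlannerConfig()
    log = TrajectoryLog()
    belief = decay_representation(belief, protocol.waiting_time, params.representation, rng)
    homing_observable = _observable_mask(env, landmarks=True, goals_upto=-1)

    if protocol.condition == "self_motion":
        homing_observable[:] = False

    elif protocol.condition == "landmark":
        dis = protocol.disorientation
        offset = rng.standard_normal(2) * dis.positional_offset_sd
        world = replace(world, x=world.x + offset[0], y=world.y + offset[1])
        mu = belief.mu.copy()
        mu[0] += offset[0]
        mu[1] += offset[1]
        belief = replace(belief, mu=mu)
        # Noisy swivel-chair rotation: the true heading follows the noisy
        # turn, the belief keeps its stale heading with inflated uncertainty
        # (the participant does not track the imposed rotation).
        n_steps = max(int(round(dis.turn_duration / config.dt)), 1)
        u = ControlInput(0.0, dis.turn_speed)
        for k in range(n_steps):
            u_noisy = sample_noisy_control(u, params.motor, rng, dt=config.dt)
            world = step_dynamics(world, u_noisy, config.dt)
            log.append(t=k, phase="disorientation", world=world, belief=belief,
                       u=u, n_obs=0)
        sigma = belief.sigma.copy()
        sigma[0, 0] += dis.position_inflation
        sigma[1, 1] += dis.position_inflation
        sigma[2, 2] += dis.heading_inflation
        belief = replace(belief, sigma=sigma)
        belief = decay_representation(
            belief, dis.turn_duration, params.representation, rng
        )

    elif protocol.condition == "conflict":
        center = world.map[
            env.goal_index(protocol.goal_sequence[protocol.conflict_center])
        ]
        new_map = world.map.copy()
        new_map[: env.n_landmarks] = _rotate_about(
            world.map[: env.n_landmarks], center, protocol.conflict_angle
        )
        world = replace(world, map=new_map)

    # combined: waiting decay only (already applied)
    return world, belief, log, homing_observable


def _rotate_about(points: np.ndarray, center: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return (points - center) @ rot.T + center


def landmark_consistent_home(
    env: EnvironmentLayout, protocol: TrialProtocol
) -> np.ndarray:
    """Where the home goal would be if the rotated landmarks told the truth."""
    center = env.goals[protocol.goal_sequence[protocol.conflict_center]]
    home = env.goals[protocol.goal_sequence[0]]
    return _rotate_about(home[None, :], center, protocol.conflict_angle)[0]


def run_trial(
    env,
    protocol: TrialProtocol,
    params: NoiseParams,
    ablation: AblationSpec | None = None,
    seed: int = 0,
    weights: CostWeights | None = None,
    config: PlannerConfig | None = None,
    participant_id: int = 0,
    trial_id: int = 0,
    return_log: bool = False,
):
    """Simulate one complete trial: outbound, manipulation, homing.

    Each trial is independent and identically set up (no trial-by-trial
    learning). The endpoint is the true stop location when the agent believes
    it has reached the believed home; the homing target is the belief's
    stored first-goal estimate, never the true goal.
    """
    env = make_environment(env)
    ablation = ablation or AblationSpec()
    params = ablation.apply(params)
    weights = weights or CostWeights()
    config = config or PlannerConfig()
    rng = np.random.default_rng(seed)

    world, belief, log = run_outbound(env, protocol, params, rng, weights, config)
    world, belief, cond_log, homing_observable = apply_condition(
        world, belief, protocol, params, rng, env, config
    )
    log.extend(cond_log)
    home_goal = env.goal_index(protocol.goal_sequence[0])
    world, belief, log = mpc_run(
        world, belief, home_goal, weights, config, params, rng, env.fov,
        observable=homing_observable, phase="homing", log=log,
        t_start=len(log.rows),
    )
    home = env.goals[protocol.goal_sequence[0]]
    lm_home = (
        landmark_consistent_home(env, protocol)
        if protocol.condition == "conflict"
        else np.array([np.nan, np.nan])
    )
    record = EndpointRecord(
        participant_id=participant_id,
        trial_id=trial_id,
        condition=protocol.condition,
        target_id=home_goal,
        stop_x=world.x,
        stop_y=world.y,
        truncated=log.truncated,
        seed=seed,
        home_x=home[0],
        home_y=home[1],
        home_lm_x=lm_home[0],
        home_lm_y=lm_home[1],
    )
    return (record, log) if return_log else record


def trial_seed(base_seed: int, participant: int, condition: str, trial: int) -> int:
    """Deterministic, order-insensitive per-trial seed below 2^31."""
    ss = np.random.SeedSequence(
        base_seed, spawn_key=(participant, CONDITIONS.index(condition), trial)
    )
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_experiment(
    env,
    protocols,
    n_participants: int,
    trials_per_condition: int,
    params: NoiseParams,
    ablation: AblationSpec | None = None,
    base_seed: int = 0,
    weights: CostWeights | None = None,
    config: PlannerConfig | None = None,
) -> pd.DataFrame:
    """Simulate a batch of participants x trials x conditions.

    ``protocols`` maps condition name -> TrialProtocol (any subset of the
    four). Per-trial seeds derive deterministically from the base seed and
    the (participant, condition, trial) triple, so trials are independent and
    the result is invariant to execution order. Returns the endpoint table as
    a DataFrame (one row per EndpointRecord).
    """
    env = make_environment(env)
    records = []
    for p in range(n_participants):
        for cond, protocol in protocols.items():
            for t in range(trials_per_condition):
                seed = trial_seed(base_seed, p, cond, t)
                records.append(
                    run_trial(
                        env, protocol, params, ablation, seed,
                        weights, config, participant_id=p, trial_id=t,
                    )
                )
    return pd.DataFrame([vars(r) for r in records])


def sample_noise_parameters(
    ranges: dict[str, tuple[float, float]], rng: np.random.Generator
) -> NoiseParams:
    """Uniform draw of a noise parameter set for sensitivity sweeps.

    ``ranges`` maps parameter names (alpha1..alpha4, sigma_r_min, sigma_r_max,
    sigma_psi_min, sigma_psi_max, delta_xy) to (low, high) bounds; missing
    parameters default to zero.
    """
    def draw(name):
        lo, hi = ranges.get(name, (0.0, 0.0))
        if hi < lo:
            raise ValueError(f"invalid range for {name}")
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    r_pair = sorted([draw("sigma_r_min"), draw("sigma_r_max")])
    psi_pair = sorted([draw("sigma_psi_min"), draw("sigma_psi_max")])
    return NoiseParams(
        motor=MotorNoise(*(draw(f"alpha{i}") for i in (1, 2, 3, 4))),
        observation=ObservationNoise(*r_pair, *psi_pair),
        representation=RepresentationNoise(draw("delta_xy")),
    )
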