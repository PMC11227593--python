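"""Belief-space planning: soft visibility, cost, NLP solution, MPC loop."""

import numpy as np
import pytest

from navactor.belief_filter import BeliefState, ekf_correct, pose_uncertainty
from navactor.env_model import (
    ControlInput,
    FieldOfView,
    MotorNoise,
    Observation,
    ObservationNoise,
    WorldState,
    visible,
)
from navactor.params import NoiseParams
from navactor.belief_filter import RepresentationNoise
from navactor.planner import (
    CostWeights,
    PlannerConfig,
    goal_reached,
    mpc_run,
    plan_trajectory,
    propagate_planning_belief,
    reorient,
    soft_visibility,
    total_cost,
)
from conftest import make_belief_with_landmarks

FOV = FieldOfView(half_angle=np.pi / 2)


def _belief_one_goal(goal=(0.0, 3.0), pose=(0.0, 0.0, np.pi / 2), pose_cov=1e-4):
    return make_belief_with_landmarks(pose, [list(goal)], pose_cov=pose_cov)


class TestSoftVisibility:
    def test_boundary_is_half(self):
        # landmark exactly on the angular boundary: signed distance 0
        b = _belief_one_goal(goal=(3.0, 0.0), pose=(0.0, 0.0, np.pi / 2))
        assert soft_visibility(b.mu, 0, FOV, a=5.0) == pytest.approx(0.5)

    def test_sharp_limit_matches_hard_indicator(self):
        for goal, pose in [((0.0, 3.0), (0, 0, np.pi / 2)), ((-2.0, -1.0), (0, 0, 0))]:
            b = _belief_one_goal(goal=goal, pose=pose)
            world = WorldState(*pose, map=[list(goal)])
            w = soft_visibility(b.mu, 0, FOV, a=1e4)
            assert round(w) == int(visible(world, 0, FOV))

    def test_monotone_in_signed_distance(self):
        # rotating the landmark outward decreases the weight
        weights = []
        for ang in np.linspace(0.0, np.pi, 7):
            b = _belief_one_goal(goal=(3 * np.cos(ang), 3 * np.sin(ang)), pose=(0, 0, 0))
            weights.append(soft_visibility(b.mu, 0, FOV, a=3.0))
        assert all(w2 <= w1 + 1e-12 for w1, w2 in zip(weights, weights[1:]))


class TestPropagatePlanningBelief:
    def setup_method(self):
        self.noise = NoiseParams(
            MotorNoise(0.2, 0.05, 0.05, 0.2),
            ObservationNoise(0.05, 0.1, 0.05, 0.1),
            RepresentationNoise(0.005),
        )
        self.config = PlannerConfig()

    def test_invisible_landmarks_reduce_to_pure_prediction(self):
        # landmark far behind: Delta ~ 0, covariance evolves as prediction only
        b = make_belief_with_landmarks((0, 0, 0), [[-50.0, 0.0]], pose_cov=0.01)
        u = np.tile([1.0, 0.0], (4, 1))
        mus, sigmas = propagate_planning_belief(
            b, u, self.config, self.noise, FOV, a=50.0
        )
        from navactor.belief_filter import ekf_predict

        bb = b
        for row in u:
            bb = ekf_predict(
                bb, ControlInput(*row), self.config.dt, self.noise.motor,
                self.noise.representation,
            )
        np.testing.assert_allclose(sigmas[-1], bb.sigma, atol=1e-6)

    def test_full_visibility_matches_ekf_zero_innovation(self):
        # Delta = identity: covariance equals the EKF correction at the mean
        b = make_belief_with_landmarks((0, 0, np.pi / 2), [[0.0, 4.0]], pose_cov=0.01)
        u = np.zeros((1, 2))
        mus, sigmas = propagate_planning_belief(
            b, u, self.config, self.noise, FOV, a=1e6
        )
        from navactor.belief_filter import ekf_predict

        bb = ekf_predict(
            b, ControlInput(0, 0), self.config.dt, self.noise.motor,
            self.noise.representation,
        )
        dx, dy = bb.mu[3] - bb.mu[0], bb.mu[4] - bb.mu[1]
        obs = Observation(0, np.hypot(dx, dy), np.arctan2(dy, dx) - bb.mu[2])
        bb = ekf_correct(bb, [obs], self.noise.observation)
        np.testing.assert_allclose(sigmas[-1], bb.sigma, atol=1e-8)
        np.testing.assert_allclose(mus[-1][:3], bb.mu[:3], atol=1e-8)

    def test_partial_visibility_between_extremes(self):
        b = make_belief_with_landmarks((0, 0, np.pi / 2), [[0.0, 4.0]], pose_cov=0.01)
        u = np.zeros((1, 2))

        def final_trace(a):
            _, sigmas = propagate_planning_belief(b, u, self.config, self.noise, FOV, a=a)
            return np.trace(sigmas[-1])

        full = final_trace(1e6)  # fully visible (landmark dead ahead)
        # off-axis landmark just outside a narrow fov: partial weight at soft
        # steepness, zero weight at sharp steepness
        b_off = make_belief_with_landmarks(
            (0, 0, np.pi / 2), [[0.4, 4.0]], pose_cov=0.01
        )
        fov_edge = FieldOfView(half_angle=0.05)
        _, sig_partial = propagate_planning_belief(
            b_off, u, self.config, self.noise, fov_edge, a=2.0
        )
        partial = np.trace(sig_partial[-1])
        _, sig_pred = propagate_planning_belief(
            b_off, u, self.config, self.noise, fov_edge, a=1e9
        )
        none = np.trace(sig_pred[-1])
        assert full <= partial <= none + 1e-12
        assert partial < none  # the soft weight does buy some correction


class TestTotalCost:
    def test_all_zero_at_goal(self):
        n = 5
        mu = np.array([1.0, 2.0, 0.0, 1.0, 2.0])  # pose at believed goal
        mus = np.tile(mu, (3, 1))
        sigmas = np.zeros((3, n, n))
        us = np.zeros((2, 2))
        assert total_cost(mus, sigmas, us, CostWeights(), 0) == 0.0

    def test_goal_term_linear_in_w1(self):
        mus = np.array([[0.0, 0.0, 0.0, 2.0, 1.0]])
        sigmas = np.zeros((1, 5, 5))
        us = np.zeros((0, 2)).reshape(0, 2)
        w1 = CostWeights(w1=1.0, w2=0, w3=0, w4=0)
        w2 = CostWeights(w1=2.0, w2=0, w3=0, w4=0)
        c1 = total_cost(mus, sigmas, np.zeros((1, 2)), w1, 0)
        c2 = total_cost(mus, sigmas, np.zeros((1, 2)), w2, 0)
        assert c2 == pytest.approx(2 * c1)
        assert c1 == pytest.approx(5.0)  # (2^2 + 1^2) under Cq = I

    def test_manual_two_step_evaluation(self):
        """Hand-evaluated two-step sequence against the printed cost terms."""
        mus = np.array(
            [
                [0.0, 0.0, 0.0, 1.0, 0.0],
                [0.5, 0.0, 0.1, 1.0, 0.0],
                [1.0, 0.0, 0.2, 1.0, 0.0],
            ]
        )
        sigmas = np.zeros((3, 5, 5))
        sigmas[1, 0, 0] = 0.1  # pose block trace 0.1 at t=1
        sigmas[2, 3, 3] = 0.2  # map block trace 0.2 at t=2
        us = np.array([[1.0, 0.5], [0.5, -0.5]])
        weights = CostWeights(
            w1=1.0, w2=2.0, w3=3.0, w4=4.0,
            cq=np.eye(2), cr=np.diag([0.1, 0.2]), c_tr=0.5,
        )
        # goal: (0-1)^2 + (0.5-1)^2 + (1-1)^2 = 1 + 0.25 + 0 = 1.25
        # pose-unc: 0.1 ; map-unc: 0.2
        # control: [0.1*1 + 0.2*0.25 + 0.5*(0.5)^2] + [0.1*0.25 + 0.2*0.25 + 0.5*(0.25)^2]
        ctrl = (0.1 * 1 + 0.2 * 0.25 + 0.5 * 0.25) + (
            0.1 * 0.25 + 0.2 * 0.25 + 0.5 * 0.0625
        )
        expected = 1.0 * 1.25 + 2.0 * 0.1 + 3.0 * 0.2 + 4.0 * ctrl
        got = total_cost(mus, sigmas, us, weights, 0)
        assert got == pytest.approx(expected, abs=1e-12)


class TestPlanTrajectory:
    def setup_method(self):
        self.noise = NoiseParams.zero()
        self.config = PlannerConfig()
        self.weights = CostWeights(w2=0.0, w3=0.0)

    def test_reaches_visible_goal_straight_ahead(self):
        b = _belief_one_goal(goal=(0.0, 2.0))
        config = PlannerConfig(T=10, N=2)
        plan = plan_trajectory(b, 0, self.weights, config, self.noise, FOV)
        final = plan.mu_sequence[-1]
        assert np.hypot(final[0] - 0.0, final[1] - 2.0) < config.goal_tolerance
        # path length close to the straight-line lower bound
        steps = np.diff(plan.mu_sequence[:, :2], axis=0)
        path_len = np.linalg.norm(steps, axis=1).sum()
        assert path_len < 2.0 * 1.05

    def test_goal_behind_starts_with_rotation(self):
        b = _belief_one_goal(goal=(0.0, -3.0), pose=(0.0, 0.0, np.pi / 2))
        plan = plan_trajectory(b, 0, self.weights, self.config, self.noise, FOV)
        assert np.abs(plan.u_sequence[:2, 1]).max() > 0.1

    def test_bounds_respected(self):
        b = _belief_one_goal(goal=(5.0, 5.0))
        config = PlannerConfig(T=8, N=2)
        plan = plan_trajectory(b, 0, CostWeights(), config,
                               NoiseParams.zero(), FOV)
        v, w = plan.u_sequence[:, 0], plan.u_sequence[:, 1]
        assert np.all(v >= config.v_bounds[0] - 1e-9)
        assert np.all(v <= config.v_bounds[1] + 1e-9)
        assert np.all(w >= config.w_bounds[0] - 1e-9)
        assert np.all(w <= config.w_bounds[1] + 1e-9)

    def test_objective_never_worse_than_zero_control(self):
        noise = NoiseParams(
            MotorNoise(0.2, 0.05, 0.05, 0.2),
            ObservationNoise(0.05, 0.1, 0.05, 0.1),
            RepresentationNoise(0.005),
        )
        for goal in [(2.0, 1.0), (-1.0, -2.0), (0.0, 4.0)]:
            b = _belief_one_goal(goal=goal, pose_cov=0.01)
            plan = plan_trajectory(b, 0, CostWeights(), PlannerConfig(), noise, FOV)
            mus, sigmas = propagate_planning_belief(
                b, np.zeros((PlannerConfig().T, 2)), PlannerConfig(), noise, FOV
            )
            zero_cost = total_cost(
                mus, sigmas, np.zeros((PlannerConfig().T, 2)), CostWeights(), 0
            )
            assert plan.objective_value <= zero_cost + 1e-9

    def test_uncertainty_weight_reduces_terminal_pose_uncertainty(self):
        """With a landmark off the direct path, penalizing pose uncertainty
        yields plans whose terminal pose covariance is no larger."""
        noise = NoiseParams(
            MotorNoise(0.3, 0.05, 0.05, 0.3),
            ObservationNoise(0.05, 0.1, 0.05, 0.1),
            RepresentationNoise(0.0),
        )
        fov = FieldOfView(half_angle=np.deg2rad(40))
        # goal ahead, landmark off to the side
        b = make_belief_with_landmarks(
            (0, 0, np.pi / 2), [[3.0, 2.0], [0.0, 4.0]], pose_cov=0.05
        )
        config = PlannerConfig(T=8)

        def terminal_pose_trace(w2):
            weights = CostWeights(w1=1.0, w2=w2, w3=0.0, w4=0.05)
            plan = plan_trajectory(b, 1, weights, config, noise, fov)
            return np.trace(plan.predicted_sigma_sequence[-1][:3, :3])

        assert terminal_pose_trace(5.0) <= terminal_pose_trace(0.0) + 1e-9


class TestGoalReached:
    def test_boundary_conventions(self):
        b = _belief_one_goal(goal=(0.0, 3.0), pose=(0.0, 0.0, np.pi / 2))
        assert not goal_reached(b, 0, 1.0)
        b2 = _belief_one_goal(goal=(0.0, 1.0), pose=(0.0, 0.0, np.pi / 2))
        assert goal_reached(b2, 0, 1.0)  # exactly at tolerance: closed
        b3 = _belief_one_goal(goal=(0.0, 1.0001), pose=(0.0, 0.0, np.pi / 2))
        assert not goal_reached(b3, 0, 1.0)

    def test_uninitialized_goal_not_reached(self):
        b = BeliefState.initial(np.zeros(3), 1)
        assert not goal_reached(b, 0, 10.0)


class TestMpcRun:
    def test_noiseless_closed_loop_hits_goal(self):
        world = WorldState(0, 0, np.pi / 2, map=[[1.0, 3.0]])
        b = _belief_one_goal(goal=(1.0, 3.0))
        config = PlannerConfig()
        world, b, log = mpc_run(
            world, b, 0, CostWeights(w2=0, w3=0), config, NoiseParams.zero(),
            np.random.default_rng(0), FOV, observable=np.array([True]),
        )
        assert not log.truncated
        assert np.hypot(world.x - 1.0, world.y - 3.0) < 2 * config.goal_tolerance

    def test_same_seed_bit_identical_logs(self):
        noise = NoiseParams(
            MotorNoise(0.15, 0.05, 0.05, 0.15),
            ObservationNoise(0.05, 0.1, 0.05, 0.1),
            RepresentationNoise(0.002),
        )

        def run(seed):
            world = WorldState(0, 0, np.pi / 2, map=[[1.0, 3.0]])
            b = _belief_one_goal(goal=(1.0, 3.0))
            _, _, log = mpc_run(
                world, b, 0, CostWeights(), PlannerConfig(), noise,
                np.random.default_rng(seed), FOV, observable=np.array([True]),
            )
            return log.to_dataframe()

        df1, df2 = run(42), run(42)
        assert df1.equals(df2)
        assert not df1.equals(run(43))

    def test_motor_noise_scatter_increases_with_alpha(self):
        """No landmarks: endpoint scatter over seeds grows with motor noise."""
        def endpoint_sd(scale, n=25):
            pts = []
            noise = NoiseParams(
                MotorNoise(0.1 * scale, 0.02 * scale, 0.02 * scale, 0.1 * scale),
                ObservationNoise(),
                RepresentationNoise(0.0),
            )
            for seed in range(n):
                world = WorldState(0, 0, np.pi / 2, map=[[0.0, 3.0]])
                b = _belief_one_goal(goal=(0.0, 3.0))
                world, _, _ = mpc_run(
                    world, b, 0, CostWeights(w2=0, w3=0), PlannerConfig(), noise,
                    np.random.default_rng(seed), FOV,
                    observable=np.array([False]),
                )
                pts.append([world.x, world.y])
            pts = np.asarray(pts)
            return np.linalg.norm(pts - pts.mean(0), axis=1).std()

        sd1, sd2 = endpoint_sd(1.0), endpoint_sd(3.0)
        assert 0.0 < sd1 < sd2


class TestReorient:
    def _noise(self):
        return NoiseParams(
            MotorNoise(0.1, 0.02, 0.02, 0.1),
            ObservationNoise(0.05, 0.1, 0.05, 0.1),
            RepresentationNoise(0.0),
        )

    def test_landmark_already_visible_immediate_correction(self):
        import dataclasses

        world = WorldState(0, 0, np.pi / 2, map=[[0.0, 4.0]])
        # well-known landmark, then pose uncertainty inflated (as after
        # disorientation) so the observation is genuinely informative
        b = make_belief_with_landmarks((0, 0, np.pi / 2), [[0.0, 4.0]], pose_cov=1e-6)
        sigma = b.sigma.copy()
        sigma[0, 0] += 0.1
        sigma[1, 1] += 0.1
        sigma[2, 2] += 0.3
        b = dataclasses.replace(b, sigma=sigma)
        w0, b0, log, saw = reorient(
            world, b, PlannerConfig(), self._noise(), np.random.default_rng(0),
            FOV, observable=np.array([True]),
        )
        assert saw
        assert w0.theta == world.theta  # no rotation happened
        assert pose_uncertainty(b0) < pose_uncertainty(b)

    def test_landmark_behind_is_acquired_by_sweep(self):
        # agent truly faces away; belief knows roughly where the landmark is
        world = WorldState(0, 0, -np.pi / 2, map=[[0.0, 4.0]])
        b = make_belief_with_landmarks((0, 0, -np.pi / 2), [[0.0, 4.0]], pose_cov=0.1)
        w0, b0, log, saw = reorient(
            world, b, PlannerConfig(), self._noise(), np.random.default_rng(0),
            FOV, observable=np.array([True]),
        )
        assert saw
        assert len(log.rows) > 1  # it had to turn

    def test_no_observable_landmark_returns_after_budget(self):
        world = WorldState(0, 0, 0, map=[[4.0, 0.0]])
        b = make_belief_with_landmarks((0, 0, 0), [[-4.0, 0.0]], pose_cov=0.1)
        config = PlannerConfig()
        w0, b0, log, saw = reorient(
            world, b, config, self._noise(), np.random.default_rng(0),
            FOV, observable=np.array([False]),  # landmarks removed
        )
        assert not saw
        # belief changed only by the predicted rotation: position mean intact
        np.testing.assert_allclose(b0.mu[:2], b.mu[:2], atol=1e-12)
        assert len(log.rows) > 10
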