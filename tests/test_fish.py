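"""Fish direction-choice model: grouping, perception, social switching,
robot controllers, and the robot-free reduction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biohybrid.core import NoiseStream, SimulationClock, run_replicate
from biohybrid.fish import (
    FishModel,
    FishObservation,
    FishParams,
    RandomSwitchingRobot,
    fish_derivatives,
    grouping_probability,
    individual_switch_flows,
    perceive,
    robot_decide,
    robot_track_fish,
    social_switch_flows,
)


def perceive_robot_free(f_cw, f_ccw, sigma, x_cw, x_ccw):
    """Independent oracle: the robot-free perception equations written out
    directly (errors built on F only, self term subtracted)."""
    e_ccw_by_cw = sigma * (f_cw - 1.0) * x_cw
    e_cw_by_cw = sigma * f_ccw * x_ccw
    e_ccw_by_ccw = sigma * f_cw * x_cw
    e_cw_by_ccw = sigma * (f_ccw - 1.0) * x_ccw
    return (
        f_cw + e_cw_by_cw - e_ccw_by_cw,
        f_ccw - e_cw_by_cw + e_ccw_by_cw,
        f_cw + e_cw_by_ccw - e_ccw_by_ccw,
        f_ccw - e_cw_by_ccw + e_ccw_by_ccw,
    )


class TestGrouping:
    def test_six_fish_never_alone(self):
        p_group, p_alone = grouping_probability(FishParams(f_total=6.0, n_robots=0))
        assert p_group == 1.0 and p_alone == 0.0

    def test_two_fish_partial_grouping(self):
        p_group, _ = grouping_probability(FishParams(f_total=2.0, n_robots=0))
        assert p_group == pytest.approx(0.4)

    def test_robot_counts_towards_grouping(self):
        p = FishParams(f_total=5.0, n_robots=1, gamma_fish=1.0)
        p_group, _ = grouping_probability(p)
        assert p_group == 1.0  # (5 + 1) * 0.2 clamped

    def test_individual_flow_arithmetic(self):
        # alpha * p_alone * F_CCW with p_alone = 0.5: 0.01 * 0.5 * 4 = 0.02
        p = FishParams(alpha_fish=0.01, f_total=2.5, sight_ratio=0.2, n_robots=0)
        into_cw, _ = individual_switch_flows(0.0, 4.0, p)
        assert into_cw == pytest.approx(0.01 * (1 - 2.5 * 0.2) * 4.0)

    def test_crowded_arena_no_individual_switching(self):
        p = FishParams(f_total=6.0)
        assert individual_switch_flows(3.0, 3.0, p) == (0.0, 0.0)


class TestPerception:
    def test_noise_free_is_exact(self):
        p = FishParams(sigma_fish=0.0, f_total=5.0, n_robots=1, gamma_fish=0.8)
        obs = perceive(4.0, 1.0, 1.0, p, 0.3, 0.7, 0.2, 0.9)
        assert obs.obs_cw_by_cw == pytest.approx(4.0 + 0.8)
        assert obs.obs_ccw_by_cw == pytest.approx(1.0)

    def test_robot_free_reduction_is_bitwise(self):
        """With gamma = 0 and no robots the general equations reduce exactly
        to the robot-free forms."""
        p = FishParams(sigma_fish=0.3, f_total=5.0, n_robots=0, gamma_fish=0.0)
        rng = np.random.default_rng(0)
        for _ in range(200):
            f_cw = rng.uniform(0.0, 5.0)
            x = rng.random(2)
            obs = perceive(f_cw, 5.0 - f_cw, 0.0, p, x[0], x[1], x[0], x[1])
            oracle = perceive_robot_free(f_cw, 5.0 - f_cw, 0.3, x[0], x[1])
            assert obs.obs_cw_by_cw == max(0.0, oracle[0])
            assert obs.obs_ccw_by_cw == max(0.0, oracle[1])
            assert obs.obs_cw_by_ccw == max(0.0, oracle[2])
            assert obs.obs_ccw_by_ccw == max(0.0, oracle[3])

    @given(
        f_cw=st.floats(0, 5),
        r_cw=st.floats(0, 1),
        draws=st.tuples(*[st.floats(0, 1)] * 4),
    )
    @settings(max_examples=300, deadline=None)
    def test_perceived_counts_nonnegative_at_defaults(self, f_cw, r_cw, draws):
        p = FishParams(f_total=5.0, n_robots=1)  # sigma_fish = 0.3 default
        obs = perceive(f_cw, 5.0 - f_cw, r_cw, p, *draws)
        assert min(
            obs.obs_cw_by_cw, obs.obs_ccw_by_cw, obs.obs_cw_by_ccw, obs.obs_ccw_by_ccw
        ) >= 0.0


class TestSocialFlows:
    def test_consensus_is_social_fixed_point(self):
        p = FishParams(f_total=5.0, n_robots=0, gamma_fish=0.0)
        obs = perceive(5.0, 0.0, 0.0, p, 0.5, 0.5, 0.5, 0.5)
        into_cw, _ = social_switch_flows(5.0, 0.0, 0.0, obs, p)
        assert into_cw == 0.0

    def test_flow_arithmetic(self):
        # beta * p_group * F_CCW * obsCW / (obsCCW + 1) = 0.05 * 1 * 2 * 4/2
        p = FishParams(beta_fish=0.05, f_total=6.0, n_robots=0)
        obs = FishObservation(
            obs_cw_by_cw=0.0, obs_ccw_by_cw=0.0, obs_cw_by_ccw=4.0, obs_ccw_by_ccw=1.0
        )
        into_cw, _ = social_switch_flows(4.0, 2.0, 0.0, obs, p)
        assert into_cw == pytest.approx(0.2)

    def test_robot_alone_can_seed_counterflow(self):
        # full fish consensus CW, one accepted robot swimming CCW: the social
        # term still moves weight towards CW's opposite
        p = FishParams(f_total=5.0, n_robots=1, gamma_fish=1.0, sigma_fish=0.0)
        obs = perceive(5.0, 0.0, 0.0, p, 0.0, 0.0, 0.0, 0.0)
        _, into_ccw = social_switch_flows(5.0, 0.0, 0.0, obs, p)
        assert into_ccw > 0.0

    def test_robots_bias_balanced_shoal(self):
        # robots constantly CW from a 50:50 start push the net flow CW-ward
        p = FishParams(f_total=3.0, n_robots=3, gamma_fish=0.7, sigma_fish=0.0)
        obs = perceive(1.5, 1.5, 1.0, p, 0.0, 0.0, 0.0, 0.0)
        d_cw, d_ccw = fish_derivatives(1.5, 1.5, 1.0, obs, p)
        assert d_cw > 0.0 and d_cw + d_ccw == 0.0

    @given(f_cw=st.floats(0, 5), r_cw=st.floats(0, 1), x=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_conservation_exact(self, f_cw, r_cw, x):
        p = FishParams(f_total=5.0, n_robots=1)
        obs = perceive(f_cw, 5.0 - f_cw, r_cw, p, x, x, x, x)
        d_cw, d_ccw = fish_derivatives(f_cw, 5.0 - f_cw, r_cw, obs, p)
        assert d_cw + d_ccw == 0.0


class TestRobotTracking:
    def test_noise_free_exact_proportions(self):
        p = FishParams(f_total=5.0, sigma_fishrobot=0.0)
        prop_cw, prop_ccw = robot_track_fish(4.0, 1.0, p, 0.5, 0.5)
        assert prop_cw == pytest.approx(0.8) and prop_ccw == pytest.approx(0.2)

    def test_error_arithmetic(self):
        p = FishParams(f_total=5.0, sigma_fishrobot=0.1)
        prop_cw, _ = robot_track_fish(4.0, 1.0, p, x_cw=0.0, x_ccw=1.0)
        assert prop_cw == pytest.approx(0.82)

    @given(f_cw=st.floats(0, 5), x1=st.floats(0, 1), x2=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_error_proportions_sum_to_one(self, f_cw, x1, x2):
        p = FishParams(f_total=5.0, sigma_fishrobot=0.2)
        prop_cw, prop_ccw = robot_track_fish(f_cw, 5.0 - f_cw, p, x1, x2)
        assert prop_cw + prop_ccw == pytest.approx(1.0, abs=1e-12)


class TestRobotControllers:
    def test_majority_rule(self):
        rng = np.random.default_rng(0)
        assert robot_decide([0.7], rng) == 1.0
        assert robot_decide([0.3], rng) == 0.0

    def test_tie_is_fair_coin(self):
        rng = np.random.default_rng(1)
        draws = {robot_decide([0.5], rng) for _ in range(50)}
        assert draws == {0.0, 1.0}

    def test_never_switching_machine(self):
        robot = RandomSwitchingRobot(p_switch=0.0)
        robot.begin_run(NoiseStream(4))
        states = {robot.decide(t, None) for t in range(100)}
        assert len(states) == 1

    def test_always_switching_machine_alternates(self):
        robot = RandomSwitchingRobot(p_switch=1.0)
        robot.begin_run(NoiseStream(4))
        states = [robot.decide(t, None) for t in range(10)]
        assert all(a != b for a, b in zip(states, states[1:]))

    def test_empirical_switch_frequency(self):
        # 1e5 steps at p = 0.014: within 3 binomial standard errors
        robot = RandomSwitchingRobot(p_switch=0.014)
        robot.begin_run(NoiseStream(12345))
        n = 100_000
        states = [robot.decide(t, None) for t in range(n)]
        switches = sum(a != b for a, b in zip(states, states[1:]))
        freq = switches / (n - 1)
        se = math.sqrt(0.014 * 0.986 / n)
        assert abs(freq - 0.014) < 3 * se


class TestFishModelRuns:
    def test_conservation_every_step(self):
        traj = run_replicate(
            FishModel(FishParams(f_total=5.0, n_robots=1), robot=RandomSwitchingRobot()),
            SimulationClock(1.0, 900.0), 5,
        )
        total = traj["f_cw"] + traj["f_ccw"]
        assert np.max(np.abs(total - 5.0)) < 1e-9

    def test_consensus_exact_fixed_point(self):
        """With no lone fish, no perception noise and no robot, a full
        consensus never decays."""
        model = FishModel(FishParams(f_total=6.0, n_robots=0, sigma_fish=0.0))
        model.begin_run(NoiseStream(0))
        model.f_cw, model.f_ccw = 6.0, 0.0
        for k in range(100):
            model.step(float(k), 1.0)
        assert model.f_cw == 6.0 and model.f_ccw == 0.0

    def test_euler_solver_switch(self):
        t_rk = run_replicate(
            FishModel(FishParams(f_total=6.0), solver="rk4"), SimulationClock(1.0, 200.0), 1
        )
        t_eu = run_replicate(
            FishModel(FishParams(f_total=6.0), solver="euler"), SimulationClock(1.0, 200.0), 1
        )
        assert not np.array_equal(t_rk.data, t_eu.data)

    def test_constant_robots_bias_towards_their_direction(self):
        from biohybrid.presets import run_preset

        _, summary = run_preset("f1_mixed", 12, base_seed=3)
        assert summary["cw_time_budget"].mean() > 0.5
        assert (summary["robot_cw_budget"] == 1.0).all()
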