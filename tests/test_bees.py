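"""Bee aggregation model: resting-time law, flows, CASU thermodynamics,
observation, feedback controllers, and zero-noise oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biohybrid.bees import (
    BeeController,
    BeeModel,
    BeeParams,
    BeeSchedule,
    bee_derivatives,
    casu_thermal_derivatives,
    equilibrium_share,
    feedback_target_update,
    individual_flows,
    observe_bees,
    resting_time,
    social_flows,
)
from biohybrid.core import NoiseStream

from conftest import run_fixed_bee


class TestRestingTime:
    @pytest.mark.parametrize(
        "temp, phi, psi, expected",
        [
            (28.0, 0.0, 0.0, 1.0),    # minimum ambient: 1 s
            (36.0, 0.0, 0.0, 25.0),   # hottest setting: 25 s
            (32.0, 0.0, 0.0, 13.0),   # midpoint of the linear law
            (36.0, 1.0, 0.0, 1.0),    # full airflow cancels the thermal term
            (36.0, 0.0, 1.0, 50.0),   # full vibration doubles resting
        ],
    )
    def test_endpoints_and_stimuli(self, temp, phi, psi, expected):
        assert resting_time(temp, phi, psi, BeeParams()) == pytest.approx(expected)

    def test_below_minimum_temperature_rejected(self):
        with pytest.raises(ValueError, match="t_min"):
            resting_time(27.0, 0.0, 0.0, BeeParams())

    @given(
        temp=st.floats(28.0, 36.0), phi=st.floats(0, 1), psi=st.floats(0, 1)
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_positive(self, temp, phi, psi):
        assert resting_time(temp, phi, psi, BeeParams()) > 0.0


class TestFlows:
    def test_individual_flow_arithmetic(self):
        into_r, _ = individual_flows(0.0, 8.0, 1.0, 4.0, alpha=0.25, x_r=1.0, x_l=1.0)
        assert into_r == pytest.approx(0.5)

    def test_individual_flow_zero_alpha(self):
        assert individual_flows(3.0, 8.0, 1.0, 4.0, 0.0, 1.0, 1.0) == (0.0, 0.0)

    def test_social_flow_arithmetic(self):
        into_r, _ = social_flows(6.0, 6.0, 1.0, 4.0, beta=0.02, x_r=1.0, x_l=1.0)
        assert into_r == pytest.approx(0.18)

    def test_social_flow_vanishes_with_empty_side(self):
        assert social_flows(5.0, 0.0, 2.0, 2.0, 0.05, 1.0, 1.0) == (0.0, 0.0)

    def test_warmer_side_receives_net_flow(self):
        # longer resting on the right (warmer) side => net flow into right
        d_r, d_l = bee_derivatives(6.0, 6.0, tau_r=25.0, tau_l=1.0, params=BeeParams())
        assert d_r > 0.0 and d_l == -d_r

    def test_consensus_outflow_only_individual(self):
        # all bees on the right: social flows vanish, only the individual
        # term drains the right side
        p = BeeParams()
        d_r, _ = bee_derivatives(12.0, 0.0, tau_r=5.0, tau_l=5.0, params=p)
        assert d_r == pytest.approx(-p.alpha_bees * 12.0 / 5.0)

    @given(
        b_r=st.floats(0, 12), tau_r=st.floats(1, 50), tau_l=st.floats(1, 50),
        x1=st.floats(0.1, 1.9), x2=st.floats(0.1, 1.9),
        x3=st.floats(0.1, 1.9), x4=st.floats(0.1, 1.9),
    )
    @settings(max_examples=200, deadline=None)
    def test_conservation_is_exact_term_by_term(self, b_r, tau_r, tau_l, x1, x2, x3, x4):
        d_r, d_l = bee_derivatives(
            b_r, 12.0 - b_r, tau_r, tau_l, BeeParams(), x1, x2, x3, x4
        )
        assert d_r + d_l == 0.0


class TestThermal:
    def test_at_ambient_inside_deadband(self):
        p = BeeParams()
        assert casu_thermal_derivatives(28.0, 28.0, p) == 0.0

    def test_active_heating(self):
        p = BeeParams(
            lambda_passive_cooling=0.01, lambda_active_heating=0.1, epsilon_temp=0.5
        )
        assert casu_thermal_derivatives(30.0, 36.0, p) == pytest.approx(0.08)

    def test_active_cooling(self):
        p = BeeParams(
            lambda_passive_cooling=0.01, lambda_active_cooling=0.1, epsilon_temp=0.5
        )
        assert casu_thermal_derivatives(36.0, 28.0, p) == pytest.approx(-0.18)


class TestObservation:
    def test_perfect_when_noise_free(self):
        p = BeeParams(sigma_beecasu=0.0)
        assert observe_bees(7.0, 5.0, p, 0.9, 0.3) == (7.0, 5.0)

    def test_half_scale_underestimate(self):
        p = BeeParams(sigma_beecasu=0.5)
        obs_r, _ = observe_bees(12.0, 0.0, p, 1.0, 0.0)
        assert obs_r == pytest.approx(6.0)

    @given(b=st.floats(0, 12), x=st.floats(0, 1), sigma=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_one_sided_underestimation(self, b, x, sigma):
        obs_r, _ = observe_bees(b, 0.0, BeeParams(sigma_beecasu=sigma), x, 0.0)
        assert 0.0 <= obs_r <= b


class TestFeedbackTargets:
    def test_positive_mode_steps_crowded_side_up(self):
        p = BeeParams(delta_temp=1.0)
        tgt_r, tgt_l = feedback_target_update(8.0, 4.0, 30.0, 30.0, "positive", p)
        assert tgt_r == 31.0 and tgt_l == 29.0

    def test_negative_mode_inverts(self):
        p = BeeParams(delta_temp=1.0)
        tgt_r, tgt_l = feedback_target_update(8.0, 4.0, 30.0, 30.0, "negative", p)
        assert tgt_r == 29.0 and tgt_l == 31.0

    def test_targets_clamped_to_range(self):
        p = BeeParams(delta_temp=1.0)
        tgt_r, tgt_l = feedback_target_update(8.0, 4.0, 36.0, 28.0, "positive", p)
        assert tgt_r == 36.0 and tgt_l == 28.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            feedback_target_update(1.0, 2.0, 30.0, 30.0, "bananas", BeeParams())


class TestZeroNoiseOracles:
    def test_symmetric_run_stays_exactly_symmetric(self, quiet_bee_params):
        traj = run_fixed_bee(quiet_bee_params, 28.0, 28.0, 600.0)
        assert np.max(np.abs(traj["b_r"] - traj["b_l"])) < 1e-9

    def test_conservation_at_every_step(self, quiet_bee_params):
        traj = run_fixed_bee(quiet_bee_params, 36.0, 32.0, 600.0)
        total = traj["b_r"] + traj["b_l"]
        assert np.max(np.abs(total - quiet_bee_params.b_total)) < 1e-9

    def test_equilibrium_matches_algebraic_solution(self, quiet_bee_params):
        traj = run_fixed_bee(quiet_bee_params, 36.0, 32.0, 5000.0)
        tau_r = resting_time(36.0, 0.0, 0.0, quiet_bee_params)
        tau_l = resting_time(32.0, 0.0, 0.0, quiet_bee_params)
        b_star = equilibrium_share(tau_r, tau_l, quiet_bee_params)
        assert traj["b_r"][-1] == pytest.approx(b_star, abs=1e-6)
        # and the warm side holds the clear majority
        assert b_star > 0.5 * quiet_bee_params.b_total

    def test_equilibrium_share_monotone_in_stimuli(self, quiet_bee_params):
        """Raising T on one side never lowers its share; airflow there never
        raises it; vibration there never lowers it."""
        def final_share(t_r, phi_r=0.0, psi_r=0.0):
            traj = run_fixed_bee(
                quiet_bee_params, t_r, 30.0, 3000.0, phi_r=phi_r, psi_r=psi_r
            )
            return traj["b_r"][-1]

        base = final_share(32.0)
        assert final_share(34.0) >= base - 1e-9          # warmer attracts
        assert final_share(32.0, phi_r=0.5) <= base + 1e-9   # airflow repels
        assert final_share(32.0, psi_r=0.5) >= base - 1e-9   # vibration retains


class TestFeedbackRegimes:
    def test_positive_feedback_heats_crowded_side(self):
        """With all bees placed on one side, positive feedback drives that
        CASU hot and the opposite one stays at ambient."""
        model = BeeModel(
            params=BeeParams(sigma_beecasu=0.0),
            schedule=BeeSchedule(),
            controller=BeeController(mode="positive"),
        )
        model.begin_run(NoiseStream(0))
        model.b_r, model.b_l = 12.0, 0.0
        for k in range(400):
            model.step(float(k), 1.0)
        assert model.t_r > 34.0
        assert model.t_l == pytest.approx(28.0, abs=0.5)
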