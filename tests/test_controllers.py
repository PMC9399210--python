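"""Controller laws: forward VCC estimate, feedback update, single prediction."""

import math
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfusim import (
    ControllerFault,
    ControllerState,
    ProcessParameters,
    advance_biomass,
    estimate_vcc_forward,
    fc_update,
    simulate_iteration,
    spc_cost,
    spc_update,
)
from perfusim.controllers import run_control_cycle
from perfusim.process_model import PlantState, close_mass_balance


class TestEstimateVccForward:
    def test_grouped_survival_times_growth(self):
        # 40 * (1 - 0.25*2/10) * e^{0.05} = 39.948
        got = estimate_vcc_forward(40.0, 2.0, 0.2, 0.25, 10.0)
        assert got == pytest.approx(40.0 * 0.95 * math.exp(0.05), rel=1e-12)
        assert got == pytest.approx(39.948, abs=5e-4)
        # within 0.2 % of the exact plant propagator (steady state: 40.0)
        assert got == pytest.approx(advance_biomass(40.0, 0.2, 0.2, 0.25), rel=2e-3)

    def test_identity_without_bleed_or_growth(self):
        assert estimate_vcc_forward(40.0, 0.0, 0.0, 0.25, 10.0) == 40.0

    def test_coincides_with_plant_at_zero_bleed(self):
        assert estimate_vcc_forward(40.0, 0.0, 0.2, 1.0, 10.0) == pytest.approx(
            advance_biomass(40.0, 0.2, 0.0, 1.0), rel=1e-12
        )

    def test_literal_reading_differs_and_lacks_fixed_point(self):
        grouped = estimate_vcc_forward(40.0, 2.0, 0.2, 0.25, 10.0)
        literal = estimate_vcc_forward(40.0, 2.0, 0.2, 0.25, 10.0, literal=True)
        assert literal != pytest.approx(grouped, rel=1e-6)
        assert literal < 40.0 * 0.999  # steady bleed decays under the literal form

    def test_overbleed_faults(self):
        with pytest.raises(ControllerFault):
            estimate_vcc_forward(40.0, 50.0, 0.2, 0.25, 10.0)


class TestFcUpdate:
    def test_zero_error_keeps_command(self):
        assert fc_update(40.0, 40.0, 10.0, 0.25, 2.0) == 2.0

    @pytest.mark.parametrize(
        "x_m, expected",
        [(41.0, 1.0 * (10.0 / 41.0) / 0.25 + 2.0), (39.0, -(10.0 / 39.0) / 0.25 + 2.0)],
    )
    def test_error_term(self, x_m, expected):
        assert fc_update(x_m, 40.0, 10.0, 0.25, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_floored_at_zero(self):
        assert fc_update(30.0, 40.0, 10.0, 0.25, 0.0) == 0.0

    def test_zero_measurement_faults(self):
        with pytest.raises(ControllerFault):
            fc_update(0.0, 40.0, 10.0, 0.25, 2.0)


class TestSpcUpdate:
    def test_printed_law_at_set_point(self):
        b, diag = spc_update(40.0, 40.0, 0.2, 0.5, 10.0)
        assert diag.x_pred == pytest.approx(40.0 * math.exp(0.1), rel=1e-12)
        assert diag.x_diff == pytest.approx(diag.x_pred - 40.0)
        # 1.903 ~ mu*Vr = 2.0: near the steady-state bleed
        assert b == pytest.approx((diag.x_diff / 0.5) * (10.0 / diag.x_pred), rel=1e-12)
        assert b == pytest.approx(1.903, abs=5e-4)

    def test_printed_law_static_overshoot(self):
        b, diag = spc_update(44.0, 40.0, 0.0, 0.5, 10.0)
        assert diag.x_pred == 44.0
        assert b == pytest.approx((4.0 / 0.5) * (10.0 / 44.0), rel=1e-12)  # 1.818

    def test_on_target_without_growth_commands_nothing(self):
        b, diag = spc_update(40.0, 40.0, 0.0, 0.5, 10.0)
        assert b == 0.0 and diag.x_diff == 0.0

    def test_small_horizon_limit_recovers_steady_bleed(self):
        b, _ = spc_update(40.0, 40.0, 0.2, 1e-6, 10.0)
        assert b == pytest.approx(0.2 * 10.0, rel=1e-6)

    def test_hold_bleed_increment_has_exact_fixed_point(self):
        b, diag = spc_update(
            40.0, 40.0, 0.2, 0.5, 10.0, b_prev=2.0,
            prediction="hold_bleed", mode="increment",
        )
        assert diag.x_pred == pytest.approx(40.0, rel=1e-12)
        assert b == pytest.approx(2.0, rel=1e-12)

    @given(
        x_m=st.floats(5.0, 100.0),
        mu=st.floats(0.0, 0.4),
        b_prev=st.floats(0.0, 4.0),
        prediction=st.sampled_from(["zero_bleed", "hold_bleed"]),
        mode=st.sampled_from(["replace", "increment"]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_command_never_negative(self, x_m, mu, b_prev, prediction, mode):
        b, diag = spc_update(
            x_m, 40.0, mu, 0.5, 10.0, b_prev=b_prev, prediction=prediction, mode=mode
        )
        assert b >= 0.0
        assert diag.x_diff == diag.x_pred - 40.0


class TestSpcCost:
    @pytest.mark.parametrize(
        "x_diff, du, r, expected",
        [(4.0, [0.5], 5.0, 5.25), (4.0, [], 5.0, 4.0), (0.0, [1.0, -1.0], 5.0, 10.0)],
    )
    def test_cost_values(self, x_diff, du, r, expected):
        assert spc_cost(x_diff, du, r) == pytest.approx(expected)


class TestRunControlCycle:
    def test_thirty_days_gives_120_cycles(self):
        p = ProcessParameters(controller="FC", noise_cv=0.0)
        tr = simulate_iteration(p, 0)
        assert len(tr.frame) - 1 == p.n_control_steps == 120

    def test_zero_noise_spc_command_constant(self):
        p = ProcessParameters(controller="SPC", noise_cv=0.0, duration=5.0)
        tr = simulate_iteration(p, 0)
        b = tr.values("b_m_Lday")
        assert abs(b - b[0]).max() < 1e-6

    def test_zero_noise_fc_holds_set_point(self):
        p = ProcessParameters(controller="FC", noise_cv=0.0, duration=5.0)
        tr = simulate_iteration(p, 0)
        assert abs(tr.values("X_MVCml") - 40.0).max() < 1e-9

    def test_faulted_cycle_holds_previous_command(self):
        p = ProcessParameters(controller="FC", noise_cv=0.0)
        flows = close_mass_balance("A", 2.0, 0.2, 0.4, 10.0)
        plant = PlantState(t=0.0, x=0.0, c=0.4, flows=flows,
                           mu_current=0.2, qp_current=20.0)
        ctrl = ControllerState(x_m=40.0, b_m=2.0)
        run_control_cycle(plant, ctrl, p)  # X=0 faults the feedback law
        assert ctrl.b_m == 2.0

    def test_zero_order_hold_between_cycles(self):
        p = ProcessParameters(controller="SPC", duration=2.0, store_interval=0.05,
                              seed=3)
        tr = simulate_iteration(p, 3)
        f = tr.frame
        # within each 6-h interval the commanded rate must not change
        interval = (f["t_days"] // p.pui).astype(int)
        # the boundary row itself starts the next interval's command
        per = f.groupby(interval)["b_m_Lday"].nunique()
        assert (per == 1).all()
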