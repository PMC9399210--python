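"""Plant-model unit and property tests: growth, product, flow allocation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from perfusim import (
    ConfigurationError,
    FlowRates,
    InvalidArgumentError,
    ProcessParameters,
    advance_biomass,
    advance_product,
    close_mass_balance,
)


class TestAdvanceBiomass:
    @pytest.mark.parametrize(
        "x, mu, b, dt, expected",
        [
            (40.0, 0.2, 0.2, 0.25, 40.0),  # steady state: apparent growth zero
            (40.0, 0.2, 0.0, 1.0, 40.0 * math.exp(0.2)),  # 48.856: pure growth
            (40.0, 0.0, 0.2, 1.0, 40.0 * math.exp(-0.2)),  # 32.749: pure bleed
        ],
    )
    def test_closed_form(self, x, mu, b, dt, expected):
        assert advance_biomass(x, mu, b, dt) == pytest.approx(expected, rel=1e-12)

    def test_negative_dt_rejected(self):
        with pytest.raises(InvalidArgumentError):
            advance_biomass(40.0, 0.2, 0.2, -0.1)

    @pytest.mark.parametrize("mu, b", [(0.2, 0.0), (0.0, 0.2), (0.3, 0.12), (0.25, 0.25)])
    def test_against_ode_oracle(self, mu, b):
        """Exponential update matches a tightly integrated dX/dt = (mu-B)X."""
        for dt in (0.01, 0.1, 0.25):
            sol = solve_ivp(
                lambda t, y: (mu - b) * y, (0.0, dt), [40.0],
                rtol=1e-10, atol=1e-12,
            )
            assert advance_biomass(40.0, mu, b, dt) == pytest.approx(
                sol.y[0, -1], rel=1e-6
            )

    @given(
        x=st.floats(0.1, 200.0),
        mu=st.floats(0.0, 0.5),
        b=st.floats(0.0, 0.5),
        dt=st.floats(0.001, 0.25),
    )
    @settings(max_examples=100, derandomize=True)
    def test_semigroup_and_positivity(self, x, mu, b, dt):
        whole = advance_biomass(x, mu, b, dt)
        halves = advance_biomass(advance_biomass(x, mu, b, dt / 2), mu, b, dt / 2)
        assert whole > 0
        assert whole == pytest.approx(halves, rel=1e-12)


class TestAdvanceProduct:
    def test_quasi_steady_fixed_point(self):
        # production 20*40*1e-3 = 0.8 g/L/day balances dilution 2 * 0.4
        for dt in (0.01, 0.5, 3.0):
            assert advance_product(0.4, 40.0, 20.0, 2.0, dt) == pytest.approx(0.4)

    def test_pure_accumulation_without_perfusion(self):
        assert advance_product(0.0, 40.0, 20.0, 0.0, 1.0) == pytest.approx(0.8)

    def test_washout_limit(self):
        assert advance_product(0.4, 0.0, 20.0, 2.0, 50.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_ode_oracle_with_growing_biomass(self):
        """Substepped exponential-Euler tracks the coupled ODE over one PUI."""
        mu, b, p, qp, dt = 0.24, 0.18, 2.0, 20.0, 0.01
        x, c = 40.0, 0.4
        for _ in range(25):  # one 6-h interval on the inner grid
            c = advance_product(c, x, qp, p, dt)
            x = advance_biomass(x, mu, b, dt)

        def rhs(t, y):
            xt = 40.0 * math.exp((mu - b) * t)
            return [qp * xt * 1e-3 - p * y[0]]

        sol = solve_ivp(rhs, (0.0, 0.25), [0.4], rtol=1e-10, atol=1e-13)
        # frozen-biomass substeps make the scheme first-order in dt
        assert c == pytest.approx(sol.y[0, -1], rel=5e-4)

    def test_negative_arguments_rejected(self):
        with pytest.raises(InvalidArgumentError):
            advance_product(-0.1, 40.0, 20.0, 2.0, 0.1)


class TestCloseMassBalance:
    def test_strategy_a_allocates_harvest(self):
        fl = close_mass_balance("A", 2.0, 0.2, 0.4, 10.0)
        assert (fl.p, fl.b, fl.h) == (2.0, 0.2, 1.8)
        assert fl.f_vol == 20.0 and fl.b_vol == 2.0 and fl.h_vol == 18.0

    def test_strategy_a_caps_bleed_at_forty_percent(self):
        fl = close_mass_balance("A", 1.0, 0.5, 0.4, 10.0)
        assert fl.b == pytest.approx(0.4)
        assert fl.h == pytest.approx(0.6)

    def test_strategy_b_closure(self):
        fl = close_mass_balance("B", 1.8, 0.2, 0.4, 10.0)
        assert fl.h == 1.8 and fl.b == pytest.approx(0.2)
        assert fl.p == pytest.approx(2.0)

    def test_strategy_b_self_consistent_cap(self):
        # B <= H * f / (1 - f) = 1.8 * 0.4/0.6 = 1.2
        fl = close_mass_balance("B", 1.8, 5.0, 0.4, 10.0)
        assert fl.b == pytest.approx(1.2)
        assert fl.b <= 0.4 * fl.p + 1e-12

    def test_strategy_b_unsatisfiable_cap(self):
        with pytest.raises(ConfigurationError):
            close_mass_balance("B", 1.8, 0.2, 1.0, 10.0)

    @given(
        strategy=st.sampled_from(["A", "B"]),
        set_point=st.floats(0.1, 5.0),
        b_req=st.floats(0.0, 3.0),
        cap=st.floats(0.0, 0.9),
    )
    @settings(max_examples=150, derandomize=True)
    def test_closure_cap_and_positivity(self, strategy, set_point, b_req, cap):
        fl = close_mass_balance(strategy, set_point, b_req, cap, 10.0)
        assert fl.p == pytest.approx(fl.b + fl.h, abs=1e-12)
        assert min(fl.p, fl.b, fl.h) >= 0
        assert fl.b <= cap * fl.p + 1e-9


class TestParameters:
    def test_exactly_one_governing_set_point(self):
        with pytest.raises(ConfigurationError):
            ProcessParameters(strategy="A", p_set=None)
        with pytest.raises(ConfigurationError):
            ProcessParameters(strategy="B", h_set=1.8)  # p_set still set
        ProcessParameters(strategy="B", h_set=1.8, p_set=None)

    def test_horizon_and_step_constraints(self):
        with pytest.raises(ConfigurationError):
            ProcessParameters(pui=1.0, pred_horizon=0.5)
        with pytest.raises(ConfigurationError):
            ProcessParameters(dt_plant=0.3)
        with pytest.raises(ConfigurationError):
            ProcessParameters(b_max_frac=1.2)

    def test_flow_rates_reject_broken_closure(self):
        with pytest.raises(InvalidArgumentError):
            FlowRates(p=2.0, b=0.5, h=1.8, vr=10.0)
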