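"""Continuous-time plant model of a steady-state perfusion bioreactor.

The reactor is a constant-volume, well-mixed vessel with 100 % cell retention
in the harvest line.  Fresh medium enters at the perfusion rate ``P``
(vessel volumes per day, VVD); cell-containing broth is deliberately removed
at the bleed rate ``B`` to cap biomass; cell-free supernatant leaves through
the retention device at the harvest rate ``H``.  Constant hold-up volume
closes the balance

    P = B + H            (all specific rates, 1/day)

which is the governing boundary condition of the model.  Viable biomass
``X`` (MVC/mL, millions of viable cells per millilitre) grows exponentially
at the cell-specific growth rate ``mu`` and is diluted only by the bleed:

    dX/dt = (mu - B) * X       =>      X(t + dt) = X(t) * exp((mu - B) dt)

Product (a secreted protein, e.g. a monoclonal antibody) is formed in
proportion to biomass with cell-specific productivity ``qp``
(pg/cell/day) and leaves with *every* outgoing stream at the reactor
concentration ``c`` (g/L); the feed carries no product:

    dc/dt = qp * X * 1e-3 - P * c        [g/L/day]

where the factor 1e-3 converts pg/cell/day x MVC/mL to g/L/day.  Two flow
allocation strategies close the balance around a requested bleed rate:
strategy A holds the perfusion rate constant (harvest results), strategy B
holds the harvest rate constant (perfusion results).  In both, the bleed is
capped at a fixed fraction of the perfusion rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "InvalidArgumentError",
    "ConfigurationError",
    "ProcessParameters",
    "FlowRates",
    "PlantState",
    "advance_biomass",
    "advance_product",
    "close_mass_balance",
    "QP_X_TO_G_PER_L_DAY",
    "L_PER_DAY_TO_ML_PER_MIN",
]

#: qp [pg/cell/day] * X [MVC/mL] -> volumetric production rate [g/L/day].
#: 1 MVC/mL = 1e9 cells/L and 1 pg = 1e-12 g, hence 1e9 * 1e-12 = 1e-3.
QP_X_TO_G_PER_L_DAY = 1e-3

#: Volumetric flow conversion used for downstream-facing reporting.
L_PER_DAY_TO_ML_PER_MIN = 1000.0 / 1440.0

_CLOSURE_TOL = 1e-9


class InvalidArgumentError(ValueError):
    """An operation was called with arguments outside its domain."""


class ConfigurationError(ValueError):
    """A parameter set is internally inconsistent or unsatisfiable."""


@dataclass(frozen=True)
class ProcessParameters:
    """Immutable configuration of one simulated perfusion campaign.

    Parameters
    ----------
    vr:
        Reactor working volume in litres (constant; no level dynamics).
    x_sp:
        Biomass set point in MVC/mL.
    mu:
        Nominal cell-specific growth rate, 1/day.
    qp:
        Nominal cell-specific productivity, pg/cell/day.
    noise_cv:
        Relative 1-sigma amplitude of the normal noise applied to ``mu``
        and ``qp`` (dimensionless; 0.20 means +/-20 %).
    p_set:
        Perfusion-rate set point in VVD; the governing set point of
        strategy A.  Must be ``None`` under strategy B.
    h_set:
        Harvest-rate set point in VVD; the governing set point of
        strategy B.  Must be ``None`` under strategy A.
    b_max_frac:
        Bleed cap expressed as a fraction of the perfusion rate.
    pui:
        Pump update interval in days (controller cadence); 6 h = 0.25 d.
    pred_horizon:
        Prediction horizon of the single-prediction controller, days.
    ctrl_horizon:
        Control horizon, days.  Equal to ``pui`` here: the controller
        commands one bleed move per pump update.
    r_weight:
        Weighting of input moves in the diagnostic cost function.
    duration:
        Total simulated steady-state time, days.
    dt_plant:
        Inner plant integration step, days.
    strategy:
        ``"A"`` (constant perfusion) or ``"B"`` (constant harvest).
    controller:
        ``"FC"`` (classical feedback) or ``"SPC"`` (single prediction).
    n_iterations:
        Monte-Carlo ensemble size.
    seed:
        Master seed of the ensemble.
    noise_cadence:
        ``"interval"`` redraws mu and qp at every pump update (default);
        ``"iteration"`` draws once per Monte-Carlo iteration.
    mu_source:
        Growth rate supplied to the SPC prediction model: ``"nominal"``
        uses ``mu`` (the controller cannot observe the noisy plant rate,
        default), ``"plant"`` assumes a growth soft sensor that tracks the
        currently active rate.
    spc_prediction:
        SPC prediction baseline: ``"hold_bleed"`` propagates the biomass
        under the currently commanded bleed (default), ``"zero_bleed"``
        assumes no bleed over the horizon (the literal printed law).
    spc_update_mode:
        ``"increment"`` treats the predictive term as a correction added
        to the previous command (default), ``"replace"`` commands the
        predictive term directly.
    store_interval:
        Trace storage interval in days; ``None`` stores one row per pump
        update interval.
    """

    vr: float = 10.0
    x_sp: float = 40.0
    mu: float = 0.2
    qp: float = 20.0
    noise_cv: float = 0.20
    p_set: float | None = 2.0
    h_set: float | None = None
    b_max_frac: float = 0.40
    pui: float = 0.25
    pred_horizon: float = 0.5
    ctrl_horizon: float = 0.25
    r_weight: float = 5.0
    duration: float = 30.0
    dt_plant: float = 0.01
    strategy: str = "A"
    controller: str = "SPC"
    n_iterations: int = 100
    seed: int = 0
    noise_cadence: str = "interval"
    mu_source: str = "nominal"
    spc_prediction: str = "hold_bleed"
    spc_update_mode: str = "increment"
    store_interval: float | None = None

    def __post_init__(self) -> None:
        if self.vr <= 0 or self.x_sp <= 0 or self.duration <= 0:
            raise ConfigurationError("vr, x_sp and duration must be positive")
        if self.mu <= 0 or self.qp < 0 or self.noise_cv < 0:
            raise ConfigurationError("mu must be > 0, qp and noise_cv >= 0")
        if not 0.0 <= self.b_max_frac <= 1.0:
            raise ConfigurationError("b_max_frac must lie in [0, 1]")
        if not 0.0 < self.dt_plant <= self.pui:
            raise ConfigurationError("dt_plant must satisfy 0 < dt_plant <= pui")
        if self.pui > self.pred_horizon:
            raise ConfigurationError(
                "pui must not exceed pred_horizon "
                "(the controller cannot predict shorter than it acts)"
            )
        if self.strategy not in ("A", "B"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.controller not in ("FC", "SPC"):
            raise ConfigurationError(f"unknown controller {self.controller!r}")
        if self.strategy == "A" and (self.p_set is None or self.h_set is not None):
            raise ConfigurationError(
                "strategy A requires p_set as the single governing set point"
            )
        if self.strategy == "B" and (self.h_set is None or self.p_set is not None):
            raise ConfigurationError(
                "strategy B requires h_set as the single governing set point"
            )
        if self.set_point <= 0:
            raise ConfigurationError("the governing set point must be positive")
        if self.strategy == "B" and self.b_max_frac >= 1.0:
            raise ConfigurationError(
                "b_max_frac >= 1 makes the bleed cap unsatisfiable under strategy B"
            )
        if self.noise_cadence not in ("interval", "iteration"):
            raise ConfigurationError(f"unknown noise_cadence {self.noise_cadence!r}")
        if self.mu_source not in ("nominal", "plant"):
            raise ConfigurationError(f"unknown mu_source {self.mu_source!r}")
        if self.spc_prediction not in ("hold_bleed", "zero_bleed"):
            raise ConfigurationError(f"unknown spc_prediction {self.spc_prediction!r}")
        if self.spc_update_mode not in ("increment", "replace"):
            raise ConfigurationError(f"unknown spc_update_mode {self.spc_update_mode!r}")
        n_ctrl = self.duration / self.pui
        if abs(n_ctrl - round(n_ctrl)) > 1e-9:
            raise ConfigurationError("duration must be an integer multiple of pui")
        n_sub = self.pui / self.dt_plant
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ConfigurationError("pui must be an integer multiple of dt_plant")
        if self.store_interval is not None:
            n_store = self.store_interval / self.dt_plant
            if self.store_interval <= 0 or abs(n_store - round(n_store)) > 1e-9:
                raise ConfigurationError(
                    "store_interval must be a positive multiple of dt_plant"
                )
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")

    @property
    def set_point(self) -> float:
        """The governing flow set point (VVD) of the active strategy."""
        return self.p_set if self.strategy == "A" else self.h_set  # type: ignore[return-value]

    @property
    def n_control_steps(self) -> int:
        return round(self.duration / self.pui)

    @property
    def substeps_per_interval(self) -> int:
        return round(self.pui / self.dt_plant)


@dataclass(frozen=True)
class FlowRates:
    """One consistent triple of specific flow rates plus volumetric views.

    ``p``, ``b`` and ``h`` are specific rates in 1/day (VVD); ``vr`` is the
    reactor volume used to derive the volumetric flows.  The closure
    ``p = b + h`` is enforced at construction.
    """

    p: float
    b: float
    h: float
    vr: float

    def __post_init__(self) -> None:
        if min(self.p, self.b, self.h) < 0:
            raise InvalidArgumentError("flow rates must be non-negative")
        if abs(self.p - self.b - self.h) > _CLOSURE_TOL * max(1.0, self.p):
            raise InvalidArgumentError(
                f"flow closure violated: P={self.p} != B+H={self.b + self.h}"
            )

    @property
    def b_vol(self) -> float:
        """Volumetric bleed flow b_m = Vr * B, L/day."""
        return self.vr * self.b

    @property
    def h_vol(self) -> float:
        """Volumetric harvest flow, L/day."""
        return self.vr * self.h

    @property
    def f_vol(self) -> float:
        """Volumetric feed flow V_in = Vr * P, L/day."""
        return self.vr * self.p

    @property
    def h_vol_ml_min(self) -> float:
        """Volumetric harvest flow in mL/min (downstream-facing units)."""
        return self.h_vol * L_PER_DAY_TO_ML_PER_MIN


@dataclass
class PlantState:
    """Instantaneous true state of the reactor."""

    t: float
    x: float
    c: float
    flows: FlowRates
    mu_current: float
    qp_current: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.c < 0:
            raise InvalidArgumentError("biomass and product concentration must be >= 0")


def advance_biomass(x: float, mu: float, b: float, dt: float) -> float:
    """Propagate biomass over ``dt`` days under growth ``mu`` and bleed ``b``.

    Exact solution of dX/dt = (mu - b) X; returns ``x`` unchanged when
    mu == b (the steady-state condition: apparent growth rate zero).
    """
    if dt < 0:
        raise InvalidArgumentError(f"dt must be non-negative, got {dt}")
    if x < 0:
        raise InvalidArgumentError(f"biomass must be non-negative, got {x}")
    return x * math.exp((mu - b) * dt)


def advance_product(c: float, x: float, qp: float, p: float, dt: float) -> float:
    """Propagate product concentration over ``dt`` days at constant biomass.

    Integrates dc/dt = qp*X*1e-3 - P*c exactly for the given (frozen)
    biomass: the concentration relaxes exponentially toward the
    quasi-steady value qp*X*1e-3/P with time constant 1/P.  Used as an
    exponential-Euler step when the caller advances biomass on a finer
    grid.
    """
    if min(c, x, qp, p, dt) < 0:
        raise InvalidArgumentError("all advance_product arguments must be >= 0")
    production = qp * x * QP_X_TO_G_PER_L_DAY
    if p == 0.0:
        return c + production * dt
    c_inf = production / p
    return c_inf + (c - c_inf) * math.exp(-p * dt)


def close_mass_balance(
    strategy: str,
    set_point: float,
    b_requested: float,
    b_max_frac: float,
    vr: float,
) -> FlowRates:
    """Allocate flows around a requested bleed rate under the active strategy.

    Strategy A (constant perfusion): ``P = set_point``, the bleed is clamped
    to ``[0, b_max_frac * P]`` and the harvest closes the balance,
    ``H = P - B``.

    Strategy B (constant harvest): ``H = set_point`` and the perfusion rate
    results from closure, ``P = H + B``.  The cap ``B <= b_max_frac * P``
    then constrains the bleed self-consistently:
    ``B <= b_max_frac * (H + B)  <=>  B <= H * b_max_frac / (1 - b_max_frac)``.

    All rates are specific (1/day); ``b_requested`` included.
    """
    if set_point <= 0:
        raise InvalidArgumentError("set_point must be positive")
    if b_requested < 0:
        raise InvalidArgumentError("b_requested must be non-negative")
    if not 0.0 <= b_max_frac <= 1.0:
        raise InvalidArgumentError("b_max_frac must lie in [0, 1]")

    if strategy == "A":
        p = set_point
        b = min(b_requested, b_max_frac * p)
        return FlowRates(p=p, b=b, h=p - b, vr=vr)
    if strategy == "B":
        if b_max_frac >= 1.0:
            raise ConfigurationError(
                "b_max_frac >= 1 makes the bleed cap unsatisfiable under strategy B"
            )
        h = set_point
        b = min(b_requested, h * b_max_frac / (1.0 - b_max_frac))
        return FlowRates(p=h + b, b=b, h=h, vr=vr)
    raise InvalidArgumentError(f"unknown strategy {strategy!r}")
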