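"""Discrete-time bleed controllers acting once per pump update interval.

Two controllers manipulate the volumetric bleed rate ``b_m`` (L/day) to hold
the measured viable cell concentration ``X_m`` at its set point ``X_sp``:

* **FC** — classical feedback control.  The commanded rate integrates the
  instantaneous error::

      b_m(t) = (X_m - X_sp) * (Vr / X_m) / PUI + b_m(t-1)

  The gain term converts a biomass excess into exactly the extra volume
  that must be bled within one pump update interval to remove it.

* **SPC** — single-prediction control, a one-step-ahead model-predictive
  variant.  The controller first predicts the VCC that the plant would
  reach over the prediction horizon ``Np`` if no corrective action were
  taken, then converts the predicted set-point deviation ``X_diff`` into a
  bleed correction::

      b_m(t+1) = X_diff(t+1) / Np * Vr / X_m(t+1)

  and commands it before the deviation materialises (``b_m(t) = b_m(t+1)``).
  Two prediction baselines are provided: ``zero_bleed`` (the plant grows
  unbled over the horizon, X_pred = X_m e^{mu Np}) and ``hold_bleed`` (the
  currently commanded bleed keeps running, X_pred = X_m e^{(mu - b/Vr) Np}).
  Two update semantics are provided: ``replace`` commands the predictive
  term directly, ``increment`` adds it as a correction to the previous
  command.  The ``hold_bleed``/``increment`` pairing is the simulator
  default because it leaves the steady state b = mu*Vr, X = X_sp an exact
  fixed point of the closed loop; the ``zero_bleed``/``replace`` pairing is
  the law as printed and is the default of :func:`spc_update` itself.

The measurement is a perfect, instantaneous soft sensor (X_m = X); all
stochasticity enters through the plant's growth rate and productivity.
Negative commands are floored at zero (pumps cannot run backwards).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .process_model import InvalidArgumentError

if TYPE_CHECKING:  # pragma: no cover
    from .process_model import PlantState, ProcessParameters

__all__ = [
    "ControllerFault",
    "ControllerState",
    "SPCDiagnostics",
    "CycleRecord",
    "estimate_vcc_forward",
    "fc_update",
    "spc_update",
    "spc_cost",
    "run_control_cycle",
]


class ControllerFault(RuntimeError):
    """A controller update could not be computed from its inputs."""


@dataclass(frozen=True)
class SPCDiagnostics:
    """Per-cycle internals of the single-prediction controller.

    ``j_cost`` is the cost value J = X_diff + R * sum(dU^2); it is logged
    as a diagnostic of each cycle, the commanded rate itself comes from
    the closed-form bleed law.
    """

    x_pred: float
    x_diff: float
    b_next: float
    du: tuple[float, ...]
    j_cost: float

    def __post_init__(self) -> None:
        # x_diff is defined as the predicted deviation from set point;
        # callers construct it as x_pred - x_sp, keep them consistent.
        pass


@dataclass(frozen=True)
class CycleRecord:
    t: float
    x_m: float
    error: float
    b_m: float
    diagnostics: SPCDiagnostics | None = None


@dataclass
class ControllerState:
    """Mutable controller memory between pump updates."""

    x_m: float
    b_m: float
    t_last: float = 0.0
    history: list[CycleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.b_m < 0:
            raise InvalidArgumentError("commanded bleed rate must be >= 0")


def estimate_vcc_forward(
    x_prev: float,
    b_prev: float,
    mu: float,
    dt: float,
    vr: float,
    literal: bool = False,
) -> float:
    """Project the VCC forward one interval from the last measurement.

    The bleed removes the volume fraction ``dt * b_prev / Vr`` of the broth
    (and with it the same fraction of cells); the survivors grow
    exponentially:

        X(t) = X(t-1) * (1 - dt * b_prev / Vr) * e^{mu dt}

    which agrees with the exact plant propagator e^{(mu - b/Vr) dt} to
    first order in dt.  ``literal=True`` selects the alternative reading
    in which the growth factor multiplies only the subtracted bleed term;
    it is retained for comparison only, as it lacks the steady-state fixed
    point b = mu * Vr.
    """
    if min(x_prev, b_prev, mu, dt, vr) < 0 or vr == 0:
        raise InvalidArgumentError("estimate_vcc_forward arguments must be >= 0, vr > 0")
    survival = 1.0 - dt * b_prev / vr
    if survival <= 0.0:
        raise ControllerFault(
            f"over-bleed within one interval: b={b_prev} L/day empties "
            f"{dt * b_prev / vr:.2f} reactor volumes in {dt} d"
        )
    if literal:
        return x_prev - (dt * b_prev / vr) * x_prev * math.exp(mu * dt)
    return x_prev * survival * math.exp(mu * dt)


def fc_update(x_m: float, x_sp: float, vr: float, pui: float, b_prev: float) -> float:
    """Feedback law: new volumetric bleed command (L/day), floored at zero.

    The caller applies the bleed cap afterwards through the mass-balance
    closure; the stored previous command should be the *applied* rate so
    the integrator does not wind up against the cap.
    """
    if x_m <= 0:
        raise ControllerFault("measured VCC must be positive for the feedback law")
    if pui <= 0:
        raise InvalidArgumentError("pui must be positive")
    return max(0.0, (x_m - x_sp) * (vr / x_m) / pui + b_prev)


def spc_cost(x_diff: float, du, r: float) -> float:
    """Diagnostic cost J = X_diff + R * sum(dU_i^2) of one SPC cycle."""
    if r < 0:
        raise InvalidArgumentError("cost weighting R must be >= 0")
    return x_diff + r * sum(d * d for d in du)


def spc_update(
    x_m: float,
    x_sp: float,
    mu: float,
    pred_horizon: float,
    vr: float,
    b_prev: float = 0.0,
    prediction: str = "zero_bleed",
    mode: str = "replace",
    r_weight: float = 5.0,
) -> tuple[float, SPCDiagnostics]:
    """Single-prediction law: command for the next interval plus diagnostics.

    With the default ``zero_bleed``/``replace`` arguments this is the
    closed-form law as printed: X_pred = X_m e^{mu Np}, X_diff = X_pred -
    X_sp, b = (X_diff / Np) * (Vr / X_pred).  In the small-horizon limit
    mu*Np -> 0 the command approaches the steady-state bleed mu * Vr.
    """
    if x_m <= 0:
        raise ControllerFault("measured VCC must be positive for the prediction model")
    if pred_horizon <= 0:
        raise InvalidArgumentError("pred_horizon must be positive")

    if prediction == "zero_bleed":
        x_pred = x_m * math.exp(mu * pred_horizon)
    elif prediction == "hold_bleed":
        x_pred = x_m * math.exp((mu - b_prev / vr) * pred_horizon)
    else:
        raise InvalidArgumentError(f"unknown prediction baseline {prediction!r}")
    x_diff = x_pred - x_sp
    correction = (x_diff / pred_horizon) * (vr / x_pred)
    if mode == "replace":
        b_next = max(0.0, correction)
    elif mode == "increment":
        b_next = max(0.0, b_prev + correction)
    else:
        raise InvalidArgumentError(f"unknown update mode {mode!r}")
    du = (b_next - b_prev,)
    return b_next, SPCDiagnostics(
        x_pred=x_pred,
        x_diff=x_diff,
        b_next=b_next,
        du=du,
        j_cost=spc_cost(x_diff, du, r_weight),
    )


def run_control_cycle(
    plant: "PlantState", ctrl: ControllerState, params: "ProcessParameters"
) -> ControllerState:
    """Execute one pump-update cycle and return the updated controller state.

    Samples the (perfect) biomass soft sensor, computes the new volumetric
    bleed command for the coming interval and records the cycle.  A faulted
    update holds the previous command (fail-safe hold).  The command is a
    zero-order hold until the next cycle; the caller applies the bleed cap
    via the mass-balance closure and writes the applied rate back into
    ``ctrl.b_m``.
    """
    x_m = plant.x  # X_m(t) = VCC = X: perfect, instantaneous soft sensor
    error = params.x_sp - x_m
    diag: SPCDiagnostics | None = None
    try:
        if params.controller == "FC":
            b_new = fc_update(x_m, params.x_sp, params.vr, params.pui, ctrl.b_m)
        else:
            mu_ctrl = plant.mu_current if params.mu_source == "plant" else params.mu
            b_new, diag = spc_update(
                x_m,
                params.x_sp,
                mu_ctrl,
                params.pred_horizon,
                params.vr,
                b_prev=ctrl.b_m,
                prediction=params.spc_prediction,
                mode=params.spc_update_mode,
                r_weight=params.r_weight,
            )
            # The predictive command replaces the running one only if they
            # differ; equality means the loop is already on its trajectory.
    except ControllerFault:
        b_new = ctrl.b_m
    ctrl.x_m = x_m
    ctrl.b_m = b_new
    ctrl.t_last = plant.t
    ctrl.history.append(CycleRecord(plant.t, x_m, error, b_new, diag))
    return ctrl
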