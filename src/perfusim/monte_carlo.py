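"""Stochastic simulation engine: noise draws, time marching, ensembles, grids.

Each Monte-Carlo iteration starts the plant in steady state (the batch
start-up phase is out of scope): X = X_sp, b_m = mu * Vr and the product
concentration at its quasi-steady value qp * X * 1e-3 / P.  At every pump
update interval the cell-specific growth rate (and productivity) are
redrawn from a truncated normal law around their nominal values, the
active controller recomputes the bleed command, the mass balance is closed
under the chosen strategy (applying the bleed cap), and the plant is then
integrated over the interval on a finer inner grid.

Seeding follows a deterministic hierarchy: a master seed spawns one child
seed sequence per iteration, so ensembles are reproducible bit-for-bit and
feedback/predictive runs with the same master seed see identical noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .controllers import ControllerState, run_control_cycle
from .process_model import (
    ConfigurationError,
    InvalidArgumentError,
    PlantState,
    ProcessParameters,
    advance_biomass,
    advance_product,
    close_mass_balance,
    L_PER_DAY_TO_ML_PER_MIN,
    QP_X_TO_G_PER_L_DAY,
)

__all__ = [
    "IterationTrace",
    "Ensemble",
    "GridResult",
    "draw_noisy_rate",
    "simulate_iteration",
    "run_ensemble",
    "run_grid",
    "GRID_X_SP",
    "GRID_MU",
    "GRID_P",
]

#: Default set-point grid of the full-factorial sweep (biomass MVC/mL, growth 1/day,
#: perfusion VVD).
GRID_X_SP = (20.0, 40.0, 80.0)
GRID_MU = (0.1, 0.2, 0.3)
GRID_P = (1.0, 2.0, 3.0)

#: An iteration is aborted when biomass exceeds this multiple of the set
#: point — the controller has lost the plant.
BLOW_UP_FACTOR = 10.0


@dataclass
class IterationTrace:
    """Time series of one Monte-Carlo iteration.

    ``frame`` holds one row per stored time point with columns
    t_days, X_MVCml, c_gL, P_vvd, B_vvd, H_vvd, b_m_Lday, f_vol_Lday,
    h_vol_Lday, h_flow_mLmin, mu_draw, qp_draw, e_MVCml, X_pred_MVCml,
    X_diff_MVCml, J_cost.
    """

    frame: pd.DataFrame
    params: ProcessParameters
    seed_entropy: int
    aborted: bool = False
    abort_reason: str | None = None

    @property
    def t(self) -> np.ndarray:
        return self.frame["t_days"].to_numpy()

    def values(self, variable: str) -> np.ndarray:
        return self.frame[variable].to_numpy()

    def closure_residual(self) -> float:
        """max |P - B - H| over all stored rows."""
        f = self.frame
        return float(
            np.abs(f["P_vvd"] - f["B_vvd"] - f["H_vvd"]).max()
        )


@dataclass
class Ensemble:
    """A reproducible collection of iteration traces plus failure records."""

    traces: list[IterationTrace]
    failures: list[tuple[int, str]]
    params: ProcessParameters
    master_seed: int
    n_requested: int

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def long_frame(self) -> pd.DataFrame:
        """All traces stacked into one long-format table."""
        frames = []
        for i, tr in enumerate(self.traces):
            f = tr.frame.copy()
            f.insert(0, "iteration", i)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def draw_noisy_rate(nominal: float, cv: float, rng: np.random.Generator) -> float:
    """One noisy rate draw: N(nominal, (cv*nominal)^2), truncated at zero.

    Negative draws are rejected and redrawn — a specific rate cannot be
    negative.  With cv = 0 the nominal value is returned exactly.
    """
    if nominal <= 0:
        raise ConfigurationError("nominal rate must be positive")
    if cv < 0:
        raise ConfigurationError("noise cv must be >= 0")
    if cv == 0.0:
        return nominal
    while True:
        value = rng.normal(nominal, cv * nominal)
        if value > 0.0:
            return float(value)


def _row(
    t: float,
    state: PlantState,
    b_m: float,
    mu_draw: float,
    qp_draw: float,
    error: float,
    diag,
) -> dict:
    fl = state.flows
    return {
        "t_days": t,
        "X_MVCml": state.x,
        "c_gL": state.c,
        "P_vvd": fl.p,
        "B_vvd": fl.b,
        "H_vvd": fl.h,
        "b_m_Lday": b_m,
        "f_vol_Lday": fl.f_vol,
        "h_vol_Lday": fl.h_vol,
        "h_flow_mLmin": fl.h_vol_ml_min,
        "mu_draw": mu_draw,
        "qp_draw": qp_draw,
        "e_MVCml": error,
        "X_pred_MVCml": diag.x_pred if diag is not None else np.nan,
        "X_diff_MVCml": diag.x_diff if diag is not None else np.nan,
        "J_cost": diag.j_cost if diag is not None else np.nan,
    }


def simulate_iteration(params: ProcessParameters, seed) -> IterationTrace:
    """March one iteration through time; deterministic given (params, seed).

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`.
    Aborted iterations (biomass beyond ``BLOW_UP_FACTOR`` times the set
    point) return a truncated trace flagged with the diagnostic.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    entropy = int(ss.entropy) if isinstance(ss.entropy, int) else 0

    # Steady-state initialisation: bleed balances nominal growth.
    flows = close_mass_balance(
        params.strategy, params.set_point, params.mu, params.b_max_frac, params.vr
    )
    state = PlantState(
        t=0.0,
        x=params.x_sp,
        c=params.qp * params.x_sp * QP_X_TO_G_PER_L_DAY / flows.p,
        flows=flows,
        mu_current=params.mu,
        qp_current=params.qp,
    )
    ctrl = ControllerState(x_m=state.x, b_m=flows.b * params.vr)

    if params.noise_cadence == "iteration":
        mu_iter = draw_noisy_rate(params.mu, params.noise_cv, rng)
        qp_iter = draw_noisy_rate(params.qp, params.noise_cv, rng) if params.qp > 0 else 0.0

    dt = params.dt_plant
    n_sub = params.substeps_per_interval
    store = params.store_interval if params.store_interval is not None else params.pui
    store_every = round(store / dt)
    rows: list[dict] = []
    aborted = False
    reason: str | None = None

    for k in range(params.n_control_steps):
        t_k = k * params.pui
        state.t = t_k
        if params.noise_cadence == "interval":
            mu_k = draw_noisy_rate(params.mu, params.noise_cv, rng)
            qp_k = draw_noisy_rate(params.qp, params.noise_cv, rng) if params.qp > 0 else 0.0
        else:
            mu_k, qp_k = mu_iter, qp_iter
        state.mu_current, state.qp_current = mu_k, qp_k

        run_control_cycle(state, ctrl, params)
        flows = close_mass_balance(
            params.strategy, params.set_point, ctrl.b_m / params.vr,
            params.b_max_frac, params.vr,
        )
        ctrl.b_m = flows.b * params.vr  # applied (capped) rate: no windup
        state.flows = flows
        rec = ctrl.history[-1]
        rows.append(_row(t_k, state, ctrl.b_m, mu_k, qp_k, rec.error, rec.diagnostics))

        for j in range(n_sub):
            state.c = advance_product(state.c, state.x, qp_k, flows.p, dt)
            state.x = advance_biomass(state.x, mu_k, flows.b, dt)
            sub_index = k * n_sub + j + 1
            t_sub = sub_index * dt
            if sub_index % store_every == 0 and abs(t_sub % params.pui) > 1e-9 \
                    and params.pui - (t_sub % params.pui) > 1e-9:
                state.t = t_sub
                rows.append(
                    _row(t_sub, state, ctrl.b_m, mu_k, qp_k, rec.error, rec.diagnostics)
                )
        state.t = (k + 1) * params.pui

        if state.x > BLOW_UP_FACTOR * params.x_sp:
            aborted = True
            reason = (
                f"plant blow-up at t={state.t:.2f} d: X={state.x:.1f} MVC/mL "
                f"exceeds {BLOW_UP_FACTOR:g} x set point"
            )
            break

    rec = ctrl.history[-1]
    rows.append(
        _row(state.t, state, ctrl.b_m, state.mu_current, state.qp_current,
             params.x_sp - state.x, rec.diagnostics)
    )
    return IterationTrace(
        frame=pd.DataFrame(rows),
        params=params,
        seed_entropy=entropy,
        aborted=aborted,
        abort_reason=reason,
    )


def run_ensemble(
    params: ProcessParameters,
    n: int | None = None,
    seed: int | None = None,
) -> Ensemble:
    """Run ``n`` iterations with child seeds spawned from the master seed.

    Aborted iterations are excluded from ``traces`` and reported in
    ``failures`` as (iteration index, diagnostic).
    """
    n = params.n_iterations if n is None else n
    seed = params.seed if seed is None else seed
    if n < 1:
        raise ConfigurationError("ensemble size must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n)
    traces: list[IterationTrace] = []
    failures: list[tuple[int, str]] = []
    for i, child in enumerate(children):
        tr = simulate_iteration(params, child)
        if tr.aborted:
            failures.append((i, tr.abort_reason or "aborted"))
        else:
            traces.append(tr)
    return Ensemble(
        traces=traces, failures=failures, params=params,
        master_seed=seed, n_requested=n,
    )


@dataclass
class GridResult:
    """Per-combination ensemble metrics of a set-point grid sweep.

    ``frame`` has one row per (x_sp, mu, p_set) combination with columns
    feasible, n_ok, n_failed, skewness, kurtosis, kurtosis_excess,
    max_abs_dev.  Infeasible combinations (nominal bleed demand above the
    cap, mu > b_max_frac * P) are flagged, not dropped.
    """

    frame: pd.DataFrame
    failures: list[tuple[tuple[float, float, float], str]] = field(default_factory=list)


def run_grid(
    base: ProcessParameters,
    x_sp_values=GRID_X_SP,
    mu_values=GRID_MU,
    p_values=GRID_P,
    n: int | None = None,
    seed: int | None = None,
    burn_in: float = 1.0,
) -> GridResult:
    """Full-factorial sweep of biomass/growth/perfusion set points.

    Each feasible combination is simulated as an ensemble (strategy A)
    and summarised by the pooled error-distribution shape statistics and
    the maximum absolute set-point deviation.
    """
    from .analytics import error_stats, max_abs_deviation

    if min(*x_sp_values, *mu_values, *p_values) <= 0:
        raise ConfigurationError("grid values must be positive")
    combos = list(itertools.product(x_sp_values, mu_values, p_values))
    seed = base.seed if seed is None else seed
    children = np.random.SeedSequence(seed).spawn(len(combos))
    rows = []
    failures: list[tuple[tuple[float, float, float], str]] = []
    for (x_sp, mu, p_set), child in zip(combos, children):
        row = {
            "X_sp_MVCml": x_sp, "mu_1day": mu, "P_vvd": p_set,
            "feasible": True, "n_ok": 0, "n_failed": 0,
            "skewness": np.nan, "kurtosis": np.nan,
            "kurtosis_excess": np.nan, "max_abs_dev": np.nan,
        }
        if mu > base.b_max_frac * p_set:
            row["feasible"] = False
            failures.append(
                ((x_sp, mu, p_set),
                 f"steady state unreachable: mu={mu} > cap {base.b_max_frac}*P={base.b_max_frac * p_set}")
            )
            rows.append(row)
            continue
        params = replace(base, x_sp=x_sp, mu=mu, p_set=p_set, h_set=None, strategy="A")
        ens = run_ensemble(params, n=n, seed=int(child.generate_state(1)[0] % (2**31)))
        row["n_ok"] = len(ens.traces)
        row["n_failed"] = len(ens.failures)
        if len(ens.traces) >= 2:
            try:
                stats = error_stats(ens.traces, x_sp, burn_in=burn_in)
            except InvalidArgumentError as exc:
                failures.append(((x_sp, mu, p_set), str(exc)))
            else:
                row["skewness"] = stats.g1
                row["kurtosis"] = stats.kurtosis
                row["kurtosis_excess"] = stats.kurtosis_excess
            row["max_abs_dev"] = max_abs_deviation(ens.traces, "X_MVCml", x_sp)
        else:
            failures.append(((x_sp, mu, p_set), "all iterations aborted"))
        rows.append(row)
    return GridResult(frame=pd.DataFrame(rows), failures=failures)
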