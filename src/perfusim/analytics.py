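"""Ensemble statistics: bands, deviation metrics, error-distribution shape.

Per-timepoint normal-theory bands across an ensemble of traces:

    CI = mean +/- z * sd / sqrt(n)          (confidence band of the mean)
    PI = mean +/- z * sd * sqrt(1 + 1/n)    (prediction band for a future run)

with z the standard-normal quantile of the requested two-sided level.
Nonparametric quantile bands are available as an alternative.

Error-distribution shape follows the population-moment conventions: the
Fisher-Pearson skewness coefficient g1 = m3 / s^3 and the plain kurtosis
m4 / s^4 (normal -> 3), both with moments divided by N and the biased
standard deviation.  Excess kurtosis (plain - 3) is reported alongside,
since "heavy-tailed" statements are usually made on the excess scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .monte_carlo import GridResult, IterationTrace
from .process_model import InvalidArgumentError

__all__ = [
    "EnsembleSummary",
    "ErrorDistribution",
    "ensemble_bands",
    "error_stats",
    "pooled_deviations",
    "max_abs_deviation",
    "moment_stats",
    "grid_surface",
]


@dataclass
class EnsembleSummary:
    """Per-timepoint mean and 95 % (by default) bands across iterations."""

    frame: pd.DataFrame  # t_days, mean, sd, ci_lo, ci_hi, pi_lo, pi_hi
    variable: str
    level: float
    n: int
    reference: float | None = None

    @property
    def max_abs_dev_mean(self) -> float:
        """max over t of |mean - reference| (reference: e.g. the set point)."""
        if self.reference is None:
            return float("nan")
        return float(np.abs(self.frame["mean"] - self.reference).max())

    @property
    def max_pi_halfwidth(self) -> float:
        return float((self.frame["pi_hi"] - self.frame["pi_lo"]).max() / 2.0)

    def max_band_deviation(self, reference: float | None = None) -> float:
        """Largest excursion of either prediction-band edge from a reference."""
        ref = self.reference if reference is None else reference
        if ref is None:
            raise InvalidArgumentError("a reference value is required")
        lo = np.abs(self.frame["pi_lo"] - ref)
        hi = np.abs(self.frame["pi_hi"] - ref)
        return float(np.maximum(lo, hi).max())


def _stack(traces: list[IterationTrace], variable: str) -> tuple[np.ndarray, np.ndarray]:
    if len(traces) < 2:
        raise InvalidArgumentError("at least two traces are required")
    t0 = traces[0].t
    values = np.empty((len(traces), t0.size))
    for i, tr in enumerate(traces):
        if tr.t.size != t0.size or not np.allclose(tr.t, t0, atol=1e-9):
            raise InvalidArgumentError("traces are not on a common time grid")
        values[i] = tr.values(variable)
    return t0, values


def ensemble_bands(
    traces: list[IterationTrace],
    variable: str = "X_MVCml",
    level: float = 0.95,
    reference: float | None = None,
    method: str = "normal",
) -> EnsembleSummary:
    """Per-timepoint mean with confidence and prediction bands.

    ``method="normal"`` uses the pointwise normal-theory formulas above;
    ``method="quantile"`` replaces the prediction band by empirical
    quantiles of the ensemble (the confidence band keeps the normal form).
    """
    if not 0 < level < 1:
        raise InvalidArgumentError("level must lie in (0, 1)")
    t, values = _stack(traces, variable)
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    z = norm.ppf(0.5 + level / 2.0)
    ci = z * sd / np.sqrt(n)
    if method == "normal":
        pi = z * sd * np.sqrt(1.0 + 1.0 / n)
        pi_lo, pi_hi = mean - pi, mean + pi
    elif method == "quantile":
        alpha = (1.0 - level) / 2.0
        pi_lo = np.quantile(values, alpha, axis=0)
        pi_hi = np.quantile(values, 1.0 - alpha, axis=0)
    else:
        raise InvalidArgumentError(f"unknown band method {method!r}")
    frame = pd.DataFrame(
        {
            "t_days": t,
            "mean": mean,
            "sd": sd,
            "ci_lo": mean - ci,
            "ci_hi": mean + ci,
            "pi_lo": pi_lo,
            "pi_hi": pi_hi,
        }
    )
    return EnsembleSummary(frame=frame, variable=variable, level=level, n=n,
                           reference=reference)


@dataclass
class ErrorDistribution:
    """Pooled set-point deviations and their shape statistics.

    ``g1`` and the kurtosis values are NaN (undefined) when the pooled
    standard deviation is zero.
    """

    deviations: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    n: int
    mean: float
    sd: float
    g1: float
    kurtosis: float
    kurtosis_excess: float


def moment_stats(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, sd, g1, kurtosis, excess) with population (divide-by-N) moments."""
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = float(values.mean())
    centred = values - mean
    s = float(np.sqrt(np.mean(centred**2)))
    if s == 0.0:
        return mean, s, float("nan"), float("nan"), float("nan")
    g1 = float(np.mean(centred**3) / s**3)
    kurt = float(np.mean(centred**4) / s**4)
    return mean, s, g1, kurt, kurt - 3.0


def pooled_deviations(
    traces: list[IterationTrace],
    set_point: float,
    variable: str = "X_MVCml",
    burn_in: float = 0.0,
) -> np.ndarray:
    """(value - set point), pooled over all iterations and t >= burn_in."""
    pools = []
    for tr in traces:
        f = tr.frame
        mask = f["t_days"].to_numpy() >= burn_in
        pools.append(f.loc[mask, variable].to_numpy() - set_point)
    return np.concatenate(pools)


def max_abs_deviation(
    traces: list[IterationTrace],
    variable: str,
    reference: float,
    burn_in: float = 0.0,
) -> float:
    """max over iterations and timepoints of |value - reference|."""
    return float(
        max(
            np.abs(
                tr.frame.loc[tr.frame["t_days"] >= burn_in, variable].to_numpy()
                - reference
            ).max()
            for tr in traces
        )
    )


def error_stats(
    traces: list[IterationTrace],
    set_point: float,
    variable: str = "X_MVCml",
    burn_in: float = 1.0,
    bins="fd",
) -> ErrorDistribution:
    """Histogram and shape statistics of pooled set-point deviations.

    Deviations are pooled over all iterations and all stored timepoints
    after the burn-in window (identical across controllers, so the
    comparison is fair).  Binning defaults to the Freedman-Diaconis rule;
    pass an integer or explicit edges to override.
    """
    dev = pooled_deviations(traces, set_point, variable, burn_in)
    if dev.size < 3:
        raise InvalidArgumentError("at least 3 pooled values are required")
    mean, sd, g1, kurt, excess = moment_stats(dev)
    if sd == 0.0:
        counts, edges = np.histogram(dev, bins=1)
    else:
        counts, edges = np.histogram(dev, bins=bins)
    return ErrorDistribution(
        deviations=dev,
        bin_edges=edges,
        counts=counts,
        n=dev.size,
        mean=mean,
        sd=sd,
        g1=g1,
        kurtosis=kurt,
        kurtosis_excess=excess,
    )


_GRID_METRICS = {
    "skewness": "skewness",
    "kurtosis": "kurtosis",
    "kurtosis_excess": "kurtosis_excess",
    "max_dev": "max_abs_dev",
}


def grid_surface(grid: GridResult, metric: str) -> pd.DataFrame:
    """Long-format (P, mu, X_sp, value) table of one grid metric.

    Suitable for contour plotting; infeasible or failed combinations carry
    missing values.
    """
    if metric not in _GRID_METRICS:
        raise InvalidArgumentError(
            f"unknown metric {metric!r}; choose from {sorted(_GRID_METRICS)}"
        )
    col = _GRID_METRICS[metric]
    out = grid.frame[["P_vvd", "mu_1day", "X_sp_MVCml", col]].copy()
    return out.rename(columns={col: "value"})
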