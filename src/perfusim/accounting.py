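"""Time-integrated mass balances: volumes, product yield and product loss.

Integrating the stored volumetric flows over the campaign gives the total
fed, harvested and bled volumes (volume closure: feed = harvest + bleed),
and integrating concentration x flow gives the product split: everything
leaving through the harvest line is yield for the downstream capture step,
everything leaving with the bleed is lost.  Strategy comparisons rescale
both runs to equal total feed before differencing, so the media budget is
held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .monte_carlo import IterationTrace
from .process_model import InvalidArgumentError, ProcessParameters

__all__ = ["MassTotals", "StrategyDelta", "integrate_totals", "compare_strategies",
           "product_offset_mass"]


@dataclass(frozen=True)
class MassTotals:
    """Time-integrated volumes (L) and product masses (g) of one run."""

    feed_vol: float
    harvest_vol: float
    bleed_vol: float
    product_harvested: float
    product_bled: float

    @property
    def product_total(self) -> float:
        return self.product_harvested + self.product_bled

    @property
    def loss_fraction(self) -> float:
        """Fraction of synthesised product lost through the bleed."""
        total = self.product_total
        return self.product_bled / total if total > 0 else 0.0

    def scaled(self, factor: float) -> "MassTotals":
        return MassTotals(
            feed_vol=self.feed_vol * factor,
            harvest_vol=self.harvest_vol * factor,
            bleed_vol=self.bleed_vol * factor,
            product_harvested=self.product_harvested * factor,
            product_bled=self.product_bled * factor,
        )


def integrate_totals(trace: IterationTrace, params: ProcessParameters | None = None) -> MassTotals:
    """Trapezoidal time integration of flows and product streams.

    The stored grid must be gap-free (strictly increasing, no step longer
    than the pump update interval); flow closure of the trace guarantees
    volume closure of the totals to integration tolerance.
    """
    params = trace.params if params is None else params
    f = trace.frame
    t = f["t_days"].to_numpy()
    if t.size < 2:
        raise InvalidArgumentError("trace too short to integrate")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.any(dt > params.pui + 1e-9):
        raise InvalidArgumentError("trace has gaps or non-increasing time")
    c = f["c_gL"].to_numpy()
    f_vol = f["f_vol_Lday"].to_numpy()
    h_vol = f["h_vol_Lday"].to_numpy()
    b_vol = f["b_m_Lday"].to_numpy()
    return MassTotals(
        feed_vol=float(np.trapezoid(f_vol, t)),
        harvest_vol=float(np.trapezoid(h_vol, t)),
        bleed_vol=float(np.trapezoid(b_vol, t)),
        product_harvested=float(np.trapezoid(c * h_vol, t)),
        product_bled=float(np.trapezoid(c * b_vol, t)),
    )


@dataclass(frozen=True)
class StrategyDelta:
    """(B - A) differences after rescaling both runs to equal total feed."""

    feed_vol_ref: float
    harvest_vol: float
    bleed_vol: float
    product_harvested: float
    product_bled: float
    product_total: float
    loss_fraction: float


def compare_strategies(
    totals_a: MassTotals, totals_b: MassTotals, normalize: bool = True
) -> StrategyDelta:
    """Difference report strategy B minus strategy A.

    With ``normalize=True`` the strategy-B totals are linearly rescaled so
    both runs consumed the same total feed volume (the strategy-A feed is
    the reference); loss fractions are scale-invariant and compared as is.
    """
    if totals_a.feed_vol <= 0 or totals_b.feed_vol <= 0:
        raise InvalidArgumentError("total feed volume must be positive")
    b = totals_b
    if normalize:
        b = totals_b.scaled(totals_a.feed_vol / totals_b.feed_vol)
    return StrategyDelta(
        feed_vol_ref=totals_a.feed_vol,
        harvest_vol=b.harvest_vol - totals_a.harvest_vol,
        bleed_vol=b.bleed_vol - totals_a.bleed_vol,
        product_harvested=b.product_harvested - totals_a.product_harvested,
        product_bled=b.product_bled - totals_a.product_bled,
        product_total=b.product_total - totals_a.product_total,
        loss_fraction=b.loss_fraction - totals_a.loss_fraction,
    )


def product_offset_mass(c_offset: float, perfused_vol: float) -> float:
    """Product mass carried by a sustained concentration offset.

    A persistent offset of ``c_offset`` g/L across ``perfused_vol`` litres
    of processed medium corresponds to ``c_offset * perfused_vol`` grams of
    product gained or lost over the campaign.
    """
    if perfused_vol < 0:
        raise InvalidArgumentError("perfused volume must be >= 0")
    return c_offset * perfused_vol
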