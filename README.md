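# perfusim

A desk-scale Monte-Carlo simulator of **bleed control in steady-state
perfusion bioreactors** that feed a continuous downstream capture step.
It is aimed at bioprocess engineers who want to compare control strategies
for the cell bleed — the manipulated variable that caps biomass in a
perfusion culture — and to quantify how control errors propagate into the
product stream (titre and harvest flow) and into the integrated product
yield and loss of a 30-day campaign.

## The model

A constant-volume, well-mixed perfusion reactor with 100 % cell retention
obeys the flow closure

```
P = B + H        (specific rates, 1/day; P = perfusion, B = bleed, H = harvest)
```

Viable cell concentration `X` (MVC/mL) grows exponentially and is removed
only through the bleed,

```
dX/dt = (μ − B)·X        ⇒        X(t+Δt) = X(t)·e^{(μ−B)Δt}
```

and a secreted product accumulates in proportion to biomass (cell-specific
productivity `q_p`, pg/cell/day) while being washed out by perfusion,

```
dc/dt = q_p·X·10⁻³ − P·c        (c in g/L)
```

Biological variability is emulated by redrawing `μ` and `q_p` every pump
update interval (PUI, 6 h) from a normal law with a ±20 % (1σ) relative
spread.  Two discrete-time controllers command the volumetric bleed rate
`b_m = V_r·B` once per PUI:

* **FC** (feedback control): `b_m(t) = (X_m − X_sp)·(V_r/X_m)/PUI + b_m(t−1)`
* **SPC** (single-prediction control): a one-step-ahead predictive law
  that forecasts the VCC over a 12-h horizon and corrects the command
  before the deviation materialises,
  `b_m(t+1) = X_diff(t+1)/N_p · V_r/X_m(t+1)`.

Two flow-allocation strategies close the balance: **A** holds the
perfusion rate constant (harvest results), **B** holds the harvest rate
constant (perfusion results); in both, the bleed is capped at 40 % of the
perfusion rate.  Ensembles (n = 100) are summarised by per-timepoint 95 %
confidence/prediction bands, pooled error histograms with Fisher–Pearson
skewness `g₁ = m₃/s³` and kurtosis `m₄/s⁴`, and trapezoidally integrated
mass totals (feed/harvest/bleed volumes, product harvested vs. lost in
the bleed).

## Worked example

Run the reference ensemble (40 MVC/mL set point, μ = 0.2 ± 20 % 1/d,
P = 2 VVD, V_r = 10 L, 30 d, n = 100) under both controllers:

```
perfusim ensemble --iterations 100 --seed 1 --controller fc  --out fc_run
perfusim ensemble --iterations 100 --seed 1 --controller spc --out spc_run
```

Each run writes `traces.csv` (all iterations, long format), `summary.csv`
(mean and 95 % bands per timepoint), `totals.csv` and `stats.json`.  For
the feedback controller, `stats.json` reads:

```json
{
  "sd_dev_MVCml": 1.2839964810650328,
  "skewness_g1": -0.047838685272788735,
  "kurtosis_excess": -0.6597503402912572,
  "max_abs_dev_MVCml": 3.9524938225596387,
  "max_band_deviation_MVCml": 2.9748312837757354
}
```

and for the single-prediction controller:

```json
{
  "sd_dev_MVCml": 0.4647645335463304,
  "skewness_g1": 0.08882068640225194,
  "kurtosis_excess": -0.0006145770545349372,
  "max_abs_dev_MVCml": 2.0284883423129756,
  "max_band_deviation_MVCml": 1.1167181812824367
}
```

Reading: under feedback control the closed loop oscillates (the integrator
over-corrects each noise kick), biomass excursions reach ±3.95 MVC/mL and
the 95 % prediction band strays up to ±2.97 MVC/mL from the set point.
The predictive controller suppresses the oscillation — pooled deviation
spread 0.46 vs. 1.28 MVC/mL, maximum excursion roughly halved, and an
error distribution that is indistinguishable from normal (g₁ ≈ 0.09,
excess kurtosis ≈ 0).  The same picture propagates downstream: harvest
flow and titre fluctuate several-fold less under SPC.  A deterministic
run (`--config` with `noise_cv: 0`) reproduces the analytic mass balance:
0.4 g/L steady titre and 240 g of product synthesised over 30 days, of
which 24 g correspond to a sustained 0.04 g/L concentration offset across
the 600 L perfused.

Other subcommands: `simulate` (single trace), `grid` (full 3×3×3 sweep of
biomass/growth/perfusion set points with shape statistics per cell),
`compare` (strategy A vs. B on matched seeds, feed-normalised totals),
`report` (recompute statistics from a stored traces CSV).  All campaigns
accept a YAML config (`--config`), accept hour-suffixed cadences
(`pui: 6 h`), and write a manifest with the config hash and master seed
from which the run is exactly reproducible.

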