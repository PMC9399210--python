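# Methods

## Scope and model structure

`perfusim` models the steady-state phase of a perfusion cell culture as a
constant-volume, well-mixed continuous reactor with ideal (100 %) cell
retention in the harvest line.  The batch start-up phase, substrate and
metabolite balances, pH/DO control, retention-device fouling and the
downstream capture unit itself are out of scope: growth is modelled as
independent of substrate availability (ds/dt = 0 at equilibrium), and the
downstream unit sees only the two outputs that matter to it — product
concentration and harvest flow.

The plant state is (X, c): viable cell concentration in MVC/mL
(10⁶ viable cells per mL) and product concentration in g/L.  Between
controller actions the plant evolves as

* biomass: exact exponential update `X ← X·e^{(μ−B)Δt}` (the closed-form
  solution of dX/dt = (μ−B)X),
* product: exponential-Euler update of dc/dt = q_p·X·10⁻³ − P·c with
  biomass frozen per inner step (Δt_plant = 0.01 d by default), i.e. the
  exact relaxation toward q_p·X·10⁻³/P for the current X.  The scheme is
  first-order in Δt_plant; at the default step its relative error over one
  control interval is ≲10⁻⁴ (checked against a tightly-tolerated
  `solve_ivp` integration in the tests).

Flow closure `P = B + H` holds identically at every stored point by
construction: flows are only ever created through the allocation routine,
which also enforces the bleed cap.  Product leaves with both harvest and
bleed at the reactor concentration; the feed carries none.  The bleed
stream is pure loss (no downstream recovery factor).

## Flow strategies and the bleed cap

* **Strategy A** (single perfusion unit): P is the set point; B is the
  manipulated variable, clamped to [0, 0.4·P]; H = P − B results.
* **Strategy B** (integrated continuous process): H is the set point; the
  perfusion rate results from closure, P = H + B.  The cap B ≤ 0.4·P then
  binds self-consistently: B ≤ 0.4·(H+B) ⇔ B ≤ H·0.4/0.6.  A cap
  fraction ≥ 1 under strategy B is rejected as unsatisfiable.

Note the deliberate asymmetry this creates: at the same nominal steady
state the absolute cap is higher under strategy B (it scales with the
achieved, not the set, perfusion rate).  This matters for the strategy
comparison below.

## Controllers

Both controllers act every pump update interval (PUI = 6 h = 0.25 d) on a
perfect, instantaneous biomass soft sensor (X_m = X; sensor noise is not
modelled — all stochasticity enters through μ and q_p).  Commands are
zero-order-held between updates and floored at zero.

**Feedback control (FC).**  `b_m(t) = (X_m − X_sp)·(V_r/X_m)/PUI +
b_m(t−1)`.  The proportional term converts the biomass excess into
exactly the extra broth volume to bleed within one interval, on top of
the running command — a deadbeat correction with an integrator.  The
linearised closed loop is a marginally stable discrete oscillator
(eigenvalues on the unit circle, period six intervals), so per-interval
growth-rate noise pumps the oscillation: amplitude grows until the
command rails against the floor b = 0 or the cap.  The previous command
stored by the integrator is the *applied* (clamped) rate, not the raw
request; without this anti-windup choice railing episodes would be
followed by large windup transients.

**Single-prediction control (SPC).**  One forward prediction of the VCC
over the horizon N_p = 12 h, converted to a bleed correction
`(X_pred − X_sp)/N_p · V_r/X_pred` and commanded before the deviation
materialises.  Two design axes are exposed:

* prediction baseline — `hold_bleed` (default): X_pred = X_m·e^{(μ−b/V_r)N_p},
  the trajectory under the currently running command; or `zero_bleed`:
  X_pred = X_m·e^{μN_p}, the unbled trajectory;
* update semantics — `increment` (default): the correction is added to
  the running command; or `replace`: the correction *is* the command.

The default pairing is the only one with the exact closed-loop fixed
point b = μ·V_r at X = X_sp: with zero noise the commanded rate is
constant and X ≡ X_sp to machine precision, which is the behaviour a
steady-state simulator must reproduce.  The `zero_bleed`/`replace`
pairing is the predictive law in its literal closed form; it commands
1.903 L/day instead of 2.0 at the set point (for μ = 0.2, N_p = 0.5 d,
V_r = 10 L) and therefore equilibrates at a small static offset above the
set point, X_sp/((1−μN_p)·e^{−μN_p})-fold ≈ +0.22 MVC/mL at the reference
settings.  It is retained as an option, as is the literal reading of the
forward VCC estimate in which the growth factor multiplies only the bleed
term (`literal=True`); that grouping lacks the steady-state fixed point
altogether and is provided for comparison only.

The controller predicts with the *nominal* growth rate by default
(`mu_source="nominal"`): a real controller cannot observe the realised
noisy rate of the coming interval.  `mu_source="plant"` emulates an ideal
growth soft sensor and is useful for bounding how much of the residual
error is attributable to growth-rate uncertainty rather than to the
control law.  The quadratic cost J = X_diff + R·ΣΔU² (R = 5) is evaluated
and logged every cycle as a diagnostic; the commanded rate comes from the
closed-form law, which contains no R, so the weighting influences
reported traces but not the trajectory.

## Noise model

Growth rate and productivity are drawn from N(nominal, (0.20·nominal)²),
truncated at zero by redraw.  ±20 % is read as a 1σ relative dispersion.
Draws are redrawn at every pump update within an iteration (default);
per-iteration-constant draws are selectable (`noise_cadence="iteration"`).
The per-interval cadence is the default because a constant-μ iteration
produces bounded oscillations under FC, whereas per-interval redraws
produce the characteristic growing-amplitude behaviour that motivates
predictive control.  q_p noise follows the same cadence as μ for
symmetry.  One consequence worth stating: with a 6-h cadence the plant
accumulates X_sp·σ_μ·PUI ≈ 0.4 MVC/mL (1σ) of biomass drift *within* a
single interval at the reference settings, and no controller acting at
that cadence can reject noise it has not yet observed — this sets the
noise floor of every deviation metric the package reports.

Seeding: a master `SeedSequence` spawns one child per iteration, so
ensembles are bit-for-bit reproducible and FC/SPC ensembles with the same
master seed experience identical noise sequences (the controllers
themselves consume no randomness).

## Simulation conditions

Reference study settings (package defaults): V_r = 10 L, X_sp = 40
MVC/mL, μ = 0.2 1/d, q_p = 20 pg/cell/day, P = 2 VVD (strategy A),
cap 40 % of P, PUI 6 h, N_p 12 h, N_c = PUI, R = 5, 30 days, n = 100
iterations, inner step 0.01 d, traces stored once per PUI (finer storage
configurable).  Iterations start in steady state — X = X_sp,
b_m = μ·V_r, c = q_p·X·10⁻³/P — because bleed control is only active once
equilibrium is reached.  An iteration whose biomass exceeds 10× the set
point is aborted, reported and excluded from ensemble statistics.  The
set-point grid sweep covers the full factorial {20, 40, 80} MVC/mL ×
{0.1, 0.2, 0.3} 1/d × {1, 2, 3} VVD (27 combinations); combinations whose
nominal bleed demand exceeds the cap (μ > 0.4·P) are flagged infeasible
rather than run.

## Statistics

Bands are pointwise normal-theory intervals: CI = mean ± z·s/√n for the
mean, PI = mean ± z·s·√(1+1/n) for a future iteration (z the two-sided
standard-normal quantile; empirical-quantile prediction bands are
available as an option).  Error distributions pool (X − X_sp) over all
iterations and all stored timepoints after a 1-day burn-in, identically
for both controllers.  Shape statistics use population moments: skewness
g₁ = m₃/s³ and kurtosis m₄/s⁴ with divide-by-N moments and biased s;
kurtosis is reported both plain (normal → 3) and as excess (normal → 0),
and both are undefined (NaN) for a degenerate sample.  Histograms use
Freedman–Diaconis binning by default.

Mass totals integrate the stored flows and c·flow products trapezoidally.
On the default storage grid the flows are piecewise constant per control
interval, so the trapezoid on interval boundaries is exact for volumes
and accurate to the storage resolution for product masses; volume closure
of the integrated totals follows from per-row flow closure.  The strategy
comparison rescales the strategy-B totals linearly to the strategy-A
total feed volume before differencing ("equal media budget"), with the
strategy-B harvest set point defaulting to H = P_set − μ so both runs
share the same nominal steady state.

## What the generator does and does not emulate

The synthetic campaigns emulate: steady-state perfusion at constant
volume, growth-rate and productivity variability on the controller's own
time scale, bleed actuation limits, and the propagation of biomass
control error into titre and harvest flow.  They do not emulate: sensor
noise or delay, substrate limitation or metabolic shifts, retention
efficiency below 100 %, volume excursions, start-up transients, or any
downstream dynamics.  Passing tests therefore demonstrate properties of
the closed control loop under the stated noise model, not fidelity to any
particular cell line's biology; in particular, the absolute magnitudes of
all deviation metrics scale with the assumed noise amplitude, which is
the least certain input of the model.

## Numerical choices and degenerate inputs

Closure is enforced to 10⁻¹² relative; commands are floored at 0; the cap
is applied inside the allocation routine so every stored row satisfies
B ≤ 0.4·P exactly.  A controller fault (non-positive measurement,
over-bleed in the forward estimate) holds the previous command for one
interval rather than aborting the run.  Zero noise short-circuits the
draw (no RNG consumption differences between deterministic runs).
Duration must be an integer multiple of the PUI, and the PUI an integer
multiple of the inner step, so grids align exactly and row counts are
predictable (duration/store-interval + 1 rows).

## Known limitations

* The two controllers share the bleed actuator model but not a tuning
  procedure; FC gain is fixed by its law, so FC-vs-SPC comparisons are
  comparisons of the two laws as given, not of optimally tuned variants.
* At the default ±20 % noise the FC loop spends part of each run railed
  against the bleed floor; its pooled error distribution is then shaped
  by the saturated limit cycle (slightly platykurtic) rather than by the
  linear-regime amplitude growth (leptokurtic).  Both regimes are
  reachable through `noise_cv`.
* The product ODE assumes instantaneous mixing and a productivity that
  responds to nothing but the drawn q_p; product-quality attributes are
  not modelled.
* `run_grid` sweeps strategy A only; strategy-B grids can be composed
  manually from `run_ensemble`.
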