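# Methods

## Scope and intended data

greycast targets univariate, strictly positive, equally spaced count series
of length roughly 8–25 — annual accident-fatality records being the
motivating case.  Zeros are rejected rather than epsilon-adjusted: both the
accumulated-scale models and MAPE are undefined at zero, and silently
perturbing the data would corrupt every downstream percentage.  Period labels
(years) are metadata; all model mathematics uses the 1-based position
t = 1…n.

## The DNGM(1,1) model

The discrete nonhomogeneous grey model assumes the accumulated series
x⁽¹⁾ follows the whitening equation dx⁽¹⁾/dt + A x⁽¹⁾ = Bt + C.  Solving it
and anchoring at the first observation gives the time response

    x⁽¹⁾(t) = K e^{−A(t−1)} + (B/A)t − B/A² + C/A ,
    K = x⁽¹⁾(1) − B/A + B/A² − C/A ,

and, by first differencing, the original-scale restoration

    x̂⁽⁰⁾(t) = (1 − e^{A}) K e^{−A(t−1)} + B/A        (t ≥ 2) .

On the original scale the model class is "constant plus decaying (or growing)
exponential" — a *nonhomogeneous* exponential, which is what distinguishes it
from GM(1,1)/DGM(1,1) and makes it suitable for series that decline toward,
or rise away from, a nonzero floor.

The time response satisfies exactly the linear recursion

    x⁽¹⁾(t+1) = α x⁽¹⁾(t) + β t + γ ,
    α = e^{−A},  β = (B/A)(1 − e^{−A}),  γ = (1 − e^{−A})(C/A − B/A²) + B/A ,

so the estimation is least squares on the n−1 stacked recursion equations
(the drift regressor is the *source* index t).  Because the recursion is an
exact consequence of the ODE, the discrete estimate carries no
discretisation error.  The inverse mapping A = −ln α, B = Aβ/(1−α),
C = A[(γ − B/A)/(1−α) + B/A²] recovers the continuous parameters whenever
α > 0 and α ≠ 1; otherwise the whitening form is simply unavailable and all
simulation/forecasting proceeds by iterating the recursion, which is always
defined and is the implementation's single simulation path for DNGM.

### Why GM(1,1) differs

GM(1,1) estimates its development coefficient from the trapezoidal
difference equation x⁽⁰⁾(k) = −a z⁽¹⁾(k) + b with background values
z⁽¹⁾(k) = ½(x⁽¹⁾(k) + x⁽¹⁾(k−1)) (weight fixed at ½), but simulates through
the exponential time response.  The two are consistent only in the limit
a → 0: on exactly geometric data the difference equations are satisfied with
zero residuals, yet the restored values are biased (on [2, 1, 0.5, 0.25] the
restored second value is ≈ 0.9732, not 1).  The discrete models (DGM, DNGM,
IDGM, DDGM) have no such gap: they simulate by iterating the very recursion
they estimate, so data generated exactly by their own recursion is restored
exactly.  The test suite asserts both facts; they are why exact
in-sample recovery is asserted for the four discrete models but only
parameter recovery for GM.

### IDGM and DDGM reconstructions

The source literature describes these two variants only in prose, so the
plain reconstructions adopted here are documented explicitly:

* **IDGM(1,1)** treats the accumulated series as the raw input: it
  accumulates a second time to x⁽²⁾, fits the DGM recursion
  x⁽²⁾(k+1) = β₁x⁽²⁾(k) + β₂, and restores twice, each difference anchored at
  its first observed element.  Note this model is *not* exact on constant
  series (x⁽²⁾ of a constant series is quadratic, which the two-parameter
  recursion cannot interpolate); its exactness class is data whose x⁽²⁾
  follows the recursion.
* **DDGM(1,1)** fits x⁽⁰⁾(k+1) = β₁x⁽⁰⁾(k) + β₂ directly on the raw data
  with no accumulation, and is allowed from three points (two equations, two
  unknowns); all other models require four.

Published variants of either may differ; results for them should be read as
"a plain indirect/direct DGM", not as a canonical citation.

## Metabolic (rolling) models

A static model fitted once to a long span encodes the whole history,
including regimes that no longer hold.  The metabolic scheme refits on a
sliding window of the n most recent observations before every one-step
forecast: window {t−n…t−1} → forecast x̂⁽⁰⁾(t).  During retrospective
evaluation windows contain *actual* observations only, so each recorded error
is an honest one-step-ahead error; `roll_extrapolate` is the separate,
clearly-labelled mode in which forecasts feed back into the window to reach
beyond the last observation (errors compound there).

Evaluation index sets — the main source of irreproducibility when comparing
grey-model results — are fixed as follows and embedded in every report:

* static fits: t = 2…n (the t = 1 point is anchored to the data by
  construction and would deflate the average);
* rolling models: t = n+1…n_obs (the first n points are in-window, reported
  as "in-window, not forecast", never scored).

Window-size selection sweeps candidates (default 4…10) and takes the argmin
of the rolling MAPE.  Infeasible candidates (below a model's minimum, or
leaving no forecast step) are skipped with a warning and recorded as
undefined rather than aborting the sweep.  Candidates within 1e-9 percentage
points of the minimum count as tied; ties resolve to the smallest window and
are flagged.  Per-step fit failures (near-singular windows) are recorded as
undefined steps and excluded from the MAPE, again with a warning — the log is
the audit trail for every reported number.

Small windows deserve caution: a four-point window gives DNGM's three
parameters exactly three equations, so every window is interpolated perfectly
and the forecast is an unregularised extrapolation — on noisy data the n = 4
MAPE is typically several times the n = 6 one, which the sweep makes visible.

## Numerical choices

* Estimation solves each stacked linear system by SVD least squares; a naive
  normal-equations/Cramer solve exists in the test suite as an independent
  oracle, not in the library (same answer, worse conditioning).
* A design matrix with reciprocal condition number below 1e-12 marks the fit
  `well_posed = False`; fitting returns diagnostics instead of raising, but
  simulation from an ill-posed fit raises.
* |α − 1| < 1e-12 is treated as α = 1 (whitening form unavailable);
  |a| < 1e-12 in GM degenerates to the exact linear-accumulation limit, i.e.
  a flat forecast at level b.
* Simulated/forecast series are returned with positivity checks relaxed —
  a bad fit may legitimately predict nonpositive values, and the evaluator
  should see them; metabolic *extrapolation* stops with an error if a
  forecast becomes nonpositive, since it would have to be fed back as data.

## Synthetic data

The generator emits four processes: the exact DNGM family (constant plus
exponential on the original scale, first value anchored), exact geometrics,
the DNGM family under multiplicative Gaussian noise value·(1 + ε),
ε ~ N(0, sd) with a 1e-6 positivity floor, and two-regime break series.
Multiplicative noise was chosen because annual count data fluctuate roughly
proportionally to their level; it is not a claim about any particular real
series.  Seeds are mandatory and never derived from the clock.

Two documented presets fix the study conditions used across the tests:

* **fig2-like** (length 20, periods 2000–2019, seed 2019, noise sd 6%):
  a 14-period decline from ~1200 toward ~620 (level 600, amplitude 600,
  rate 0.25) followed by a 6-period renewed rise to ~980 (level 380,
  amplitude 220, rate −0.20) — the decline-then-pronounced-rise shape of a
  long-run construction-fatality record, with the rise magnitude (~+60% in
  five periods) matching that record's rebound.  The noise level puts
  one-step-ahead errors of a well-sized metabolic model in the high single
  digits of percent, the regime where these models are typically reported.
* **table1-like** (length 10, periods 2010–2019, seed 2010, noise sd 4%):
  a declining series at road-fatality scale (65 000 → ~56 000), long enough
  for window candidates 4…9 but not 10, exercising the sweep's skip path.

What the synthetic processes do **not** emulate: genuine count (integer)
noise, serially correlated shocks, outliers from single catastrophic events,
policy-driven level shifts mid-regime, and any seasonal structure.  Passing
tests on these fixtures therefore demonstrate correctness of the estimation,
restoration and metabolism machinery and the qualitative static-vs-dynamic
contrast — not forecast accuracy on any real series.

## Problem sizes

Everything is small by design: series of length ≤ 20, 1 000 parameter draws
for the closed-form/recursion equivalence check, 200 random windows for the
estimation cross-check.  The full test suite and the acceptance script each
run in seconds on one CPU.

## Known limitations

* One variable, first order: no GM(1,N), no fractional-order accumulation,
  no background-value weight optimisation (fixed at ½), no interval/fuzzy
  grey numbers.
* MAPE is the only accuracy index, as the sweep criterion and the report
  metric; RMSE/MASE and significance tests of accuracy differences are out
  of scope.
* The IDGM/DDGM forms are reconstructions from prose descriptions (above).
* Rolling evaluation is strictly one-step-ahead; multi-step rolling error
  matrices and expanding windows are not implemented.
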