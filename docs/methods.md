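# Methods

## Model and estimation

The fitted model is `y(t) = B + A·exp(−k·t)·sin(2πt/T + P)` with the
period `T` held fixed (24 h by default).  The literal exponentially
damped sine — damping factor `exp(−t)` with `t` in hours — suppresses
the oscillation by e⁻²⁴ within one period, which is incompatible with
multi-day oscillatory recordings; we therefore treat the damping as a
rate parameter `k` estimated within `[0, k_max]`, with `k_max = 0.2 /h`
by default (amplitude half-life ≥ 3.5 h, generous for culture
desynchronization), and provide `k_fixed=1.0` as a literal mode.
`fit_damping=False` freezes `k = 0` (plain cosinor).

Estimation is nonlinear least squares (`scipy.optimize.least_squares`,
analytic Jacobian).  Sinusoid fits are multimodal in phase, so the
optimizer is multi-started from 8 equally spaced phases in `[0, 2π)`
with `A₀` = half the data range and `B₀` = the data mean, plus
variable-projection starts: for fixed `k` the model is linear in
`(B, b1, b2)` with `b1 = A cos P`, `b2 = A sin P`, so an exact linear
solve at a few candidate damping rates seeds the nonlinear refinement.
In practice this start already sits at the global optimum of the
undamped problem, which is why the fit reliably attains the minimum
located by an exhaustive phase-grid oracle in the tests.  The best
start by residual sum of squares wins; the result is normalized to
`A ≥ 0`, `P ∈ [0, 2π)` (the two representations `(A, P)` and
`(−A, P+π)` describe the same curve).

By default the per-time replicate means are fitted (an option fits all
points); the degrees of freedom use the number of fitted points minus
the number of free parameters (3, or 4 with damping).  `R² = 1 −
SSres/SStot` with SStot about the mean of the fitted values; a series
with SStot = 0 is rejected rather than assigned an R².  Fewer points
than free parameters is an error, surfaced as a non-rhythmic call with
reason `fit_error` in batch runs.

The parameter covariance is evaluated in the linear parametrization
`(B, b1, b2[, k])` — an exact reparametrization of the asymptotic
covariance at the optimum that stays well-conditioned as `A → 0`,
where the phase column of the `(B, A, P)` Jacobian vanishes.  Reported
standard errors for `A` and `P` come from the delta method.

## Rhythmicity gates

A series is rhythmic iff `R²` exceeds the threshold (0.55 by default;
configurable because reported gates vary between 0.5 and 0.55 across
assay types) AND the zero-amplitude test rejects.  Both gates are
reported separately, with the failing gate(s) named.

**Zero-amplitude test.**  The default test asks whether the joint
`1−α` confidence ellipse of `(b1, b2)` excludes the origin — the
classical cosinor rhythmometry zero-amplitude test, computed as a
2-degree-of-freedom F statistic `F = β̂ᵀΣ̂⁻¹β̂ / 2` against
`F(2, dof)`.  The reported amplitude CI is the range of
`√(b1² + b2²)` over the ellipse (lower bound set to 0 when the origin
is inside), evaluated on a 1440-point boundary grid — amplitude is
convex, so the extremes lie on the boundary; the grid resolution error
is < 10⁻⁵ relative.  For the undamped model under Gaussian noise this
test is exactly calibrated, and the simulation suite verifies a ~5%
type-I error over 1000 null series.

A Wald interval `A ± t(1−α/2, dof)·SE(A)` is available
(`method="wald"`) because it is what common curve-fitting software
prints.  It is deliberately not the default: under the null the fitted
phase maximizes the apparent amplitude, making `Â/SE(Â)` behave like
`√(2F(2,dof))` rather than a t statistic; the measured null rejection
rate is ≈ 0.13 at nominal 0.05.  Singular covariance (collinear design,
e.g. from pathological time grids) yields `significant = False` with
reason `singular_covariance`; a numerically perfect fit (SSres ≤ 10⁻¹²
· SStot) collapses the CI onto the point estimate and is significant
whenever `A > 0`.

Damping is fitted for population and single-cell series (it absorbs
bleaching-like decay; no other detrending is applied).  The calibration
simulations freeze `k = 0`, since under the null the damping rate is
unidentifiable and the boundary constraint distorts the reference
distribution; the calibration statement therefore applies to the
undamped test.

## Normalizations

Ratio-to-reference divides each quantity by its matched loading control
(pairing preserved per replicate and time; missing/zero references are
an error naming the rows).  Percent-of-anchor scales by the replicate
mean at the anchor time (earliest sampled time by default, or a stated
time, or the latest).  Nuclear/cytoplasmic ratios are formed per
matched (time, replicate) observation — per replicate first, averaged
only by the fitter — with unmatched observations an error.  Fold
enrichment is the ratio of means.  R² is invariant to affine rescaling
of the values, so percent scaling does not change rhythmicity calls.

## Single-cell pipeline

QC retains a trace iff it was tracked ≥ 48 h and its mean fluorescence
is ≥ 1.10 × the field background, both bounds inclusive (equality at
floating-point tolerance passes).  Background is a supplied per-field
scalar; background estimation from images is out of scope.  Retained
traces (96 h at 0.5-h spacing by default) are fitted with the damped
cosinor, T = 24 h fixed; per-line summaries count rhythmic cells, and
lines are compared with Fisher's exact test on the pooled 2×2
(rhythmic × line) table, two-sided, since per-cell calls are binary and
well structure is not always available.

## ANOVA for foci counts

Per-well totals sum all cells; the per-cell mean is computed over
focus-positive cells only (zero-foci cells count toward totals but not
the mean; an all-zero well is flagged, not averaged).  One-way ANOVA
(via `scipy.stats.f_oneway`, with explicit df bookkeeping) is applied
to well totals grouped by time point and to per-cell counts grouped by
time point — the two groupings correspond to the two reported df
structures.  For two groups F equals the squared pooled t statistic;
the tests verify this identity and a closed-form textbook example.

## Synthetic data: what it emulates, what it does not

The generators define the study conditions for every test:

* **Population series** — damped cosinor plus i.i.d. Gaussian noise;
  defaults B = 100, A = 30 (percent-of-initial scale), k = 0.02/h,
  P = 1.0 rad, noise SD 10, 3 replicates, sampled every 4 h from T2 to
  T30 (8 points; `extended_grid` runs to T38).
* **Cell traces** — 200 cells over 96 h at 0.5-h spacing; background
  100; retained-cell brightness 1.3–2.5× background; rhythmic fraction
  0.5 among QC-passing cells, amplitude half the excess over
  background, per-cell damping ~N(0.005, 0.002)/h (clipped ≥ 0), phase
  ~N(π, 0.5); per-frame noise 3% of the cell level.  Non-rhythmic cells
  drift linearly (slope SD 0.0015/h).  10% of cells are truncated
  between 8 and 47 h (track loss) and 5% are set to 0.95–1.07×
  background to exercise both QC rules; generator labels record the
  intended violations, and the margins are wide enough that realized
  means never straddle the thresholds at these noise levels.
* **Pull-down libraries** — 500 true target genes and 1500 background
  genes, desk-scale rather than transcriptome-scale; true targets
  appear above 1 FPKM in each library with configurable per-library
  sensitivity (1.0 by default), background genes appear in each library
  with probability 0.5 at low log-normal FPKM (so some pass the cutoff
  in both libraries — shared noise); 10% of genes get a second, lower-
  FPKM transcript to exercise the max-per-symbol collapse.  External
  lists are built to exact intersection counts (sizes 362 and 675,
  sharing 68 and 182 genes with the truth set, 24 genes with each other
  of which 6 are targets) by drawing in-target members from the truth
  set and the rest from symbols outside the expression universe; the
  counts are exact against the true target set whenever sensitivity
  is 1.
* **Foci counts** — Poisson per cell; mean
  `2.5·(1 − 0.5·cos(2π(t−15)/24))` across time points 3, 9, 15, 21 h
  (trough at 15 h), 6 wells × 25 cells per time.

Real data differ in ways the generators do not model: correlated
replicate noise, non-sinusoidal waveforms, cell-to-cell period
dispersion, segmentation/tracking artifacts, transcriptome-scale
library sizes and annotation noise in symbol matching.  Passing tests
demonstrate that the estimators and set arithmetic are correct under
the stated model, not that the model captures every property of the
assays.

## Numerical choices and edge cases

Optimizer tolerances 10⁻¹² (xtol/ftol/gtol), ≤ 2000 evaluations per
start; non-convergence from every start is reported as
`converged=False` with best-found parameters and classified
non-rhythmic.  Covariance inversion falls back to a pseudo-inverse
with a `singular` flag when the normal matrix is ill-conditioned
(condition number > 10¹²).  Degenerate inputs (constant series, too
few points, all-zero wells, empty panels) produce explicit errors or
flags, never silent NaNs.  Problem sizes in the test and acceptance
runs — 1000 null series for calibration, 20 oracle instances, one
200-cell panel, 20 000-phase oracle grids — were chosen to keep
Monte-Carlo error small relative to the tolerances being checked.

## Known limitations

Period is never estimated and no nonparametric rhythm test is offered;
no multiple-testing correction is applied across a panel (matching the
analysis convention this package reproduces); the hypergeometric
overlap p-value is an off-by-default extension; amplitude comparison
between conditions ("knockdown reduces amplitude") is not implemented —
loss of rhythm is operationalized as control-rhythmic AND
treated-non-rhythmic under identical configuration.
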