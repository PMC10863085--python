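# Methods

## Preprocessing

A raw well trace is corrected by subtracting the *pointwise mean* of the
blank traces (wells containing medium only). By default the first three
samples in a file serve as blanks for every well; any list of sample names
can be substituted.

Optional smoothing is a centered rolling average (default window 10 points
when enabled; window 1 disables it). At the edges the window is truncated
symmetrically — both sides shrink by the larger overhang — so output length
equals input length, a constant series is preserved exactly, and the output
never leaves the input's range. Even windows place their extra point on the
left. Smoothing, when requested, is applied before log transformation, i.e.
the fitters see the smoothed trace.

The log transform maps a blanked series to `y = ln(N/N0)` with **N0 = the
smallest strictly positive value of the series**. The models never observe
the true inoculum size, so a measured reference is required; the minimum
makes `y ≥ 0` everywhere and ties the total-doublings count ("from lowest to
highest measured population size") to the same reference. Points that are
zero or negative after blanking are *masked*, not clipped: masked points are
invisible to the fitters and break subsegment contiguity for the
sliding-window method. A trace with no positive point at all is an error
("entirely at or below blank").

Consequence worth knowing: on noisy data the minimum positive value is
biased low (it is an extreme order statistic), which shifts `y` up by
`ln(N0_true/N0_hat)` and inflates A estimates for wells with small inocula.
This is intrinsic to any measured-minimum reference and is visible in the
noisy validation study below; smoothing before transformation reduces it.

## Growth models

Both sigmoids are used in the Zwietering parameterization (asymptote
`A = ln(N∞/N0)`, maximum specific rate `μmax` in h⁻¹, lag `λ` in h):

* Logistic: `y = A / (1 + exp[4μmax/A (λ−t) + 2])`; inflection at
  `λ + A/(2μmax)` where `y = A/2`.
* Gompertz: `y = A exp(−exp[μmax e/A (λ−t) + 1])`; inflection at
  `λ + A/(e μmax)` where `y = A/e`.
* Exponential: `N = N0 exp(μmax t)`, i.e. `y = μmax t`; it has no lag or
  plateau, so landmark queries on it raise an unsupported-model error rather
  than returning sentinel numbers.

Phase landmarks come in two conventions, selected by a single switch that
applies to both ends of the phase:

* **standard** — the tangent construction: lag = `λ` (the tangent at the
  inflection crosses y = 0 there, by construction of the parameterization);
  phase end = `λ + A/μmax`, where the same tangent reaches `y = A`. Identical
  for both models.
* **tight** — the curvature construction: the phase is bounded by the
  smallest and largest zeros of `d³y/dt³`. These are found numerically:
  closed-form third derivatives, sign-change bracketing on a 4001-point grid
  spanning `[λ − A/μ, λ + 3A/μ]`, then Brent refinement to 1e−10 h. The
  logistic zeros have a closed form (sigmoid levels `(3±√3)/6`, giving tight
  lag `λ + A/(2μ)(1 − ln(2+√3)/2)`), used in tests as an independent
  cross-check of the root finder, never as the implementation; the Gompertz
  zeros are transcendental (`e^{-u}` levels `(3±√5)/2`). The tight interval
  lies strictly inside the standard one for every valid parameter set.

## Fitting

**Parametric.** Nonlinear least squares of the model against all valid
points, via trust-region-reflective least squares (bounds keep A, μmax
positive), tolerances 1e−10, at most 5000 evaluations. Initialization is
data-driven: `A₀ = max(y)`; `μ₀` = the largest centered finite-difference
slope; `λ₀` = (time of that slope) − y/μ₀, floored at 0. Bounds:
`A ∈ (0, 2·max(y)]`, `μ ∈ (0, ∞)`, `λ ∈ [t_min − span, t_max]`. Optimizer
failure is reported as `converged=False` rather than an exception so whole
plates can be fitted in one pass. Standard errors are
`sqrt(diag(inv(JᵀJ)·RSS/(n−3)))` from the final Jacobian, NaN when the
normal matrix is singular. Degenerate inputs fail fast: fewer than 5 valid
points is a data error, a perfectly flat trace a non-identifiability error.

**Easy Linear.** An ordinary least-squares line through every contiguous run
of exactly `w` valid points (default `w = 10`; the underlying publication of
the heuristic leaves the default open, and 10 matches the smoothing default
— too small a window overestimates the rate on noisy data). The maximum
slope is `μmax`; ties are broken toward the earliest window so output is
deterministic. The winning window's first and last data indices delimit the
exponential phase. A masked point splits the trace: no window spans a gap.

**Manual.** A least-squares line through the valid points inside a
user-chosen `[t_start, t_end]`; needs at least two points. Running it over
the Easy Linear winning window reproduces the Easy Linear slope exactly.

## Derived statistics

Doubling time `ln2/μmax`. Doublings in exponential phase
`μmax·(t_end − t_start)/ln2` — with standard bounds this equals `A/ln2`
exactly, since `μmax·(t_end − t_start) = A` by the tangent construction
(note it is *not* `Δy/ln2`: the sigmoid rises only ~76% (logistic) of A
between the standard bounds, the tangent construction deliberately
over-covers). Total doublings `log₂(Nmax/Nmin)` over the positive blanked
trace. Yield is the *measured* maximum of the blanked trace — uniform across
all three fitting methods; the fitted plateau `N0·e^A` is additionally
exposed for parametric fits. Window methods leave the lag undetermined (a
slope carries no lag information). Every underivable statistic is NaN, and
NaN propagates to the summary file as the literal `nan`.

Replicates are grouped by identical sample name in order of first
appearance. Group statistics are NaN-aware means and *sample* standard
deviations (ddof = 1; a singleton group has NaN sd) over non-excluded
members; a fully excluded group reports NaN and its exclusion counter.

## Plate-position mapping

With 6, 12, 24, 96 or 384 samples, the 1-based sample ordinal maps row-major
onto the plate (96-well: 8×12, so sample 14 → B2); other counts use the
ordinal itself as the label. The mapping is by sample ordinal, not file line
number (the time row does not shift positions).

## Synthetic validation study

The generator draws parameters independently and uniformly from
`N0 ∈ (0, 0.5)`, `A ∈ (0.5, 4)`, `μmax ∈ (0, 2)` h⁻¹, `λ ∈ (0, 100)` h —
ranges spanning typical microplate experiments from slow to fast growers —
redrawing N0 or μmax below 1e−3 to avoid numerically invisible curves. Each
curve is rendered in population space `N = N0·e^{y(t)}` on a 0–200 h grid at
0.5 h steps (401 points; the grid accommodates λ up to 100 h plus
saturation), with optional additive Gaussian noise of sd 0.01 population
units by default — noise lives in population space, as instrument noise on
OD does. Curves whose standard phase end exceeds the grid are fitted anyway
and counted as unsaturated.

Each curve then runs through the *same* pipeline measured data would: log
transform with measured-minimum reference (the true N0 is never revealed)
and a nonlinear fit with the generating model. Recovery is summarized as the
median over converged fits of `|estimate − truth|/|truth|` per parameter;
more than 50% non-convergence aborts the study as uninterpretable.

At study scale (100 curves per model) noise-free recovery is exact to
optimizer precision (medians ~1e−15, reported as 0.000 at three decimals),
and under the default 0.01 noise the medians stay below 0.071. What this
does and does not show: the generator produces ideal sigmoids with
independent Gaussian noise — no drift, no diauxie, no death phase, no
condensation artifacts — so passing validates the *estimator machinery*
(transform, optimizer, landmark algebra), not the adequacy of sigmoid models
for any particular organism. Curves violating the models are exactly the
cases the Easy Linear and manual routes exist for.

## Numerical conventions

* Times are hours throughout; rates h⁻¹; no date parsing.
* Summary CSVs print floats with shortest round-trip `repr`, so re-reading
  (with round-trip float parsing) reproduces every bit; XLSX round-trips at
  the format's 15 significant digits.
* The Easy Linear slope comparison is strict (`>`), fixing the earliest-
  window tie-break; under exact slope ties the winning *window* is therefore
  formula-independent only up to floating-point rounding of the tied slopes.
* Random studies are driven by a single integer seed through numpy
  Generators; identical seeds reproduce reports bit-for-bit.
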