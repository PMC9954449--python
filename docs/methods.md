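# Methods

## The agreement model

The unit of analysis is a cases × observers matrix of ordinal categories,
obtained by applying a cut-off scheme to continuous percentage scores. For a
set *S* of observers, the overall percent agreement OPA(*S*) is the fraction
of the *C* cases on which every observer in *S* assigned the identical
category; it is always a multiple of 1/*C*. For an ordering (permutation) of
all *n* observers, the OPA curve is OPA over the growing prefix, *k* = 2…*n*.
Because the set of unanimously rated cases is intersected as each observer is
added, every curve is non-increasing, all curves meet at *k* = *n* in OPA(n),
and the prefix OPA at *k* depends only on *which* observers are in the prefix,
not their order — which is what makes exhaustive subset enumeration a valid
oracle for sampled extrema.

An analysis samples `n_permutations` **distinct** observer orderings (default
100). When *n*! ≤ `n_permutations` all permutations are enumerated instead
(exhaustive mode; at the default this covers *n* ≤ 4), making small-panel
results exact rather than resampled. Sampling without replacement costs
nothing at large *n*, where duplicates are practically impossible anyway, and
guarantees the distinctness property at small *n*.

## Readings and the plateau rule

* **OPA(n)** — full-panel agreement; shared endpoint of every curve.
* **Bandwidth** — max − min OPA at *k* = 2 over the sampled curve bundle.
  This matches the plot-based definition read off a simplified ONEST figure.
  An `exact_bandwidth` option computes it over all C(*n*, 2) observer pairs
  instead; the sampled bandwidth is a lower bound of the exact one, and which
  variant a published figure used is generally not stated, so both are
  provided.
* **ONEST value** — published analyses read the plateau of the minimum curve
  by eye, and repeated runs of the same data are known to shift that read-off
  by a few observers. This package therefore uses an explicit rule: the ONEST
  value is the smallest *k* such that `min_curve(k) − min_curve(j) < ε` for
  every *j* ≥ *k* (vacuously true at *k* = *n*, so the value always exists and
  lies in [2, *n*]). The default tolerance ε = 1/*C* declares drops smaller
  than one case's worth of agreement — below OPA's resolution — to be noise.
  ε is exposed (`plateau_tolerance`, `--plateau-tol`) because the right
  tolerance is a judgement about the application, not a mathematical fact.
  The comparison uses a 1e-9 absolute guard so that a drop of exactly ε
  (e.g. exactly one case at ε = 1/*C*) reliably blocks the plateau despite
  floating-point subtraction.

## Cut-off schemes

Cut-offs t₁ < … < tₘ in (0, 100] induce half-open bins [0, t₁), [t₁, t₂), …,
[tₘ, 100]; a score lands in the highest bin whose lower bound it reaches
(so `v ≥ t` is inclusive, matching "< t vs ≥ t" definitions). The built-in
schemes are the two lymphocyte-predominant thresholds (≥ 50, ≥ 60), the
prognostic ≥ 30 threshold, and the three-tier 0–20 / 21–49 / ≥ 50 working
group classification, encoded with lower bounds {21, 50}: a non-integer score
in (20, 21) falls in the lowest tier, consistent with the "0–20%" label.

## Missing ratings

A missing cell is replaced by the arithmetic mean of the same case's observed
ratings, rounded to the closest integer with .5 rounding up. The mean is taken
per case (not per observer or globally) because a case's difficulty — its true
lymphocyte burden — is the dominant predictor of the score an absent observer
would have given; an observer-wise mean would ignore it entirely. The
operation is idempotent, and each imputed value lies within ±0.5 of the
case's observed range.

## Repeated-run comparison tests

Two rank-based procedures compare repeated analyses (e.g. three fresh
100-permutation draws, or runs with and without divergent raters):

* **Kruskal–Wallis** across minimum curves, one group per curve, with midrank
  ties and the standard tie correction (delegated to `scipy.stats.kruskal`;
  the all-identical-pooled-values case is defined as H = 0, p = 1). The n − 1
  values within one curve are prefix OPAs and therefore *not* independent;
  the test is the conventional screening device for this design and should be
  read as such, not as calibrated inference.
* **Two-sample Wilcoxon rank sum** on two sets of ONEST values, two-sided,
  midranks for ties. The exact method enumerates all C(n₁+n₂, n₁) group
  assignments, so its p-values are multiples of 1/C(n₁+n₂, n₁) — with 3-vs-3
  replicates the smallest attainable two-sided p is 2/20 = 0.1. Published
  p-values below that for such designs necessarily come from an approximate
  variant, so the tie-corrected normal approximation (no continuity
  correction) is also provided and is selected automatically for larger
  groups (min group size > 8 or more than 200 000 assignments).

## Synthetic rater studies

The generator emulates a panel reproducibility study of sTIL scoring. Per
case a latent true percentage is drawn from a two-component Beta mixture on
[0, 100]; each observer reports `clip(latent + noise + bias, 0, 100)` with
i.i.d. Gaussian noise and an optional per-observer additive bias (divergent
raters); cells are masked missing independently, with the guarantee that each
case keeps at least one observation.

Defaults describe a realistic circulation: 49 cases × 23 observers;
low component Beta(1.2, 6) (mean ≈ 17%, the lymphocyte-poor majority) with
weight 0.75 and high component Beta(6, 3) (mean ≈ 67%, lymphocyte-rich) with
weight 0.25; observer noise sd 10 percentage points, consistent with reported
between-observer differences of roughly ten absolute points; missing rate
0.002 (≈ 2 cells in a 49 × 23 matrix).

What the generator does *not* model: spatial heterogeneity within a slide and
field-of-view selection (a major real-world driver of disagreement),
observer-specific scale compression or rounding habits (real raters report
round numbers), and correlated errors between raters trained together. Tests
passing on these synthetics therefore demonstrate the correctness of the
*computation* — curve construction, plateau detection, sampling, statistics —
and the qualitative response of the readings to noise, outliers and score
distribution; they do not certify quantitative agreement levels for any real
panel.

## Numerical and design choices

* OPA values are computed as boolean-mean fractions; invariant checks compare
  `value × C` to the nearest integer at 1e-9.
* Median of an even number of curves = midpoint of the two middle values
  (NumPy convention).
* Exhaustive subset enumeration (`exact_extrema`) is guarded at 200 000
  subsets — a work bound rather than a hard cap on *n*, so full enumeration is
  available for any *n* ≤ 12 while pairs (*k* = 2) remain enumerable for much
  larger panels.
* Permutation sampling uses a single seeded NumPy `RandomState`; the seed is
  recorded in the result for provenance, and results are byte-reproducible
  given (matrix, permutation count, seed, tolerance).
* The simplified plot draws exactly the stored min/median/max arrays and the
  full plot exactly the stored curve bundle; CSV exports are written from the
  result object, never recomputed in the plotting layer.

## Problem sizes

The test suite and the acceptance script run on deliberately small panels:
oracle-equivalence checks use 3–7 observers (where all *n*! ≤ 5040
permutations are enumerated), structural property checks use up to ~40 cases
and 12 observers, and seed-averaged effect checks use 49 cases × 14 observers
over 50 replicate seeds. These sizes exercise every code path — exhaustive and
sampled modes, both bandwidth variants, both test methods — while keeping the
whole suite in the seconds-to-a-minute range.

## Known limitations

* The ONEST value depends on ε; two analyses are only comparable under the
  same tolerance. The default 1/*C* is a resolution argument, not an estimate
  of practical relevance.
* The minimum curve of a 100-permutation sample is an upper bound of the true
  worst-case curve (and the maximum a lower bound of the best case); for
  panels beyond ~7 observers the exact extrema are not enumerable and the
  sampled envelope is what the readings describe.
* The Kruskal–Wallis comparison inherits the dependence problem described
  above; its p-values are descriptive.
* No case-level resampling (bootstrap over cases) is offered: the method as
  implemented treats the case set as fixed.
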