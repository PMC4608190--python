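# Methods

## The Tucker3 model

`hetcube` decomposes a complete three-mode array `X[i,j,k]` (persons ×
symptoms × times) as

    x_ijk = Σ_{p≤P} Σ_{q≤Q} Σ_{r≤R} a_ip b_jq c_kr g_pqr + e_ijk

with loading matrices A (n×P), B (m×Q), C (T×R) and core array G
(P×Q×R).  The model is identified only up to invertible within-mode
transformations; we adopt the standard orthonormal parameterization —
columns of A, B, C orthonormal, core unconstrained — and fix the
remaining indeterminacies by convention (below).  No rotation
(varimax-style or otherwise) is applied to the fitted solution.

Assumptions worth stating explicitly: the cube must be *complete*
(persons with missing occasions are rejected, never imputed — the
least-squares decomposition has no missing-data mechanism), residuals
are treated as exchangeable in the least-squares sense, and ordinal
item scores are handled as numeric after recoding, as is customary for
questionnaire sum-type data.

## Preprocessing

The decomposition should describe heterogeneity *around* the average
course shared by the whole sample, so:

* **Fiber centering.** Each (item, time) fiber is centered across
  persons.  This removes every symptom's mean trajectory — exactly the
  "general trend" a shared recovery pattern induces.  Grand-mean or
  per-person centering would not remove it and are not offered.
* **Slab normalization.** Each item slab is rescaled to mean square 1
  (`Σ_it x²_ijt = nT`), so high-variance items cannot dominate the
  fit.  This is the common multiway convention for questionnaire items;
  it can be disabled (`normalize: none`) since other slab conventions
  exist in the literature and the choice is ours, not a data fact.

After both steps the total sum of squares is exactly `n·m·T`, the
denominator of every fit percentage.  The transform is affine per item,
so `inverse_transform` restores original units exactly (round-trip error
below 1e-9 is enforced by test).  A zero-variance item slab is an error
(`DegenerateItemError`): a constant symptom carries no heterogeneity
and cannot be normalized.

## Fitting: ALS / higher-order orthogonal iteration

Each sweep updates one mode's loadings to the leading left singular
vectors of the cube projected onto the other two modes' current
loadings, then recomputes the core.  Because every update solves its
subproblem exactly, the explained sum of squares never decreases; the
per-iteration fit trace is exposed on the results object and checked in
tests.  Convergence is declared when the relative fit change drops
below `tol` (default 1e-8), with at most `max_iter = 500` sweeps.

Multi-start: the truncated HOSVD start (leading singular vectors of the
three unfoldings) is always included, plus `n_starts − 1` random
orthonormal starts (default 5 starts total), all derived from a single
integer seed via independent counter-keyed generators, so a fit is
bit-reproducible given its seed.  When a projected subproblem has lower
rank than the requested component count (possible for unbalanced
component numbers), the singular basis is extended with a deterministic
orthonormal complement; the extra columns carry zero explained variance
and are free to rotate in later sweeps.

Output conventions, applied once after convergence with compensating
changes absorbed into the core so the reconstruction is untouched:

* columns within each mode ordered by descending explained sum of
  squares (squared norm of the matching core slice), ties kept stable;
* each column signed so its largest-magnitude entry is positive.

These make output reproducible across runs and platforms, but do not
(and cannot) remove the rotational indeterminacy inherent to the model.

## Fit percentage and parameter counting

`fit = 100·(1 − SSE/SST)` on the preprocessed cube.  For orthonormal
loadings `SSE = SST − ‖G‖²`, which is how the ALS loop evaluates it;
`fit_percentage` recomputes it from residuals as an independent check
written into every pipeline report.  Free parameters are counted as
`nP + mQ + TR + PQR − P² − Q² − R²`, the usual correction for
orthonormality plus within-mode rotational freedom.

## Choosing (P, Q, R)

A grid of component combinations is fitted and an elbow rule applied.
Two design points matter:

* **Feasibility.** A core with `P > Q·R` (or any permutation) is
  algebraically equivalent to the model with `P = Q·R`; the surplus
  components cannot change the fit.  The grid therefore contains only
  combinations with `P ≤ QR`, `Q ≤ PR`, `R ≤ PQ` (the min-product
  condition).  This is not merely an economy: an elbow rule that
  compares a model only against single-mode additions would otherwise
  always stall at (1,1,1), whose single-mode neighbours are all
  equivalent to itself.
* **Warm-started nesting.** Every combination's start set includes the
  orthonormally padded solutions of all maximal dominated grid entries
  (plus the HOSVD start).  Since the padded start already achieves the
  smaller model's fit and ALS is monotone, fit percentages are
  guaranteed non-decreasing along every coordinate of the grid.  The
  grid is scanned at a looser tolerance (1e-6) than a final fit, since
  only differences of tenths of a fit point matter for selection.

The selection rule (`select_model`) picks the smallest combination — by
total component count, ties broken lexicographically — none of whose
*minimal strictly-dominating* grid entries improves fit by at least
`min_gain_percent` (default 1.0 point).  The rule is deterministic and
monotone in the threshold, and the full grid is always emitted so users
can apply any other tradeoff.  Fit-versus-parameters selection for
Tucker models is inherently informal; this is our reproducible version
of it, not a canonical statistic.

## Interpretation tables

Items and time points are allocated to the component on which they have
the largest *absolute* score (the "boldface" rule familiar from factor
tables); the sign of the assigned loading is reported, and rows whose
top two absolute scores differ by less than 0.05 are flagged as
borderline.  The core array is emitted as a long-format labelled table,
person-component major, with values exactly equal to the stored core.
Narrative component labels are the analyst's job; nothing is inferred
automatically.

For recovery studies, `match_components` aligns estimated with
reference loadings by greedy maximum |Tucker congruence|
(φ = Σxy/√(Σx²Σy²)), reporting the permutation and signed φ per
column.  Because Tucker loadings are rotation-indeterminate, the
synthetic generator returns its ground truth in a canonical form (see
below) so that column-wise matching is meaningful.

## Latent-variable baselines

**Latent class analysis** of an n×m ordinal slice: K classes, items
conditionally independent given class, category probabilities free per
class/item.  EM with multiple random starts; responsibilities by Bayes'
rule, M-step weighted category frequencies.  Category probabilities are
floored at 1e-10 and renormalized so no person can reach zero density
in every class (underflowed responsibilities would otherwise yield NaN
log-likelihoods); the floor is far below any estimable probability and
perturbs EM monotonicity by no more than ~1e-9.  Parameters:
`(K−1) + K·m·(C−1)`.  Classes are reported in descending weight order
to resolve label switching.

**Growth mixtures** of n×T sum-score trajectories: class-specific
quadratic mean curves `β0 + β1 t + β2 t²` on raw time 1..T (an option
recentres time, affecting only coefficient interpretation).  Two
covariance structures, shared across classes: `σ²I` (LCGM — all growth
parameter variances fixed at zero) and `τ²J + σ²I` (GMM with random
intercepts; slopes and quadratic terms never vary within class).
Sharing σ² across classes stabilizes small-class estimation.  The
M-step is exact: with 1 in the design's column space, GLS for β equals
OLS on the responsibility-weighted mean trajectory regardless of the
covariance, and the variance components have closed-form maximizers
from the residual decomposition along/against the ones direction, with
τ² clamped at zero when the unconstrained maximizer is negative.
Starts: a deterministic severity-quantile split plus random
responsibility draws; the random-intercept fit additionally warm-starts
from the converged LCGM solution, so by EM monotonicity its
log-likelihood can never fall below the LCGM's (the LCGM is its τ²=0
restriction).  Likelihoods are exact multivariate-normal/multinomial
densities, so AIC/BIC are comparable across model families fitted to
the same data.  A class with fewer than ~10 persons triggers a warning,
not an error.

## Synthetic data

All inputs are emulated; generators are pure functions of their spec
(seed included).

* **Planted cubes** (`generate_planted_cube`): random orthonormal
  loadings, Gaussian core, white noise.  With `noise_sd=None` the noise
  level is derived from the realised signal so the construction-expected
  fit `100·‖S‖²/(‖S‖² + σ²nmT)` equals `target_fit` (default 80, the
  explained-variance regime typical of questionnaire cubes of this
  size).  The returned ground truth is the exact truncated HOSVD of the
  noise-free signal — the canonical representative of the planted
  (rotation-indeterminate) solution — making column-wise congruence
  against estimates well-defined.
* **QIDS-like cohorts** (`generate_qids_like`): defaults of n=82
  persons, 12 recoded items on a 0–2 scale, T=9 weeks; a shared
  downward latent trend (1.15 − 0.09·week), a stable person offset
  (SD 0.20), occasion noise (SD 0.32), and a planted
  3-archetype × 2-domain × 2-phase interaction table (quick recovery /
  persistent somatic / increasing symptomatology; somatic-affective vs
  cognitive-appetitive items; weeks 1–5 vs 6–9), thresholded at fixed
  global cutpoints.  The defaults are calibrated so the selection rule
  picks (3,2,2) at the default noise level — a property of the fixture
  suite, not a claim about any real cohort.  `raw_scale=True` instead
  emits the 16 raw 0–3 items (with mutually exclusive appetite/weight
  directions fixed per person) purely to exercise the recoding path.
* **LCA and growth data**: direct sampling from the respective models.

What the generators do *not* emulate: missing data and dropout, item
floor/ceiling idiosyncrasies, per-item thresholds (available as an
option but not default), serial correlation beyond the random
intercept, and treatment effects.  Passing recovery tests therefore
demonstrates correctness of the estimators under their own model
class and robustness to ordinal coarsening — not validity for any
particular clinical dataset.

## Problem sizes and numerical defaults

Simulation-based checks use 82×12×9 cubes (the reference cohort
layout), 20 replicates for recovery/selection/criterion rates, n=1000
for LCA benchmarks and n=200–500, T=9 for growth-mixture benchmarks —
sizes at which every construction-expected quantity is measurable while
the full suite runs in about a minute.  Defaults: ALS `tol=1e-8`,
`max_iter=500`, 5 starts; grid scan `tol=1e-6`, warm starts only;
EM `tol=1e-8`, `max_iter=500`, 10 (LCA) / 8 (growth) starts; selection
`min_gain_percent=1.0`.  All tolerances are configurable.

## Known limitations

* No missing-data support by design; reject, don't impute.
* No CANDECOMP/PARAFAC, Tucker2, constrained cores, bootstrap
  confidence intervals, or rotation of the fitted solution.
* The elbow selection rule is a heuristic; borderline grids (a planted
  component carrying under ~1 fit point) legitimately select the
  smaller model.
* Growth mixtures assume shared residual variance and random
  *intercepts* only; no random slopes/quadratics, no robust (sandwich)
  standard errors — model comparison here rests on likelihoods and
  information criteria, not on standard errors.
* Ordinal items are treated numerically after recoding; no
  item-response-theoretic measurement model is attempted.
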