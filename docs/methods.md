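# Methods

## Problem and model

Pediatric analyte distributions shift with growth, so one reference
interval (RI) per analyte misclassifies children at the edges of
development stages. The pipeline partitions age 1–<18 (completed years,
bin *t* covering [*t*, *t*+1)) into contiguous classes per analyte, then
decides per class whether the sexes need separate intervals, and finally
estimates the nonparametric central-95% RI per cell.

The partitioning model is ordered-sample clustering: classes must be
contiguous runs of age bins (no reshuffling), each bin represented by the
20-vector of its empirical percentiles P5…P100. Using a percentile profile
rather than a mean makes the row a sketch of the whole within-bin
distribution — location, spread and tail shape all participate in the
between-bin distances — while remaining robust to extreme values.
Percentiles are computed on raw values: quantiles are invariant under the
monotone Box–Cox transform, so transforming first would change nothing.
Box–Cox enters only where means matter (the summary-mode mean/median
choice and the Z-test inputs).

Columns are nondimensionalized by their maximum (`x'_ij = x_ij/x_max,j`)
in both percentile and summary mode, so heterogeneous scales contribute
comparably to the squared-Euclidean class diameters.

## Exact segmentation and the class-count rule

`optimal_segmentation` computes, for every k up to `k_max` (default 6),
the global minimum of the total within-class dispersion over all
C(n−1, k−1) contiguous partitions via the standard dynamic program, using
a precomputed diameter table built from prefix sums (O(n²m) time; n = 17
here, so cost is negligible). An exhaustive enumerator
(`brute_force_segmentation`) with the identical tie rule serves as the
independent oracle in the tests. Tie-breaking: a candidate cut only
replaces the incumbent when it improves the objective by more than 1e-12
relative, and candidates are scanned in ascending index order, so equal
optima resolve to the smallest cut indices, deterministically, in both the
DP and the oracle.

The class count is read from the drop curve f(k) = B*(n, k−1) − B*(n, k).
A drop is *substantial* when it is at least `tolerance × B*(n, 1)`
(default tolerance 0.05, i.e. 5% of the total dispersion — the package's
quantification of "f(k) close to zero"). The default rule
(`select_k(rule="elbow")`) subdivides while drops stay substantial and
returns the largest such k — the bend where the B*–k curve flattens. If
even f(2) is below the floor, 1 is returned: no age partition.

Why not simply the argmax of f(k)? On profiles that trend monotonically
with age — the typical case for developmental analytes — the first split
captures more than half of the between-class dispersion whenever the
extreme classes differ most, making f(2) the maximum for essentially any
3-phase structure; the argmax rule would then terminate at k = 2 even for
perfectly separated three-segment data. The bend criterion recovers the
true phase count in that regime (verified by the recovery suite: 3-segment
cohorts with between-segment shifts ≥ 5 within-SDs yield k = 3 and the
true boundaries in ≈100% of seeded replicates). `rule="argmax"` is kept as
an option for comparison.

On age-homogeneous (pure-noise) profiles the elbow rule deliberately does
*not* try to report k = 1 reliably — successive noise drops remain a
sizable fraction of a small total dispersion. Protecting against
over-partitioning is the job of the next stage: statistical verification
merges everything back.

## Harris–Boyd verification and merging

Between-class differences are judged by the standardized mean difference
z = |m₁−m₂| / √(s₁²/n₁ + s₂²/n₂) against the sample-size-scaled critical
value z* = 3·√(n̄/120), n̄ = (n₁+n₂)/2. With the guideline-minimum 120
subjects per group z* = 3; the bar rises as √n̄ so that ever-larger
cohorts do not declare clinically meaningless differences significant.
Classes separate only when z > z*. (Stated decision rules for this
statistic sometimes appear with the inequality direction inverted;
the direction used here — large z keeps classes apart — is the one
consistent with the method's published outcomes and standard practice.)

When the pooled pair sample fails the Kolmogorov–Smirnov normality check
(one-sample, against a normal with the sample's mean/SD, α = 0.05) and is
strictly positive, both groups are Box–Cox transformed with a *shared*
lambda before the summaries are computed; a per-group lambda would make
the mean difference scale-incommensurable. Lambda maximizes the profile
log-likelihood on the grid [−3, 3] in steps of 0.05 (resolution well below
the ~0.15 differences that matter for this use).

Merging is greedy left-to-right with re-testing: whenever an adjacent pair
merges, the merged range is re-tested against its next neighbour, and
sweeps repeat until a full pass makes no change. The output is a fixed
point. With ≤ 6 candidate classes order effects are negligible, but the
rule is fixed for determinism. Sex testing applies the same pair test
M vs F inside each final age range.

## Reference intervals

Limits use the rank convention r = p(n+1) with linear interpolation
between order statistics, clamped to [1, n] — the same convention as the
percentile profiles, so the two stages are mutually consistent. Each
partition must contain at least 120 reference individuals; estimators
refuse smaller cells unless explicitly overridden (simulations only).

90% confidence intervals for each limit come from binomial order-statistic
ranks: bounds X₍ₗ₎ ≤ q_p ≤ X₍ᵤ₎ with each binomial tail ≤ 5%, so coverage
is ≥ 90% by construction (empirically ≈ 91–93% at n = 5000 in the
calibration test — slight over-coverage is inherent to the discrete rank
method). When no valid rank exists inside the sample (possible near the
edges for n ≲ 110 at p = 0.025), a seeded 2,000-resample bootstrap
percentile interval is used instead. The 90% level follows clinical
laboratory convention for reference-limit CIs.

Values reported at an assay's lower detection limit participate in the
ranks at the floor value; no distributional correction is attempted, and a
lower limit that lands at the floor is flagged `censored` so consumers
know the true 2.5th percentile may be lower.

## Synthetic cohorts

The generator emulates a cross-sectional screened cohort: per analyte and
sex, ages 1–17 are tiled by segments, each segment a normal or lognormal
distribution whose *exact* 2.5th/97.5th percentiles equal prescribed
limits (closed-form quantile matching — both families are monotone
transforms of a normal). Lognormal is the default for enzyme activities
(positive, right-skewed); an optional linear per-year drift of both
quantiles creates gradual trends without changing the family. Each
(age, sex) cell receives a fixed count (default 200, comfortably above the
120-per-partition minimum once bins are pooled); an optional per-analyte
floor models the detection limit. Draw order is fixed (age ascending, M
before F, analytes in spec order, one seeded generator), so identical
(spec, seed) give byte-identical cohorts.

The bundled example panel encodes age-segmented limits for AST, LDH, CK
and CKMB patterned on published pediatric myocardial-enzyme reference
data: AST and LDH decline in three phases, CK is age-stable, CKMB
diverges by sex from age 6 and has a 2.7 U/L detection limit.

What the generator does *not* emulate: within-segment continuous aging
(values jump at segment boundaries unless drift is set), analyzer batch
effects and drift, measurement rounding, correlated analytes within a
subject (draws are independent across analytes), non-lognormal skew
shapes, or realistic missingness. Passing recovery tests therefore show
the pipeline recovers piecewise structure of the stated form at the stated
sample sizes — not that real cohorts satisfy that form.

## Cleaning

Outliers are removed per (analyte, age bin) by the Dixon range test: the
larger end gap divided by the range, compared against 1/3, iterated until
stable (ties between ends delete the upper extreme). Survivors outside
Tukey fences (1.5×IQR) are flagged for inspection, not removed — the
box-plot step is an audit aid. A warning fires when more than 5% of a
sample is deleted. Subjects whose value is deleted leave that analyte's
analysis only, not the cohort.

Laboratory screening applies the standard exclusion thresholds (serology,
creatinine, uric acid, glucose, albumin, CRP, CK, hemoglobin, WBC) as
strict inequalities exactly as printed; threshold-equal values are kept,
and a record missing a screening field is never excluded on that field, so
screening is optional for synthetic cohorts.

## Problem sizes and determinism

The recovery suites use 200 subjects per age–sex cell (6,800 per
single-analyte cohort), 25 seeded replicates per segmentation claim and 50
per reference-limit claim, with CI calibration at 500 replicates of
n = 5,000 — sizes at which the recovery probabilities are effectively
saturated while the whole suite runs in well under a minute per claim.
All randomness flows through explicit integer seeds (numpy `default_rng` /
`SeedSequence`); reruns are bit-reproducible.

## Known limitations

- Age and sex cannot enter the segmentation jointly; sex is tested after
  age classes are fixed, so a sex difference confined to part of a class
  can be diluted.
- The elbow tolerance (5% of total dispersion) is a convention; cohorts
  with genuinely weak but real stage structure near that threshold will be
  sensitive to it.
- Percentile profiles at 20 fixed probabilities lose tail information
  beyond P5/P100 asymmetry; the RI stage re-estimates limits from raw
  values, so only the *partitioning* sees this coarsening.
- Detection-limit censoring is flagged, not modeled; heavily censored
  cells (> 2.5% at the floor) report the floor as their lower limit.
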