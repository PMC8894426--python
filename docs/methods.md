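# Methods

This note documents the statistical procedures `metabophen` implements,
the synthetic-data model used to exercise them, the numerical choices
made where the design was open, and the known limitations of each.

## Normalization chain

Raw peak areas for one matrix (cells, spent media, or blank media) pass
through, in order:

1. **Batch median scaling.** For each metabolite, observed values within
   each instrument batch are divided by their within-batch median, so
   every (metabolite, batch) group — and hence the metabolite — has
   median 1. Missing values never enter a median. A (metabolite, batch)
   group with no observed value is an error: imputation is defined
   *after* scaling and cannot rescue it.
2. **Protein normalization (cells only).** Each sample's values are
   divided by that sample's protein concentration, then each metabolite
   is re-scaled to overall median 1. The re-scaling median is global per
   metabolite (not per batch); this choice is recorded in the run
   manifest.
3. **Minimum-value imputation.** Each missing entry receives its
   metabolite's minimum observed scaled value across all batches. This
   presumes below-detection missingness, which is exactly how the
   generator censors. The imputed mask is carried alongside the data.
4. **Log + center-scale.** Natural log, then per-metabolite
   `(x − mean)/sd` with the sample sd (n − 1). Constant metabolites are
   dropped with a warning rather than erroring; their count is logged.

Two properties are worth knowing and are covered by tests rather than
hidden:

- With more than one batch, estimating and dividing out batch medians
  perturbs the error structure slightly. Per-feature null p-values are
  exactly uniform in the single-batch configuration and mildly
  *conservative* in the far tail with two batches; adjusted discoveries
  remain controlled either way.
- Minimum-value imputation puts a point mass at the imputation value.
  At the default 10% censoring this inflates the mid-tail of the null
  p-value distribution slightly (fraction below 0.05 around 0.07), while
  BH-adjusted null discoveries remain near nominal. Distributional
  calibration checks therefore run on un-censored nulls, and a separate
  test bounds the censored-null behavior.
- The chain applies batch median scaling *before* protein normalization.
  Because raw cell values scale with each sample's protein content, the
  batch medians are computed on protein-loaded values: the protein ranks
  of a batch shift every metabolite's median simultaneously, and after
  the (exact) protein division a residual, cross-feature-correlated
  noise component remains. On all-null cell data this raises the
  BH any-discovery rate to ≈ 0.07 versus ≈ 0.045 for the media path,
  which has no protein step (200 clean-null datasets of 30 × 500 each).
  FDR calibration is therefore asserted on the media path; the
  cells-path rate is computed and reported by the acceptance script, and
  cells-matrix discoveries should be read with this mild optimism in
  mind. Normalizing protein before batch scaling would remove the
  artifact but would change the normalization chain this package
  defines, so it is not the default.

## Differential abundance

Each feature (metabolite or log-ratio) is fit by OLS against
`intercept + group + age + sex`; for the two-group contrast samples
outside the contrast are excluded, for the three-group design two group
indicators are used and an omnibus moderated F is available. Models are
fit on the *natural-log* values, not the center-scaled ones:
coefficients are then log-scale effects, and — more importantly —
center-scaling every feature to unit total sd flattens residual
variances by construction, which would make the empirical-Bayes prior
degenerate and shrink genuine effects toward the pooled null.
Per-feature t and p are scale-invariant, so this choice only acts
through the moderation prior.

The prior `(d₀, s₀²)` is estimated by moment matching on
`z = log s²_g`: with `e = z − ψ(d_g/2) + log(d_g/2)`,
`ψ′(d₀/2) = Var(e) − ψ′(d_g/2)` is solved for `d₀` by a monotone Newton
iteration on the trigamma function (tolerance 1e-10, ≤ 100 iterations),
and `s₀²` follows from the matched first moment. When the empirical
dispersion of log variances does not exceed the chi-square baseline,
`d₀ = ∞` and `s₀²` is the bias-corrected geometric-mean pooled variance;
the moderated t then reduces to a z-statistic against the common
variance. Features with zero residual variance are excluded from prior
fitting and retained with p = 0 (nonzero effect) or 1. The
implementation reproduces the standard R implementation to ~1e-14 on a
frozen fixture.

Multiple testing is Benjamini–Hochberg step-up with enforced
monotonicity, significance at adjusted p < 0.05. Unadjusted pairwise
tests (Welch t; rank-sum, exact for combined n ≤ 20 without ties, else
tie- and continuity-corrected normal) are available for spot checks.

## Ratio features

Ratios are formed on the log scale *before* center-scaling (difference
of logs = log of ratio), then the ratio features themselves are
center-scaled for testing, clustering, and classification. Cells/media
ratios use each matrix's own fully normalized log values and exist only
for shared metabolites. Metabotype features are all unordered pairs of
panel metabolites detected in one matrix, stored in lexicographic order
(the reversed pair is the negation and would duplicate every test).
Ratio features are invariant to per-sample global log shifts, which
single-metabolite features are not — the core reason ratio analysis can
expose alterations that single-metabolite analysis misses.

## Correlation and clustering

Feature correlations default to Pearson (Spearman available); two-sided
p comes from the t transform `t = r√((n−2)/(1−r²))`, and the
significance mask is p < 0.05. Negative blocks are formalized — the
original identification was visual — by clustering features on `1 − r`
with complete linkage, cutting at distance 1.0 (clusters internally
positively correlated), and reporting every cluster pair of size ≥ 3
each whose mean significant between-cluster r ≤ −0.3, ranked by |mean
r|. Samples are clustered on `1 − Pearson r` between feature profiles
with complete linkage (distances in [0, 2]; merge heights
non-decreasing); the k-cut assigns each cluster its majority phenotype
and reports samples disagreeing with their cluster's majority, ties
broken toward "not misclassified".

## Classification

LogitBoost with depth-1 stumps, implemented from the additive logistic
regression formulation: per iteration, working responses
`z = (y* − p)/(p(1−p))` and weights `w = p(1−p)` with p clipped to
[1e-4, 1 − 1e-4]; the weighted least-squares stump is searched over all
(feature, midpoint-threshold) candidates with ties broken by (feature
index, threshold) for determinism; half the fitted value joins the
committee, and p updates through the logistic link. Multiclass uses
one-vs-rest committees and argmax. The iteration count is picked from a
grid (default {11, 21, 31}) by best LOOCV accuracy, ties to the smallest
count.

Feature variants: ALL_SIG (identity); REMOVE_LINEAR_CORRELATED (exact
linear combinations removed by rank-revealing pivoted QR at relative
tolerance 1e-8, then greedy pruning of pairs with |r| ≥ 0.90, dropping
the member with the larger mean absolute correlation); PCA (smallest
component set reaching 95% cumulative explained variance; the retention
threshold is configurable and achieved component counts are logged).

By default feature selection and extraction are fitted once on all
samples before the LOOCV loop — the protocol small-cohort biomarker
studies commonly use; this lets the held-out sample influence selection
and biases accuracy upward. `nested=True` re-fits selection inside each fold and is the
honest-generalization setting; both are exposed deliberately.

Reports contain the confusion matrix (truth rows), accuracy with exact
Clopper–Pearson 95% interval, the no-information rate (largest class
frequency), the one-sided exact binomial p against it, and
sensitivity/specificity for the declared positive class (cancer by
default) or per class one-vs-rest. Intervals always come from the
pipeline's own prediction count (20 for the two-group task); published
analyses of this kind sometimes print CIs implying a different effective
n, which this package does not attempt to match.

## Synthetic-data model

Log-scale generative model per observation:
`log x = μ_m + b_{batch,m} + effect + ε`, with per-metabolite baselines
`μ_m ~ N(10, 2)` (natural log; positive, right-skewed peak areas whose
absolute magnitude is irrelevant after normalization), per-(metabolite,
batch) effects `b ~ N(0, batch_sd = 0.3)`, and noise of constant sd
`noise_sd = 0.5`. Missingness is left-censoring at each metabolite's
`censor_fraction` (default 10%) quantile. Protein concentration is
log-normal with 20% CV around 2 (arbitrary units). Ages are uniform over
the study range identically in every group; batches are assigned
round-robin over a group-interleaved order so batch never confounds
group. Raw cell values carry each sample's protein factor
(`x · protein/2`), since pellet peak areas scale with the amount of cell
material — this is what makes the protein-normalization step a genuine
correction rather than an added noise source. All draws flow from one
seeded generator; identical seeds give bit-identical tables.

Correlation structure, chosen as the package's own design: metabolites
shared between cells and media split their noise into a cross-matrix
component (ρ = 0.5) and an idiosyncratic remainder — the same biology
sampled in a cell and its supernatant — which is what makes cells/media
ratios cancel shared fluctuations. Panel metabolites are organized into
pathway modules of 5 sharing a per-sample module factor (ρ = 0.5),
reflecting that a metabotype panel is by construction co-regulated;
planted ratio pairs are adjacent within-module pairs, so the pair's own
log-ratio is more stable than the nominal `√2·noise_sd` scale on which
the effect is expressed. Planted effect sizes are given in multiples of
the noise sd (`effect = 2` ⇒ a 2-SD log shift, 1.0 natural-log units at
defaults); realized shifts are recorded in the ground-truth record.

What the generator does **not** emulate: heterogeneous per-metabolite
variances (the moderation prior is instead validated directly on
simulated scaled-F variances), missing-not-at-random beyond left
censoring, instrument drift within batch, non-normal heavy tails,
sample-size imbalance, and any real metabolite identity. Passing tests
therefore certify the machinery — normalization algebra, test
calibration, recovery at stated effect sizes, classifier behavior — not
performance on real cohorts.

## Default problem sizes and runtime

Defaults mirror the study scale: 3 × 10 samples (7F/3M per group), 645
cell / 489 media / 386 shared metabolites, a 43-metabolite panel with 38
detected in cells and 39 in media (703 and 741 ratio tests), 2 batches.
Simulation-heavy checks use sizes chosen to keep a full test run on one
CPU in well under half an hour: FDR control uses 200 null datasets of
30 × 500; planted-effect recovery averages 20 cohorts at full scale;
permutation nulls use 100 label shuffles at n = 20; the acceptance
script scales these to 200/30/100 and adds one full default run plus its
byte-identical replay.

## Known limitations

- Min-imputation's point mass mildly distorts raw null p-values under
  censoring (documented above); alternatives (half-minimum, kNN) are out
  of scope.
- Blank media are normalized and carried for QC only, never subtracted.
- Paper-mode (non-nested) feature selection is optimistically biased by
  design; nested mode exists but is not the default, to mirror the
  original procedure.
- The g × 2 exact test enumerates tables with fixed margins; it is exact
  but exponential in the number of groups, fine for the 3 × 2 design it
  serves.
- Three-group classification reports per-class one-vs-rest sensitivity
  and specificity; no averaging convention is imposed beyond the grid's
  macro mean.
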