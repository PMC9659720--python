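# Methods

## Scope and model

`hullshift` screens multi-site tabular cohorts for dataset shift with
two complementary instruments and then checks what that shift does to
an actual endpoint model.

The object of study is a set of per-site patient-by-feature tables
drawn, site by site, from unknown joint distributions. The package
asks three questions: (1) how much of site Q's data cloud lies inside
site H's — the *support* question; (2) can a classifier tell the sites
apart — the *density* question; (3) does a model trained at H degrade
when deployed at Q — the *consequence* question. The design premise is
that (1) upper-bounds generalization (a model cannot be trusted
outside its training hull), (2) catches divergence that (1) misses,
and the direction of (1) predicts the direction of the drop in (3).

## Data preparation

Cohorts are prepared per site: each charted parameter is summarized as
the per-patient median over the first day of ICU stay (half-open
window `[0, 24)` hours, so a measurement at exactly 24 h is excluded —
"first day" has no boundary semantics of its own, and half-open avoids
double counting between consecutive windows). Features missing in
more than `max_missing_frac` of a site's patients (default 0.30,
strict inequality, so an exactly-30% feature is retained) are dropped;
the cohorts are then restricted to the feature set present at every
site; remaining gaps are filled with the site's own median for the
feature. Imputation is deliberately univariate and strictly per site:
pooling medians across sites would leak exactly the between-site
differences the analysis is meant to detect. The order
sparse-filter-then-intersect is configurable
(`sparse_filter_first`); the default filters per site first, so a
feature badly charted at one site is removed globally by the
intersection rather than imputed into noise. Medians use the
mean-of-middle-two convention for even counts. Only numeric features
are accepted; categorical columns are rejected at load.

## Coverage estimator

For an ordered site pair (query, hull) and feature pair (i, j):

1. both cohorts' rows are resampled with replacement at original size
   (`resample="both"`, the default; `"hull"` restricts resampling to
   the hull side for sensitivity analysis, `"none"` disables it);
2. both samples are z-scored by the hull sample's mean and SD, so all
   geometric tolerances are scale-free;
3. DBSCAN removes noise points from the hull-forming sample only —
   removing query outliers would silently inflate coverage;
4. the convex hull (Quickhull) of the denoised sample is built, and
   the fraction of query points satisfying every hull half-plane
   inequality up to an absolute tolerance of 1e-9 (boundary counts as
   inside) is recorded.

The pair coverage is the mean over `n_boot` replicates (default 100;
the replicate SD is also kept). Per-feature coverage is the median
over the p−1 pairs containing the feature; the site-pair score is the
arithmetic mean of per-feature values; the low-coverage threshold is
`Q1 − 1.5·IQR` of the per-feature distribution with quartiles by
linear interpolation between order statistics (the most common
convention; recorded in run metadata), and flagging is strict (<).
Flagging requires at least 4 features for quartiles to be meaningful;
below that the threshold is undefined and nothing is flagged.

DBSCAN parameters default to `min_samples = 5` and, per feature pair
and replicate, `eps` equal to the 90th percentile of distances to the
5th nearest neighbor on the standardized projection. This makes the
denoising scale-free across heterogeneously scaled clinical features;
both knobs are configurable. A consequence worth knowing: denoising
trims the hull, so even two samples from the same distribution have
coverage slightly below 1 (≈0.93–0.97 at n in the low thousands), and
self-coverage is exactly 1 only with denoising and resampling off.
Interpretation of "high" coverage should therefore always be relative
to the same-distribution baseline at comparable n, which the synthetic
generator can produce.

Degenerate projections (fewer than 3 points or collinear after
denoising, e.g. a protocol-constant setting) are skipped, logged in a
QC file, and excluded from the per-feature medians; a constant feature
must not crash a run. The site-pair mean is taken over surviving
features.

Every (site pair, feature pair) cell draws its seed from the master
seed keyed by *site and feature names* (not positions), so the full
matrix is bit-for-bit reproducible and permuting the input order of
cohorts permutes the matrix consistently.

Direction convention: `matrix[query, hull]` is the fraction of the
query site's points inside the hull site's hull. All outputs label
both roles explicitly.

## Origin discrimination

The stacked pair dataset (label 0/1 = site) is split 80/20 with
stratification; each family (logistic regression, random forest,
RBF-SVM, AdaBoost) is grid-searched by ROC AUC with stratified 5-fold
cross-validation on the train split and refit; ROC AUC, precision,
recall and F1 are reported on the test split. Class weights are
balanced for logistic regression, random forest and SVM (AdaBoost has
no such option and is left unweighted). Features are standardized with
train-split statistics (inside the CV pipeline) for the margin-based
families only; tree ensembles consume raw values. Default grids are
deliberately small — LR C ∈ {0.01, 0.1, 1, 10}; RF trees {100, 300} ×
depth {∞, 10}; SVM C ∈ {0.1, 1, 10}; AdaBoost {50, 200} estimators —
and fully overridable. The best-test-AUC family is surfaced as the
pair's headline. The exclusion rerun removes the union of flagged
features over both directions of the pair (flagging is directional,
the classifier is not) and requires at least 2 surviving features.

## ARDS labeling and cross-prediction

Only the oxygenation component of the Berlin definition is
implemented. The Horowitz index is PaO2/FiO2 with FiO2 values above 1
read as percentages (both conventions occur in ICU charting). Onset is
the earliest below-300 run that spans at least 24 h under
last-observation-carried-forward semantics: a run starts at a
measurement < 300, is broken by the first measurement ≥ 300, and — if
the record ends while still below — qualifies only if its *observed*
span reaches 24 h. The index series pairs each PaO2 measurement with
the most recent FiO2 (LOCF); PaO2 values before any FiO2 record are
dropped. A patient is included only with PaO2, FiO2 and PEEP all
charted in the first 24 h; cases are patients carrying a qualifying
code (ICD-10 J80, or the ICD-9 surrogate set 5185/51851/51852/51853/
51882 where no specific code exists) *and* day-1 onset; coded patients
with later or undetected onset are controls, counted separately from
uncoded controls so either control reading can be audited.

Cross-prediction trains one random forest per site (balanced weights,
same grid as above, stratified 80/20 split); the diagonal is internal
held-out AUC, off-diagonal entries evaluate the model on the entire
external cohort — the external site contributes no training data, so
there is nothing to hold out.

## Synthetic cohorts

Sites are Gaussian mixtures with per-feature support scaling about the
grand mean, optional hard truncation at a fixed number of component
SDs, MCAR missingness, and a logistic endpoint model with an optional
diagonal quadratic (set-point) term. Canonical scenarios:

- **identical** — two iid standard-normal sites (null case);
- **single-feature-shift** — one feature's mean shifted by a given
  number of pooled SDs at one site;
- **cluster-gap** — one site bimodal with a gap, the other unimodal in
  the gap: its hull coverage matches the identical-site baseline while
  an origin classifier separates the sites, the canonical
  necessary-but-not-sufficient counterexample (a *linear* classifier
  cannot separate this pair; the tree ensemble can, which is why the
  multi-family battery matters);
- **nested-support** — three narrow sites plus one site with support
  scaled by (1 + magnitude), all truncated at 2.5 component SDs so
  "support" is literal.

The nested-support endpoint uses set-point risk on the first feature,
`logit = 3·(x₀ − 1.5)² − 12`. Rationale: with a monotone (linear
logistic) signal, a tree ensemble trained on the narrow site
extrapolates by capping and its *external* AUC on the wider site does
not drop — wider spread separates a monotone signal better, not worse.
Deviation-from-set-point risk is both clinically natural (blood
pressure, bicarbonate, glycemia) and the minimal construction in which
the narrow site observes only the falling risk branch while the wide
site contains the rising branch (activating around x₀ > 3.5, outside
the narrow sites' truncated support), so the narrow-site model
systematically misranks the wide site's far region. The truncation is
what makes the failure deterministic: without it, a lucky tail point
occasionally teaches the narrow model the rising branch. Endpoint
prevalence in this scenario is ~0.30 (narrow) / ~0.49 (wide), chosen
for AUC stability at desk-scale n; the generator's *default* linear
endpoint model instead targets ~7% prevalence, the realistic order for
day-1 respiratory-failure endpoints.

Trajectory generation encodes P/F through PaO2 at fixed FiO2 with
noise clipped away from the 300 mmHg threshold, so template class
membership (day-1 onset, late onset at 26–32 h, never-below) is
unambiguous by construction; PEEP is charted constant to satisfy the
inclusion rule.

All generators are pure functions of (spec, seed).

## What the synthetic studies do and do not show

The generator emulates support shift, density shift, cluster structure,
MCAR missingness and endpoint prevalence. It does not emulate
measurement-unit mismatches, non-random missingness, temporal drift,
label noise from evolving coding practices, or realistic inter-feature
physiology. Passing the suite therefore demonstrates that the
estimators and the pipeline behave as specified under controlled
shift, not that the screen has any particular sensitivity on real
hospital data; on real data the same-distribution coverage baseline
and the AUC < 0.7 "poor discrimination" rule of thumb should be
calibrated per cohort size.

## Numerical and design choices

- Hull membership via half-plane inequalities from Qhull with absolute
  tolerance 1e-9 on standardized coordinates; closed polygon (boundary
  is inside). Verified exactly against an O(n²) brute-force hull and a
  sign-test membership oracle.
- Bootstrap SD uses ddof = 0 (it is a descriptive spread over
  replicates; with one replicate the SD is 0 by definition).
- The site coverage matrix diagonal is 1 by convention and excluded
  from summaries.
- Grid-search and split seeds derive from the run seed; reports embed
  (seed, config hash), the hash excluding the output directory so that
  runs into different directories remain comparable.
- No report file contains wall-clock content; a rerun with an
  identical configuration is byte-identical (logging goes to the
  logging subsystem, not into reports).
- Problem sizes in the test and acceptance studies (null calibration
  n = 400/site over 20 seeds; shift detection and exclusion n =
  800/site; flag recovery n = 2000/site with 5 bootstrap replicates;
  area-ratio recovery n = 1000 with 100 replicates; nested-support
  n = 1500/site) are the package's desk-scale study conditions: large
  enough for the assertions' tolerances, small enough to keep a full
  run in minutes on one core.

## Known limitations

- 2D projections outer-approximate the full-dimensional hull: full
  coverage of every projection does not imply full-dimensional
  coverage unless the data fill the projected box.
- Univariate site-median imputation distorts joint structure; heavily
  imputed features should be read with care.
- DBSCAN defaults are heuristics; pathological densities (very small
  samples, heavy ties) may need manual `eps`/`min_samples`.
- Coverage depends on cohort size (hulls of small samples are small);
  compare directional coverages only at comparable n or against a
  same-distribution baseline.
- The onset rule sees only charted measurements; sparse charting
  coarsens onset times to measurement times.
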