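# Methods

## Problem setting

A clonal drug-resistance screen profiled by high-content microscopy yields a
table of wells × morphological features plus a platemap (clone identity,
resistance status, plate/batch, incubation time, treatment). Observed feature
variance mixes the biological signal of interest (resistance status) with
technical structure: batch-to-batch shifts, incubation-time effects, well
confluence (cell count), and idiosyncrasies of individual clones. The goal is
a compact directional feature set — an *up* list elevated in resistant lines
and a *down* list depressed in them — that generalizes to clones and plates
never used in its construction, plus a single-sample score to apply it.

## Profile processing

- **Aggregation.** Well profiles are the per-feature median over the well's
  segmented cells; the cell count is carried as metadata (it is a covariate
  in the confluence model). Medians are insensitive to single-cell outliers,
  which is why the corruption model below operates at well granularity.
- **Normalization.** Per plate, each feature is z-scored:
  (x − μ<sub>plate</sub>)/σ<sub>plate</sub> with the population SD (ddof = 0;
  configurable). Features with zero plate SD are flagged as missing so the
  missing-value rule removes them. Normalization uses all wells of a plate —
  every well in this design is vehicle-treated (0.1% DMSO), so there is no
  separate negative-control stratum to normalize against.
- **Feature selection** runs once across all plates of an analytical dataset,
  with rules applied in a fixed order so that each dropped feature has exactly
  one attributed cause: blocklist patterns → any missing value → low variance
  (most-frequent-value fraction > 0.95 or variance < 1e−12) → outliers
  (dataset-wide re-standardized |z| > 15) → pairwise |Pearson r| > 0.9. For a
  correlated pair, the member with the larger mean absolute correlation to all
  other features is dropped (ties by name), keeping the less redundant one.
  Selection is idempotent and leaves no surviving pair above the threshold.
- **No batch correction** is applied; batch structure is handled by exclusion
  at the discovery stage instead.

A note on the 15-SD outlier rule: after z-scoring, the largest attainable
|z| among n observations is (n−1)/√n ≈ √n, so the rule can only ever fire
when the dataset (and, with per-plate scoring, the plate) holds more than
~226 wells. On 96-well plates the rule is structurally inert; the planted
outlier tests therefore use a 384-well single-plate design with 300 wells.

## Signature discovery

Per feature, two ordinary-least-squares models are fit (one closed-form
solve across all features simultaneously):

1. `Y ~ status + batch + incubation_time + clone_id` (all categorical,
   treatment-coded). Clones nest within status, so the dummy design is
   rank-deficient; aliased columns are dropped greedily to restore full rank.
   R², coefficients and residual variance are recorded, but per-covariate
   *inference* never relies on the possibly-aliased coefficients: each
   categorical covariate gets a Tukey's HSD family computed on the raw
   feature values grouped by its levels — well-defined regardless of
   nesting, and the natural reading of a per-covariate post-hoc test.
2. `Y ~ status + cell_count`, supplying the confluence slope
   β<sub>count</sub> and its two-sided t p-value (cell count is continuous
   and has no Tukey family). A constant feature gets slope 0 and p = 1; a
   constant cell count is an error (slope unidentifiable).

**Tukey–Kramer HSD.** For a family with k levels and N wells, each pair
(i, j) is tested with q = |m̄<sub>j</sub> − m̄<sub>i</sub>| /
√(MSE · ½(1/n<sub>i</sub> + 1/n<sub>j</sub>)) against the studentized range
distribution with (k, N − k) degrees of freedom — the Kramer standard error
accommodates unequal group sizes. For k = 2 the exact identity
q = |t|·√2 against the pooled t distribution is used. For k > 2, scipy's
studentized-range survival function (a slow numerical integral) is evaluated
once per (k, df) on a dense q grid and cubic-splined on the log scale;
observed interpolation error is ≲ 1e−8 on the probability scale, and
q > 30 saturates to p = 0. The implementation is cross-checked against
statsmodels' `pairwise_tukeyhsd` in the test suite.

**Filtering.** With n features tested, the threshold is α\* = α/n (default
α = 0.05; for the 782-feature scale of a real screen this is
0.05/782 = 6.4×10⁻⁵). A feature enters the signature iff:

- its status comparison has Tukey p < α\*; and none of
- any batch pair significant at α\*;
- any incubation-time pair significant at α\*;
- model-2 confluence p < α\*;
- **two or more** wild-type–wild-type clone pairs significant at α\*
  (a feature that separates sensitive clones from each other is a clone
  idiosyncrasy, not a resistance marker; a single significant pair is
  tolerated).

Survivors split by the sign of (resistant mean − sensitive mean) on the
normalized values: positive → up, negative → down. An empty result is a
warning (and scoring refuses an empty signature). Every threshold, including
the base α and the exclusion set, is exposed in the API.

## Scoring

The score is a single-sample rank statistic. Over the N surviving
post-selection features of a profile (the full pool, not just signature
members — the rank universe follows the reference single-sample convention),
features are ranked ascending with average ties. For a direction set of size
n<sub>s</sub>, the mean rank is min–max normalized by its theoretical
extremes, (n<sub>s</sub>+1)/2 and (2N−n<sub>s</sub>+1)/2, and centered by
−0.5; the down component uses reversed ranks (N+1−rank). The total
(up + down) lies in [−1, 1], hits the bounds exactly at full
concordance/discordance, is antisymmetric under direction swap, and is
invariant to any strictly monotone transform of the profile — hence
comparable across plates and normalization schemes. N is recorded with the
output.

The permutation null shuffles the profile's rank vector uniformly
(equivalently, reassigns feature identities) with the signature fixed,
default 1,000 permutations, and reports the empirical 2.5/97.5 percentiles.
Nulls are computed per well; a dataset-pooled interval over all wells'
permuted scores is also emitted, covering both readings of a "shuffled-data
95% interval".

## Evaluation

Prediction: resistant iff score > 0 (ties, score = 0, go to sensitive by the
strict inequality). Per split: accuracy = correct/total; average precision by
step-interpolated summation over the score-ranked precision–recall curve
(scikit-learn, resistant = positive); AUROC by the Mann–Whitney rank
formulation (equal to the fraction of resistant–sensitive pairs correctly
ordered, with half-credit for ties), cross-checked against trapezoidal ROC
integration to 1e−9; ROC points from a grouped-ties threshold sweep, with
the operating point at the minimum observed score reported. Chance baselines
re-draw the signature's feature identities uniformly from the surviving pool
(sizes preserved; default 1,000 repeats) and report mean ± SD of each metric;
label permutation is available as an alternative mode. Splits are routed by
clone, plate/batch and within-clone replicate ordinal, with well-level
disjointness enforced; the default configuration mirrors the four-way
design: training and validation share clones and plates but not wells, test
holds never-seen clones on the training plates, holdout is a separate plate.

## Synthetic data

The generator emulates the screen's design, not its images: 5 wild-type +
5 resistant clones × 20 replicate wells across 3 batches (one 96-well plate
per batch, 50–150 cells per well), 100 features. Clones are laid out in a
repeating serpentine fill so each occupies dispersed positions; incubation
times (4 h / 13 h) alternate across each clone's replicates. Each feature has
exactly one role:

| role | count | planted structure |
|---|---|---|
| signature up / down | 10 + 10 | ± d (d = 1.5) cell-level shift in resistant clones |
| batch-confounded | 5 | centered per-batch offsets, spacing g = 1.0 |
| time-confounded | 5 | centered per-time offsets, spacing g |
| count-confounded | 5 | g × standardized well cell count |
| clone-idiosyncratic | 5 | per-clone N(0, g) shifts — wild-type clones too, exercising the WT–WT rule |
| correlated block | 5 | shared latent factor, ρ = 0.8, at both cell and well level |
| inert | 55 | noise only |

Cells are the per-well mean vector plus a per-(well, feature) technical noise
term (SD 0.5) plus unit Gaussian cell noise. The well-level term reflects the
empirical fact that replicate wells of the same condition disagree by more
than cell-sampling error (position, staining, handling); without it, all
features sharing the status factor would be near-collinear at the well level
(r ≈ 0.97) and the correlation filter would delete the planted signature —
an artifact of a sampling-only noise model, not of real screens. Outliers
and missing values are injected at (well × feature) granularity — every cell
of a chosen well — because median aggregation absorbs any single-cell
corruption; rates default to 0. The ground-truth sidecar (feature → role,
direction, corruption counts) lets tests measure recovery directly.

**What passing tests do and do not show.** The generator is Gaussian,
additive and exactly linear in its covariates; real morphology features are
skewed, heteroscedastic, nonlinearly confounded and correlated in large
blocks. Recovery of the planted signature here validates the machinery
(models, exclusions, thresholds, scoring, splits), not the biological claim;
the published real-data metrics require the study's deposited profiles and
are out of scope.

## Numerical and design choices

- One master seed per run; substream seeds for simulation, scoring and
  baselines are derived from it (`RunConfig.derived_seeds`) and recorded in
  the manifest. Identical config + seed ⇒ byte-identical tables.
- Tukey tests use raw grouped values, not residualized ones; with two
  incubation-time levels, Tukey and the model coefficient tests coincide up
  to pooling, and the grouped form needs no modelling assumption.
- Study sizes in the test suite (100 features, 200–300 wells, 20 seeds for
  the recovery and null studies, 1,000 permutations/shuffles) were chosen as
  the smallest sizes at which every planted effect is decisively detectable
  and the null studies have interpretable expectations.
- Degenerate inputs: empty signatures are refused by the scorer; single-well
  plates are a normalization error; zero within-group variance gives p = 0
  for a real difference and p = 1 for none; a single baseline repeat reports
  SD 0.

## Known limitations

- The 15-SD outlier rule is inert below ~226 wells per plate (see above).
- Null-calibration properties of the discovery stage are Monte Carlo
  statements: with α\* = α/n, the expected number of false admissions is
  α ≈ 0.05 per dataset, so "the null signature is empty" holds per run only
  with probability ≈ e^(−α), not surely.
- The permutation null assumes exchangeable feature identities; strongly
  correlated feature blocks make it slightly liberal.
- Average precision and ROC inherit scikit-learn's tie conventions; scores
  here are continuous, so ties matter only in adversarial constructions.
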