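# Methods

## The IFN score

The score treats per-individual interferon (IFN) pathway activity as a
latent quantity and estimates it from whole-blood expression of
interferon-stimulated genes (ISGs). For signature gene g and sample s,

    z(g, s) = (x(g, s) − μ_g) / σ_g,        score(s) = Σ_g z(g, s),

where μ_g and σ_g are the mean and sample SD (n−1) of covariate-adjusted
expression over the euploid-control samples only. Three exact consequences
define the contract: the control cohort's mean score is 0, each gene's
control z-SD is 1, and a sample sitting c control-SDs above the mean on one
gene moves its score by exactly c.

z-scores are computed on log2(RPKM + 0.5) by default. The linear-RPKM
reading is supported (`IFNScorer(log_scale=False)`) but not the default:
linear-scale SDs are dominated by the most abundant samples, and on the log
scale a fold change is the same perturbation for low- and high-expressed
genes. External samples — e.g. the longitudinal subject — are always scored
against a frozen `ReferenceStats` from the cross-sectional cohort, never
against their own draws, so their scores live on the cohort's scale.

## Signature selection

Differential expression T21 vs control is a per-gene Gaussian linear model
on log2(RPKM + 0.5) with karyotype + age + sex terms, a Wald t-test on the
karyotype coefficient (which is the log2 fold change), and BH adjustment
across genes. This is a deliberate stand-in for count-based negative
binomial modeling: the package's subject is signature selection and
scoring, its inputs are RPKM-scale abundances, and at n = 400 with
moderate dispersion the Gaussian approximation on log expression is
adequate (the null-calibration acceptance check verifies its q-values
behave).

The signature keeps genes that are (i) annotated ISGs, (ii) elevated at
linear fold change ≥ 1.5 — only positive fold changes qualify, the score
summarizes *induction* — (iii) significant at q < 0.1, and (iv) not on
chr21. The chr21 exclusion removes ISGs whose elevation is explained by the
three-copy gene dosage (~1.5×) rather than downstream IFN signaling.
Relaxing `fc_min` produces the larger signature presets; scores from nested
signatures rank-correlate > 0.95 on cohorts with one latent axis, so the
small panel is sufficient in practice.

## Preprocessing

* **Extreme outliers**: per analyte within each karyotype stratum, values
  outside [Q1 − 3·IQR, Q3 + 3·IQR] are excluded. Quantiles use linear
  interpolation between order statistics (the "type 7" convention — the
  dominant default; configurable in principle but a convention had to be
  fixed). The rule is single-pass: fences are computed once from all
  non-missing values, not recomputed after exclusion. Strata with fewer
  than 4 values are left alone with a warning.
* **Immunoassay fit-range handling**: below-range values take the minimum
  in-range calculated concentration of that analyte on the same plate,
  above-range the maximum; duplicate wells are then averaged; analytes with
  more than 10 % out-of-range values are flagged for the analyst. In-range
  values pass through bit-identical.
* **Metabolomics**: zeros (detection-limit censoring) are replaced by a
  seeded Uniform(0, 0.5 × min nonzero) draw per metabolite; each sample is
  then scaled so its median equals the global median intensity. The
  normalization is idempotent on an already-normalized zero-free matrix.
* **Covariate adjustment**: per feature, one linear model with protected
  terms (karyotype) plus nuisance terms (age, sex, source); only the fitted
  nuisance contributions, computed from mean-centered nuisance columns so
  the overall level is retained, are subtracted. Protecting the karyotype
  contrast in the design prevents the nuisance fit from absorbing group
  signal when covariates are imbalanced. Adjustment is idempotent to
  floating precision. Sample source enters as a fixed covariate rather
  than a random effect; with two or three sources and large n the fixed-
  and mixed-model adjustments target the same estimand, and the fixed form
  needs no specialized solver.

Missing values propagate; nothing outside the immunoassay rule is imputed.

## Association screens

* **Spearman screens** use average ranks, pairwise-complete observations
  (≥ 4 pairs), the t-approximation for p, and BH within the screen. Each
  screen is its own BH family, matching per-analysis q-values.
* **Differential abundance** is a per-analyte linear model of
  log2(abundance) on karyotype + age + sex + source; the karyotype
  coefficient is the reported log2 fold change.
* **Beta regression** for cell-cluster relative frequencies: y ~
  Beta(μφ, (1−μ)φ) with logit(μ) = Xβ and constant precision φ, fit by
  Fisher scoring with analytic expected information, step-halving (the
  accepted log-likelihood never decreases), OLS-on-logit starting values,
  and Wald standard errors from the inverse expected information at the
  optimum. Exponentiated coefficients read as fold changes in mean
  frequency per unit predictor. Exact 0/1 frequencies are rejected unless
  the Smithson–Verkuilen shrink y′ = (y(n−1)+0.5)/n is enabled — cohort
  frequencies are interior, but toy data need the option. The fit matches
  `statsmodels` BetaModel to ~1e-5 on shared instances (cross-checked in
  the test suite) while exposing the iteration/convergence contract the
  screens rely on.
* **Preranked GSEA**: weighted Kolmogorov–Smirnov running sum with weight
  exponent 1; ES is the extreme deviation (an exact ± tie, which symmetric
  toy sets can produce, resolves positive — the tie tolerance is 1e-12);
  the null permutes gene labels, implemented as random same-size sets and
  cached per set size; p is the same-sign permutation tail with add-one
  smoothing; NES = ES / mean(|same-sign null ES|). Ranking ties break by
  stable gene-ID order so results are deterministic given the seed.
  Default 10,000 permutations; the ranking metric is the caller's choice
  (log2FC for RNA, log2FC × −log10 p for proteomics, Spearman rho for
  correlation screens).

## Stratification

* **Consensus clustering** (Monti scheme): each of `reps` (default 100)
  iterations subsamples `item_fraction` (default 0.8) of the samples,
  computes 1 − Pearson correlation distance between samples, cuts an
  average-linkage tree at each k; consensus(i, j) is the co-clustering
  count over the co-sampling count. Final labels per k come from a
  hierarchical cut of 1 − consensus. The subsample fraction and linkage
  follow the conventional defaults of the resampled-clustering literature.
  k is chosen from the consensus-CDF area curve: the first k whose relative
  area gain over k−1 drops below `gain_threshold` (default 0.05) marks the
  stability plateau and the k before it is selected — an automatic
  replacement for choosing the elbow by eye, which a pipeline cannot do.
  Note the Pearson distance between *samples* is blind to a shift shared by
  every marker; subtype structure must differ in marker profile, not only
  in overall level.
* **Gower distance** for mixed clinical records: binary variables use
  symmetric simple matching (co-absence counts as agreement, the default
  behavior of the standard mixed-data implementations), numeric variables
  |xi − xj| / range; missing values and zero-range variables are excluded
  pairwise. Gower values lie in [0, 1] and are symmetric; the triangle
  inequality is not guaranteed and not asserted.
* **PAM**: when the number of candidate medoid sets C(n, k) is at most
  2,000 the optimum is found by exhaustive enumeration — tiny instances are
  exact by construction. Larger instances use greedy BUILD followed by
  steepest-descent SWAP until no single medoid exchange improves the cost.
  Single-swap descent is a local search: instances exist (already at n = 6)
  whose optimum needs two simultaneous exchanges, which is why the exact
  small-instance path exists. All tie-breaks go to the lowest index, so
  results are deterministic.
* **Silhouette k selection** runs PAM per k and picks the highest average
  width s(i) = (b − a)/max(a, b); singleton-cluster members take s(i) = 0
  by convention.
* **Condition enrichment**: conditions are pre-filtered to ≥ 10 cases and
  ≥ 10 controls; per cluster, O/E = observed cases / (cluster size ×
  overall case rate), so the cluster-size-weighted mean O/E is 1 by
  construction. Unequal occurrence is tested with Fisher's exact test for
  two clusters and a seeded Monte-Carlo exact test (probability ordering of
  k×2 tables with fixed margins) otherwise; BH across conditions.
* **Score comparisons** are two-sided Mann-Whitney U tests — exact
  enumeration for small tie-free groups, normal approximation with tie
  correction otherwise — BH-adjusted when several comparisons are made.

## Longitudinal case analysis

Per-feature on/off contrasts are log2 fold changes of geometric means
(means of log2 values — consistent with the log-scale modeling elsewhere;
an arithmetic-mean option exists), with Mann-Whitney p per feature across
draws and BH across features. A single draw in one status still yields a
fold change but no p. Cohort reference bands are per-karyotype quartiles of
the cohort scores; each draw is classified relative to the control IQR,
the T21 IQR, or the gap between them. The on-vs-off score contrast is a
Mann-Whitney test plus an explicit flag for whether the on-drug median
falls below the off-drug median. Fold changes are antisymmetric under
swapping the status labels, and classifications ignore draw order.

## The synthetic cohort generator

The generator emulates the statistical structure of a T21 vs euploid
multi-omics cohort, with one latent IFN activity per individual driving
every layer:

* latent activity ~ Normal(μ_karyotype, latent_sd) with μ_T21 − μ_control
  = `latent_shift` — elevated but overlapping distributions;
* expression on the log2 scale: per-gene baseline ~ Uniform(2, 8),
  + log2(`dosage_fold`) for chr21 genes in T21, + `isg_effect` × activity
  for induced ISGs, + Gaussian noise, then exponentiated to RPKM-like
  values, so configured effects are multiplicative fold changes;
* three analyte panels with per-analyte log2 slopes on activity; the
  immunoassay panel adds plates, duplicate wells and censored fit-range
  tails, the metabolite panel a censored zero fraction (both exercise the
  preprocessing rules);
* cell compositions are logistic-normal — softmax of Gaussian logits with
  per-cluster slopes — rather than Dirichlet, precisely so the logit-scale
  slopes match what beta regression estimates; compositions are positive
  and sum to 1 within 1e-12;
* condition flags are Bernoulli with logit = baseline + enrichment ×
  activity;
* the longitudinal subject sits at `latent_shift` + 1.5·`latent_sd` when
  off drug; on-drug draws shrink the ISG induction toward the control mean
  by the fraction `drug_effect`, leaving the chr21 dosage untouched. The
  default schedule is 7 on-drug and 4 off-drug draws.

All randomness flows from one seed through named per-layer substreams:
identical configs are byte-identical, and changing one layer's parameters
does not perturb the draws of another. The latent truth is returned for
recovery tests only; no analysis stage may read it.

Default conditions: 300 T21 / 100 control samples, 2,000 genes of which
120 on chr21, 18 planted signature ISGs (plus 30 ISG-annotated null genes
and 3 induced chr21 ISGs that selection must exclude), `dosage_fold` 1.5,
`isg_effect` 0.5 with `latent_shift` 2 (planted ISGs average a 2× fold
change), log2 noise SD 0.5. Effect-size magnitudes for the analyte, cell
and condition layers are free parameters — chosen once as moderate,
realistic loadings (|log2 slope| 0.2–0.4, logit slopes ±0.2–0.3, log-odds
slopes 0.5–0.6) — and are documented in `CohortConfig`, not estimates of
any real cohort.

What the generator does **not** emulate: count-level sequencing noise and
library-size artifacts, batch effects in expression, assay-specific
normalization quirks, correlated condition comorbidity beyond the shared
latent axis, missingness mechanisms other than censoring, and any real
biobank's effect sizes. Passing tests therefore demonstrate that the
pipeline recovers planted structure under its own model assumptions at
realistic scale — not that any particular biological cohort will show the
same effect sizes.

## Problem sizes and numerical choices

The test and acceptance workloads use the default cohort scale (400
samples × 2,000 genes), 10–20 seeds per stochastic property, 100 consensus
resamples, 200 beta-regression coverage replicates at n = 500, φ = 30, and
999–10,000 GSEA permutations — sizes at which every stochastic check is
stable across seeds while the whole suite runs in well under a minute per
module. Convergence tolerances: beta regression stops at |Δloglik| <
1e-10 (cap 100 iterations); PAM swaps require improvement > 1e-12;
BH/q-values are exact transforms, not approximations. Degenerate inputs
are contracts, not crashes: zero-variance genes/markers are dropped with
warnings, empty signature selections warn and return empty, sub-minimum
strata skip exclusion, constant predictors raise.

## Known limitations

* The Gaussian log2-RPKM differential test is not a count model; at small
  n or with heavy overdispersion its p-values will be less calibrated than
  negative-binomial inference.
* Fixed-effect source adjustment slightly understates uncertainty relative
  to a mixed model when sources are many and small.
* PAM above the exact-enumeration threshold is a local search and carries
  PAM's usual no-global-optimality caveat.
* The delta-area rule makes the k choice automatic but inherits the
  arbitrariness of its threshold; inspect the full area curve for
  borderline cohorts.
* GSEA p-values are permutation-granular (floor 1/(n_perm + 1)); raise
  `n_perm` before interpreting very small q-values.
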