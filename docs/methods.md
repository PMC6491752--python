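# Methods

## The index

The Stroke Dysbiosis Index treats dysbiosis as a directed contrast between
two genus sets learned from a case-control cohort. For a sample with percent
relative abundances a<sub>g</sub>, a signature (S = stroke-enriched,
C = control-enriched) gives

    SDI = ( mean_{g∈S} a_g − mean_{g∈C} a_g ) × 100.

Three conventions matter and are fixed package-wide:

- **Units.** Abundances enter the formula in percent (0–100), not fractions.
  With fractional units the index's attainable range shrinks by 100×, which
  is incompatible with the score scale the index is known for (patient
  medians in the tens); percent units are the only reading under which the
  published score scale is attainable.
- **Missing genera.** A signature genus absent from a sample's table
  contributes 0, and the denominators are always |S| and |C| of the
  signature in use. This keeps scores comparable across cohorts — a
  validation cohort can always be scored with a training signature even
  when some genera were filtered out of it. The corollary is that swapping
  S and C exactly negates the index (the denominators travel with their
  sets); only if the printed constants were pinned to the formula slots
  would the swap be non-antisymmetric.
- **Stratification.** Patients split at their median SDI; a score equal to
  the threshold goes to the high (SDI-H) stratum. All scores identical is a
  degenerate stratification and an error.

## Preprocessing

Order is fixed: low-abundance filter → rarefaction → relative abundance.

- **Filter** (default `min_count_fraction = 0.001`): a genus is retained iff
  its total count over all samples ≥ fraction × grand total of the table
  (threshold inclusive). This is the whole-table semantics of the classic
  QIIME-1 OTU filter, not a per-sample rule.
- **Rarefaction** (default depth 4,800 for index construction; 8,000 is the
  conventional choice for the diversity analyses and available via the same
  argument): each sample is subsampled without replacement (multivariate
  hypergeometric); samples shallower than the depth are dropped and logged.
  Each sample draws from an independent RNG stream keyed on
  `(seed, crc32(sample_id))`, so results never depend on sample order.
- **Relative abundance**: percent per sample; zero-total samples are an
  error (they cannot occur after rarefaction).

Genus collapse sums OTU counts by genus; OTUs unclassified at genus rank
pool per family under `Un <Family>`, and lineages lacking both ranks go to
`Unassigned`. Counts are conserved per sample.

## Signature selection

Per genus, a two-sided Mann-Whitney U test on percent abundances: exact
enumeration when the pooled sample has ≤ 12 observations without ties,
otherwise the tie-corrected normal approximation (scipy); a genus constant
across all samples is degenerate with p = 1. P-values are
Benjamini-Hochberg adjusted (statsmodels) and the cut is strict
(`fdr_p < 0.1`). Direction is the group with the larger **mean** relative
abundance (median available via `direction_stat`); means are used because
they are the very quantities the index averages, keeping the signature
self-consistent. A significant genus with exactly tied group summaries has
no defined direction and is excluded with a warning. The full per-genus
table (statistic, p, FDR-p, direction, group means, selected flag) is
returned as an audit trail. With two groups the Kruskal-Wallis test of the
classic QIIME command is equivalent to this rank-sum test up to tie
handling.

A null cohort typically yields an empty signature; `fit()` then returns a
results object whose score-dependent accessors raise, rather than failing
inside the pipeline.

## Ecology statistics

- **Unweighted UniFrac** (scikit-bio) on presence/absence (> 0) against a
  genus-level tree. The published analysis used an OTU-level tree;
  genus-level is the documented approximation here, since only genus tables
  are in scope.
- **PCoA**: classical scaling of the double-centred squared-distance matrix
  (scikit-bio backend); all eigenvalues are reported, axes with
  non-positive eigenvalues carry no coordinates.
- **PERMANOVA** is implemented in-package because the test needs a seeded,
  reproducible permutation stream, the +1-smoothed p-value
  `(hits + 1)/(n_permutations + 1)` and an R² = SS_between/SS_total that the
  scikit-bio routine does not expose; scikit-bio's pseudo-F is the
  independent cross-check in the tests. Default 999 permutations.
- **Distance-to-reference**: all patient-to-control pairwise distances per
  stratum (per-patient means available via config in downstream code),
  compared between strata with the rank-sum test.

## Clinical battery

- **ROC/AUC** by threshold sweep + trapezoid; identical to the tie-averaged
  U/(n₁n₀) identity, which the tests assert on random instances.
- **Spearman** via midranks; for n ≤ 9 without ties the p-value is an exact
  enumeration over all rank permutations, otherwise the t-approximation.
- **Group tables**: continuous variables report mean (SD) with a t-test
  when Shapiro-Wilk does not reject normality in either group (α = 0.05),
  else median (IQR) with a rank-sum test; binary variables report n (%)
  with chi-square, switching to Fisher's exact test when any expected cell
  is < 5.
- **Logistic regression** (statsmodels Logit, Newton/IRLS, tol 1e-8, max
  100 iterations) with Wald 95% CIs, exp(β ± 1.96·SE). Complete separation
  is detected up front and raised with the offending covariate;
  non-convergence is reported on the result, never silent. Severity is
  dichotomised at NIHSS ≥ 8 and outcome at mRS > 2; these are study
  definitions, exposed as read-only constants, and NIHSS/mRS never enter as
  predictors since they define the outcomes. The univariate screen retains
  covariates at *P* < 0.20 for one multivariable fit. No multiplicity
  correction is applied in the clinical battery (FDR lives only in
  signature selection).
- **Infarct volume**: per serial section, corrected area = direct lesion −
  (ipsilateral − contralateral hemisphere area), floored at 0; volume =
  Σ area × section interval.

## Synthetic cohorts

The generator emulates a genus-collapsed 16S case-control study:

- **Counts**: per-sample Dirichlet-multinomial. Base genus concentrations
  are log-normal (σ = 1.6) so a fat tail of rare genera exercises the 0.1%
  filter; planted signature genera are floored at concentration 0.5 so they
  survive filtering. Case samples multiply stroke-enriched concentrations
  by 2^effect and divide control-enriched ones likewise (default effect =
  1.5 log2 units — a strong, clearly recoverable signal; parameter-recovery
  tests use 1.0). Depths are uniform integers in 6,000–12,000, keeping
  every sample above the 4,800 rarefaction depth by default.
- **Population vs cohort seeds**: base concentrations are drawn from a
  `population_seed` (defaulting to the cohort seed) while subjects are
  drawn from the cohort seed. A validation cohort shares the training
  population_seed, so the two cohorts are fresh samples from one
  population — without this, cohort-level composition shifts act as a batch
  effect that breaks pooled analyses.
- **Truth**: each sample's true SDI is computed from its latent Dirichlet
  proportions with the planted signature; `truth` carries it with the
  planted signature for recovery tests.
- **Clinic**: within patients, z = standardised true SDI. NIHSS at
  admission = round(clip(4 + β_sev·z + N(0, 3²), 0, 42)) with β_sev = 1
  point/SD; mRS at discharge is proportional-odds: latent = β_out·z +
  standard logistic noise cut at fixed thresholds (β_out = 0.7, cutpoints
  placed so roughly a quarter of patients exceed mRS 2). These defaults put
  the observed Spearman correlations in the weak-to-moderate 0.2–0.45 range
  typical of severity-microbiome associations, and make the
  unfavorable-outcome indicator exactly a logistic model in z, so logistic
  parameter recovery is well-defined. Controls carry no NIHSS/mRS.
  Covariates (age, sex, comorbidities, labs) are drawn from plausible
  cohort distributions, with WBC weakly coupled to severity.
- **Trees**: random rooted bifurcating trees by repeated random joins,
  exponential(0.2)+0.01 branch lengths, deterministic per (seed, names).

What the generator does *not* emulate: read-level artifacts (chimeras, OTU
picking, taxonomy errors), covariate-microbiome confounding (age/diabetes
do not shift composition), inter-cohort batch effects, or any specific real
cohort's abundance distributions. Passing tests therefore demonstrate that
the pipeline's statistics behave correctly under a realistic
overdispersed compositional model with known truth — not that any
particular biological finding replicates.

## Problem sizes and determinism

Tests and the acceptance script run the study-sized designs (104/90
training, 83/70 validation, 60 genera, depths ≤ 12,000); calibration suites
use 20 seeds for signature recovery, 50 seeds of 200-genus null cohorts for
FDR calibration, and 40 + 40 subjects per null run — sizes at which the
binomial/KS calibration tests have adequate power while the whole suite
stays fast. All randomness flows through explicit integer seeds
(numpy `default_rng`/`SeedSequence`); rarefaction and tree generation key
per-item streams with CRC32 of the item name so results are independent of
ordering.

## Known limitations

- Genus-level UniFrac against a synthetic or user-supplied tree only; no
  OTU-level phylogeny.
- No LEfSe-style effect-size ranking; selection is rank-sum + FDR only.
- No ordinal mRS shift analysis, survival analysis, or 90-day outcomes.
- The index has no learned weights — it is exactly the two-set mean
  contrast above.
- Whether a validation cohort should be scored with the training signature
  or a re-derived one is a design choice; the default is the training
  signature (`SDIResults.score`), with refitting available by constructing
  a new model.
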