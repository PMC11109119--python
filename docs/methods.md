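# Methods

This note documents the statistical models implemented in `crcith`, the
assumptions they make, the synthetic cohort generator that exercises
them, and the numerical choices behind both.

## Per-gene intra-tumor heterogeneity (ITH) scoring

For each gene, expression across all samples of all tumors is modelled
with a one-way random-intercept model,

    x_ts = mu + u_t + e_ts,    u_t ~ N(0, sigma_t^2),  e_ts ~ N(0, sigma_e^2),

with tumor `t` as the grouping factor. The intraclass correlation
ICC = sigma_t^2 / (sigma_t^2 + sigma_e^2) is the fraction of a gene's
variance lying *between* tumors, and the ITH score is 1 − ICC: genes that
vary mostly within tumors score high.

Estimation is REML. Because the model has a single variance ratio
gamma = sigma_t^2 / sigma_e^2, the REML criterion is profiled: for fixed
gamma both the GLS mean and sigma_e^2 have closed forms, leaving a 1-D
bounded minimisation on log(gamma) started at the ANOVA method-of-moments
estimate. For balanced designs the REML solution coincides with the
ANOVA closed form whenever that is non-negative; negative estimates are
truncated at zero (boundary REML). The implementation agrees with
`statsmodels` MixedLM to ~1e-4 on unbalanced toys (checked in the test
suite) and with the exact ANOVA solution to 1e-6 on balanced ones.

Genes with a 10–90th percentile expression range ≤ 1 (log2 scale) are
non-informative and excluded before model fitting. Percentiles use
linear interpolation between order statistics (the rank `1 + (n−1)p`
convention). Retained genes are categorised at ITH-score thresholds
`(t_low, t_high) = (0.5, 0.8)` by default: `< t_low` low, `≥ t_high`
high, otherwise intermediate. The thresholds are configuration, not
constants; the defaults were calibrated once against the generator's
default variance profile so that the three categories split roughly
48% / 48% / 5%, the regime reported for multiregional tumor data.

## Single-sample subtype scoring and the heterogeneity caller

Template gene sets per subtype are derived one-vs-rest with a moderated
t-test: gene-wise variances are shrunk towards an empirical-Bayes prior
whose scale and degrees of freedom are obtained by moment-matching the
observed variance distribution to a scaled F distribution (with prior df
0 the statistic reduces exactly to the ordinary two-sample t). Genes
with Benjamini–Hochberg adjusted p < 0.001 and |log2FC| > 1 enter the up
or down template by the sign of the fold change. Samples without a class
label are excluded from the "rest" group.

The single-sample enrichment score ranks all measured genes of one
sample ascending (average ties). For an up set of size n in a universe
of N genes the component is `(meanRank − (n+1)/2) / (N − n)`, which lies
in [0, 1]; the down component is computed identically on reversed ranks,
and a directed template's score is the mean of the two components (an
order-preserving rescaling of their sum, so argmax decisions and
p-values are unchanged). The score depends on ranks only and is
invariant under any strictly monotone transformation of a sample's
values.

Significance uses a sample-specific permutation null: B random gene sets
of matching sizes drawn without replacement from the same sample's
measured genes, with p = (1 + #{null ≥ observed}) / (B + 1). B defaults
to 1000 (500 in the heavier test scenarios). Note that for one *fixed*
template this null is conditional on the template's baseline rank
positions, so p-values for a fixed set on null data are conservative
rather than exactly uniform; uniformity holds over random draws of the
set, which is the property the test suite asserts.

The heterogeneity decision per sample: classes with p < 0.05 are
significant; no significant class → unclassified; more than one →
heterogeneous; the top-scoring significant class is the major subtype.

Nearest-template prediction (NTP) z-scores each gene across samples,
represents each class as a signed vector (+1 up, −1 down) over its
template genes, assigns a sample to the class at minimum cosine
distance, and obtains p by comparing with the same signed pattern
applied to random gene subsets of the sample; BH-FDR across samples,
classified at FDR < 0.05.

Microenvironment scores (e.g. cancer-associated fibroblasts, cytotoxic
lymphocytes) are marker-gene means on the log2 scale. The competitive
gene-set comparison between sample groups is an explicitly simplified
test: a two-sided rank-sum z of gene-level moderated t statistics
(in-set vs out-of-set) deflated by a variance-inflation factor
`1 + (n−1)·rho_bar`, with rho_bar the mean inter-gene correlation of
within-group residuals, floored at 0.

## Tumor-level summaries

A multiregional tumor is heterogeneous when two samples carry distinct
classified labels; homogeneous when all classified labels agree and no
sample is unclassified; undetermined otherwise. The asymmetry is
deliberate: two discordant labels prove heterogeneity even with missing
calls, while homogeneity cannot be proven while calls are missing. The
major component is the label covering ≥ 50% of classified samples; exact
ties are broken by mean enrichment score when scores are available,
else lexicographically (logged). General transcriptomic heterogeneity is
the maximum pairwise Euclidean distance of a tumor's samples in
PC1–PC3, from covariance PCA (gene centering only) on the 1000
highest-variance genes, with component signs fixed so each loading
vector sums non-negatively. Framework agreement uses accuracy and
Cohen's kappa; 2×2 enrichments use the conditional-MLE odds ratio with
exact CI and Fisher's exact p.

## Consensus NMF subtyping on ITH-low genes

Expression is anti-logged (2^x) to obtain the non-negative input NMF
requires. Factorisation minimises the generalized Kullback–Leibler
divergence D(V‖WH) by multiplicative updates from random non-negative
initialisation; terms with V = 0 contribute WH (limit convention) and WH
is floored at machine epsilon. The per-iteration objective trace is
recorded and is non-increasing up to round-off; iteration stops at a
relative objective change below 1e-5 (tighter in oracle tests) or at the
iteration cap.

For each rank k the fit is repeated over n_runs random starts (100 by
default; 10–20 in test scenarios for speed — the methods are unchanged,
only the run count). Samples are hard-assigned to the argmax row of H
(ties to the lowest index, logged); the consensus matrix is the
run-averaged connectivity. Final labels cut an average-linkage
dendrogram of (1 − consensus) at k; diagnostics are the cophenetic
correlation of that dendrogram against the (1 − consensus) distances and
the mean silhouette width on the same distances. The selected rank is
the one preceding the first drop larger than 0.05 (configurable) in
either diagnostic — an operationalisation of "first large drop", which
is qualitative in the underlying procedure; with no such drop the
largest evaluated rank is returned with a warning.

Cluster-to-reference mapping maximises agreement via Hungarian
assignment on the confusion matrix; surplus clusters beyond the
reference classes are named `<class>.5` after their best-overlapping
reference class and excluded from kappa. For external series, genes with
median log2 expression < 4 or variance < 0.1 are removed before
classification.

## Survival analysis

Relapse-free survival uses a 5-year horizon: event-free follow-up beyond
60 months is administratively censored at 60. Kaplan–Meier estimates
carry Greenwood standard errors; group comparisons use the log-rank
test. Cox proportional-hazards models are fitted by partial likelihood
with the Efron tie correction (month-resolution times produce ties),
via lifelines; every term is checked against the PH assumption with
scaled Schoenfeld residuals on Kaplan–Meier-transformed time.

Explained variation per covariate uses the likelihood-ratio pseudo-R²,
R² = 1 − exp(−LR/n). Each term's raw contribution is the drop in R² when
the term is removed from the full model; negative raw contributions are
floored at zero (logged) and the contributions are rescaled to sum to
100% of the full model's R². Uncertainty comes from a nonparametric
bootstrap over patients (5000 replicates by default; reduced in test
scenarios). Any monotone-equivalent pseudo-R² would change the absolute
percentages, so the package asserts ordering and recovery properties of
the partition, not particular printed percentages.

## The synthetic cohort generator

The generator emulates the structure of a multiregional colorectal
cancer series so every estimator has a recoverable ground truth:

* 100 tumors with 2–4 spatially distinct samples each (mean 2.9 under
  the default distribution {2: 0.3, 3: 0.5, 4: 0.2}), one patient per
  tumor.
* Per-gene two-level variance: a tumor-level random effect and a
  residual, with a category-specific profile (template, superclass,
  stromal, low/intermediate/high background, flat). Flat genes fail the
  expression-range filter by construction, mirroring the large
  non-informative fraction of real transcriptomes.
* Four latent subtypes (CMS1–4, default proportions 0.25/0.30/0.25/0.20)
  expressed through 100 signed template genes per class at log2FC 2.0
  (4-fold — typical of strong subtype markers; the derivation threshold
  of 1.0 would be straddled by weaker effects). CMS1/CMS3 effects are
  scaled by 0.7, making the MSI-like pair transcriptionally closer than
  CMS2/CMS4, and an 80-gene superclass axis (log2FC 1.2) separates
  {CMS1, CMS3} from {CMS2, CMS4}. This two-level geometry mirrors the
  empirical nesting of a two-state intrinsic classification inside the
  four-subtype structure, and it makes low-rank consensus merges
  data-determined rather than initialisation-determined.
* A stromal-infiltration confounder: per-sample infiltration
  ~ Uniform(0, 1), independent of tumor, scales a dedicated gene block,
  so stromal genes are ITH-high by construction — the generator's
  counterpart of stroma-driven transcriptomic heterogeneity.
* Heterogeneous tumors (default fraction 0.4) carry one minor subtype
  from a fixed pairing (CMS2↔CMS4, CMS1↔CMS3, the combinations observed
  in multiregional data); about 35% of their samples are assigned the
  minor class, the major class always retaining ≥ 50%. Every sample of a
  heterogeneous tumor is additionally a within-sample mixture of the two
  classes (admixture weight 0.35 for the non-assigned class), because
  bulk regions of a mixed tumor are never clonally pure. This admixture
  is what makes single-sample heterogeneity calling a well-posed
  recovery problem; with pure samples a single-sample caller would have
  nothing to detect.
* MSI labels correlated with subtype (P(MSI) = 0.75/0.02/0.25/0.05 for
  CMS1–4) and exponential relapse-free survival with subtype log-hazard
  offsets (reference CMS1; HRs ≈ 3.7/2.3/4.3 for CMS2–4), a
  heterogeneity offset (HR ≈ 1.6), baseline hazard 0.0015/month,
  independent exponential censoring (0.005/month) and administrative
  censoring at 120 months. An exponential (constant-hazard) model was
  chosen over Weibull for simple parameter-recovery algebra.
* Optional patient-matched metastasis samples whose subtype switches
  from the primary's with a configurable probability (phenotypic
  plasticity).

What the generator does **not** emulate: platform/batch effects,
probe-level noise, correlated gene-gene co-expression modules beyond the
planted factors, copy-number or mutation effects on expression, non-
proportional hazards, and informative censoring. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not performance on any particular real dataset; on real data the
caller's operating characteristics will be worse than the near-ceiling
values seen on clean synthetic mixtures.

## Numerical and design choices

* REML search on log(gamma) over ±16 around the ANOVA start, `xatol`
  1e-10; explicit comparison against the gamma = 0 boundary.
* Degenerate inputs: all-singleton tumors are an error (residual
  variance unidentifiable); genes failing the fit are reported
  `not_scored` rather than dropped.
* Ranks use average ties throughout; permutation p-values carry the
  +1/(B+1) floor and are exactly reproducible given (seed, B).
* NMF hard assignment uses argmax of H without column scaling; runs that
  produce an empty cluster are kept and logged.
* A cophenetic correlation that is undefined because all consensus
  distances coincide (perfect consensus) is reported as 1.
* Cox fits that fail outright are retried with a 1e-6 ridge penalty and
  flagged `converged = False`.
* Survival-eligibility filters (stage I–III, etc.) are explicit
  sample-sheet predicates applied by the caller, not hidden defaults.

## Problem sizes in tests

The test suite and the acceptance script run the full pipeline at
reduced but statistically meaningful sizes chosen as the package's own
test design: 100–400 tumors per cohort, 2000 genes (of which ~1450 pass
the range filter), B = 500 permutations, n_runs = 10–20 NMF restarts,
and 20 replicate cohorts for replicate-level claims. Defaults in the
library remain at the full values (B = 1000, n_runs = 100, 5000
bootstrap replicates).
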