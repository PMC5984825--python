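# Methods

## The data model and what the generator emulates

`cortexsig.simulate` produces cohorts shaped like a two-region post-mortem
cortical microarray study: `n_subjects_case = 15` and
`n_subjects_control = 16` subjects, each contributing a frontal and a
temporal cortex sample (62 samples; designs with one region per subject are
supported). Subject-level covariates are drawn once per subject and shared
by both of the subject's samples:

| covariate | distribution | rationale |
|---|---|---|
| RIN | Normal(7.5, 1) truncated > 0 | plausible brain-bank RNA quality |
| PMI (hours) | Normal(20, 8) truncated > 0 | plausible post-mortem intervals |
| age (years) | Uniform(5, 60) | wide pediatric-to-adult span |
| sex | Bernoulli(0.8 male) | male-skewed case ascertainment |

Expression on the log2 scale is

    x_gs = μ_g + Δ_g·case_s + λ_g·f_s + Σ_c γ_c·z_cs + ε_gs

with μ_g ~ N(`baseline_mean`=8, `baseline_sd`=1.5), ε ~ N(0, `noise_sd`=0.5),
f_s ~ N(0, `factor_sd`=1) per sample, and covariate slopes γ (defaults: RIN
0.05, PMI −0.005, age −0.002, male +0.05, temporal +0.1 log2 units per
covariate unit). The matrix handed to preprocessing holds raw intensities
2^x so the detection filter, log2 transform and quantile normalization
apply exactly as to real array data. Detection p-values are Uniform(0, 0.05)
except at a `detection_fail_rate` (default 0.05) of positions, which get
Uniform(0.05, 1). One seeded generator drives every draw, so a config
reproduces its dataset bit for bit.

The default planted condition mirrors the study design the analysis is
meant for: a 50-gene "mitochondria" set and a 100-gene "synapse" set, both
shifted by Δ = −0.5 log2 in cases, both loading λ = 0.3 on the shared
factor. Two consequences are worth stating plainly:

* With Δ = −0.5 on both pathways and `noise_sd` = 0.5, the diagnosis shift
  alone already induces a mito-synapse signature correlation above ~0.93;
  the measured default correlation is ≈ 0.94–0.97. A correlation nearer 0.9
  would require either much larger gene-level noise (which would starve the
  differential-expression step) or a weaker planted shift; we kept the
  shift and accept the stronger correlation.
* λ = 0.3 is the only subject/sample-level variance component beyond
  averaged gene noise. Much smaller loadings make the signature separate
  the groups almost perfectly, which is unrealistic and makes logistic
  regression degenerate (quasi-separation).

`null_config()` zeroes Δ, λ **and** the covariate slopes γ. The last matters:
with γ ≠ 0 a subject's two region samples share an expression shift, so
pooled two-sample tests over 62 non-independent samples would be
miscalibrated by design — a property of pseudo-replication, not of the code
under test. Calibration claims are therefore made under the full null;
`signature_ttest(..., collapse_subjects=True)` offers the subject-mean
collapse for correlated designs.

What the generator does **not** emulate: probe-level chip physics, batch
effects, missing values, non-normal heavy-tailed noise, gene-gene
correlation beyond the single shared factor, or realistic annotation
databases. Passing tests show the pipeline's statistical machinery is
correct and calibrated under the stated model; they do not certify
performance on real arrays.

## Preprocessing

* **Detection filter**: keep a probe iff it is detected (detection
  p < 0.05, strict) in at least ⌈fraction·n⌉ of the autism samples or of
  the control samples (default fraction 0.5; ceiling is the conservative
  reading of "at least half" for odd group sizes).
* **log2**: y = log2(max(x, floor)), floor = 1.
* **Quantile normalization**: every column is mapped onto the per-rank
  across-column means; ties within a column receive the mean of the
  reference values at their tied ranks (the common convention).
* **Inter-array QC** (advisory; nothing is removed automatically): flag a
  sample whose *mean* Pearson correlation with the others is ≤ 0.85
  (configurable; whether to use mean or minimum is an open choice — mean is
  the default), whose column is constant ("zero variance"), or which joins
  an average-linkage dendrogram on 1 − r as a singleton above
  Q3 + 1.5·IQR of merge heights. With very few arrays one outlier drags
  every array's mean correlation down, so exclusive flagging of the bad
  array should only be expected at n ≳ 8.
* **Probe collapsing**: probes mapping to several genes get one gene chosen
  uniformly at random (seeded). Genes measured by several probes are then
  *dropped entirely* in list mode (the rule for enrichment inputs, so no
  genomic feature is over-represented) or collapsed to the highest-mean
  probe in matrix mode (needed to build gene-level signatures).

## Differential expression

Each gene is fit by OLS against a shared design (intercept, diagnosis with
control as reference, then RIN, PMI, age, sex, region as configured).
Subjects contributing two regions are treated as independent samples in the
pooled fit — deliberately, matching the region-stratified reruns provided
alongside; no mixed model is fitted. Rank-deficient designs raise an error
naming the collinear columns (note a 31-subject draw can produce an
all-male cohort, in which case `sex` must be dropped by the caller).

Variance moderation follows the standard empirical-Bayes scheme: with
e_g = log s²_g − ψ(d/2) + log(d/2), the prior df solves
trigamma(d₀/2) = Var(e) − trigamma(d/2) (Newton inversion) and
s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)); when the observed spread of log
variances does not exceed its sampling noise, d₀ = ∞ and s₀² is the plain
mean variance. The moderated t uses d₀ + d_g degrees of freedom; we do not
cap d₀ + d_g at the total pooled df (the reference R implementation does,
which changes p-values only in the d₀ = ∞ regime and only marginally — the
test suite cross-checks t, d₀ and s₀² against R limma to 1e−10).

Limits: d₀ = 0 reproduces the ordinary t exactly; d₀ = ∞ pins every gene's
variance to s₀². BH adjustment is the standard step-up with enforced
monotonicity (backed by statsmodels, verified against a brute-force
implementation). Region-restricted reruns skip BH by default rationale:
with half the samples nothing survives correction, and the reruns are used
only to check list overlap with the pooled fit.

## Enrichment and annotation clustering

Over-representation of a gene list (size n) against a term (K of N
background genes, overlap k) uses the hypergeometric upper tail
P(X ≥ k); the EASE variant scores P(X ≥ k−1), with k ≤ 1 scoring 1 by
convention so single-gene overlaps never rank. BH is applied across tested
terms on the EASE p. Annotation clustering follows the medium-stringency
defaults of the DAVID-style scheme: Cohen's kappa of term memberships over
the background, seed groups of a term plus its κ ≥ 0.50 neighbours kept at
≥ 3 terms, merging of groups sharing ≥ 50% of the smaller group's members
iterated to a fixed point (the merge loop strictly decreases the group
count, so it terminates), final clusters of ≥ 3 terms scored by the mean of
−log10 EASE p (the geometric-mean convention; p floored at 1e−300).
Cluster *contents* on real data depend on the annotation snapshot used and
are not a target of this package's tests.

## Signatures and the random-set null

A pathway is `(base ∩ include) \ ∪ exclusions` — e.g. downregulated genes
in the mitochondrion term, minus the synapse pathway and a related
co-expression module — and errors if empty. Its signature is the unweighted
per-sample mean over the pathway genes present in the matrix. Group
difference is tested by Welch's t (Student's is a flag) and by logistic
regression of diagnosis on the signature plus covariates (Newton, BFGS
fallback; separation detected via the fitter's warning and reported as an
error).

The correlation null fixes one pathway and redraws the *reference*: B sets
of exactly the reference's effective size (genes present in the matrix),
sampled uniformly without replacement from all matrix genes. Pathway genes
are *not* excluded from the pool by default (an `exclude_fixed` flag
exists); consequently random sets occasionally overlap the fixed pathway
and share its gene-level noise, which shifts the null exceedance slightly
upward of uniform — the calibration tests therefore assert the operational
property (share of null runs with exceedance < 0.05 is ≈ 0.05), not exact
uniformity. Exceedance uses strict `>` ("greater correlation than all but
x% of random sets"); `permutation_p()` gives the (+1)/(B+1) version. Draws
are generated in fixed-size chunks from one seeded generator, so the null
vector is bit-reproducible for a given seed regardless of B's chunking.

## Reporting

Heatmaps z-score each gene row (ddof = 1) and order rows and columns by
average-linkage hierarchical clustering on Euclidean distance; constant
rows are excluded with a warning; ties are broken by input order, making
the layout deterministic for a given input. Every figure writes a TSV twin
of exactly the plotted values.

## Problem sizes used by the test suite

The acceptance-style tests run the calibration and power studies at 2,000
genes with 500 (t-test calibration), 200 (exceedance calibration and
t-test power) and 100 (logistic calibration, exceedance power) replicate
cohorts, B = 500–1,000 null draws per run, and the end-to-end
reproducibility check at 1,500 genes with B = 400 — sizes chosen so the
whole suite completes in a couple of minutes while keeping Monte-Carlo
error well inside the asserted bands. The acceptance script runs the full
12,632-gene, 62-sample, B = 10,000 configuration.

## Known limitations

* Pooled per-gene fits ignore the within-subject correlation of paired
  regions (by design, with stratified reruns as the check).
* The d₀ = ∞ p-values differ marginally from implementations that cap the
  total degrees of freedom.
* The generator's single shared factor cannot represent multiple
  overlapping co-expression modules; clustering tests use constructed term
  families instead.
* Signature tests assume enough pathway genes survive preprocessing; empty
  pathways are a hard error rather than a silent skip.
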