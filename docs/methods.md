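# Methods

`copdsubtype` implements a candidate-gene molecular-subtyping analysis for
bulk expression cohorts, of the kind used to stratify COPD patients from
blood microarray profiles. This note documents the statistical procedure,
the parameters that matter, the synthetic-cohort model used for testing, and
the design decisions taken where the procedure was genuinely open.

## The procedure

**Working scale.** Input expression is assumed already background-corrected
and summarized (e.g. RMA output exported as TSV). Probes mapping to the same
gene symbol are collapsed by their arithmetic mean (a probe annotated to
several symbols contributes to each), then every gene row is z-scored to
mean 0 and sample SD 1 (ddof = 1). Zero-variance genes are dropped and
reported. The fixed order is collapse → z-score → subset-to-candidates;
z-scoring before or after collapsing gives slightly different scales, and
the collapse-first order was fixed so that the normalized scale is the one
every downstream statistic sees.

**Subtype discovery.** Samples are clustered on the candidate-gene submatrix
with average-linkage (UPGMA) agglomeration. The default inter-sample
distance is 1 − Pearson correlation between expression profiles — the
community default for expression data, where profile shape matters more
than magnitude; Euclidean distance is available. Clustering fidelity is
summarized by the cophenetic correlation coefficient (Pearson correlation
between the n(n−1)/2 input distances and the dendrogram-implied distances).
The tree is cut into exactly k subtypes (default k = 3). Cluster numbers are
arbitrary, so labels are renumbered 1..k by decreasing cluster size, with
ties broken by the earliest member in sample order; this makes confusion
matrices reproducible across runs.

**Gene allocation.** Each candidate gene is tested per subtype with a Welch
(unequal-variance) two-sample t-test, subtype versus all remaining samples,
two-sided. Welch's form is the robust default when subtype sizes are
unequal. A gene joins every subtype with p < α (α = 0.05, raw p by default —
Benjamini–Hochberg is available but off, matching the common raw-threshold
practice in candidate-gene studies); among its significant subtypes, the one
with the largest |t| is flagged *primary*. Membership is deliberately
overlapping: with strongly shifted genes a subtype-vs-rest test is
significant in several subtypes at once, and the cross-subtype *common gene
set* is defined as the intersection of the per-subtype sets.

**Pathway enrichment.** Each subtype's gene set is tested for
over-representation in every pathway of a GMT annotation by one-sided
Fisher's exact test, with the universe defaulting to the genes present in
both the expression matrix and the annotation. P-values are BH-adjusted
across pathways within one query; a pathway is *enriched* at adjusted
p < 0.05. Pathways enriched in every subtype are *common*; those enriched in
exactly one are *unique* to it.

**Deviation score.** The functional deviation of pathway P in subtype c is

    A(P) = (1/N) · Σᵢ (X̄ᵢ − Ȳᵢ)²,

the mean squared difference between the subtype mean X̄ᵢ and the cohort mean
Ȳᵢ of each of the N differential genes of subtype c lying in P. On z-scored
data Ȳᵢ = 0, so A(P) is the mean squared subtype mean — 0 exactly when the
subtype is indistinguishable from the cohort, growing with the shift of its
differential genes. Pathways with N = 0 for a subtype are skipped with a
logged reason.

**Clinical association.** FEV1, FEV1/FVC and age are compared across
subtypes by one-way fixed-effects ANOVA. Sex is a binary category, so it is
tested by a chi-square test of independence on the k×2 table (no continuity
correction); an ANOVA-on-0/1-coding mode exists behind a flag for strict
replication of pipelines that pushed sex through ANOVA. Missing values are
dropped per variable with logged counts.

**Subtype predictors.** An SVM needs a per-sample feature vector; the
subtype-level score A(P) does not provide one. The bridge is the per-sample
deviation feature

    d_s(P) = (1/N) · Σᵢ (x_{is} − Ȳᵢ)²,

with reference means Ȳᵢ learned from the training cohort and stored for
reuse. Note E_c[d_s(P)] ≠ A(P) in general — A squares a mean, d averages
squares (Jensen gap) — so the two are documented as related but distinct.
Feature columns are the common pathways (falling back to all enriched, then
to all pathways, with a logged warning), and each pathway's gene list is its
intersection with the allocated genes. One soft-margin linear SVM (C = 1) is
trained per subtype against the rest; multi-class prediction is the argmax
of decision scores with ties to the lower-numbered subtype. Performance is
estimated by stratified 5-fold cross-validation, pooling out-of-fold
decision scores into one ROC/AUC per subtype; pooled AUC equals the
normalized Mann–Whitney U of the scores, which the tests verify.

**Cross-cohort validation.** An independent cohort is restricted to the
genes shared with discovery, re-z-scored within itself, clustered on its own
at the same k, and also predicted by the trained SVMs. Cluster numbers are
matched to model classes by a Hungarian assignment maximizing the diagonal
of the predicted×clustered confusion matrix (logged). The per-class
*consistency ratio* is diagonal count / cluster-column total, reported as a
percentage at one decimal. Significance is assessed by permuting the
predicted labels uniformly across samples (preserving both marginals)
n_perm = 10,000 times; p = (1 + #{null ratio ≥ observed}) / (n_perm + 1),
which is bounded below by 1/(n_perm+1) and super-uniform under the null. A
"resample with replacement" mode exists as a sensitivity alternative.
Because a disease-only discovery cohort gives the model no control class,
an optional refit (`SubtypeClassifier.with_control_class`) adds a
control-vs-rest SVM trained on the validation cohort's known controls; it is
off by default and unused in the headline run.

## Synthetic cohorts

The generator emulates the structure of the target study design: a
genes×samples matrix (default 1000×229) in which a 213-gene candidate list
contains a fraction of *informative* genes; each informative gene has one
signature subtype whose mean is shifted by `effect_size · noise_sd`
(defaults 2.0 and 1.0); three subtypes at proportions 98:53:78; i.i.d.
Gaussian noise per gene (matching the z-normalized working scale); pathway
annotations of 50 sets, sizes 10–80, a configurable fraction planted with
informative genes; and clinical covariates with subtype-dependent
distributions — FEV1 (% predicted, N(55, 15²)) and FEV1/FVC (N(0.55, 0.08²))
lowered in the "severe" subtype 2 by `clinical_shift` SDs (default 0.4),
shared age N(63, 8²), and a higher female proportion outside subtype 1 when
`clinical_shift > 0`. The validation generator draws new samples (default
560) from the same subtype-mean model, optionally restricts to a random gene
subset (platform-difference emulation) and adds controls at the baseline
mean vector, labeled 0. A single seed drives independent per-stage
substreams (`numpy` `SeedSequence` spawn keys), so adding pathways never
perturbs expression draws and identical configs are bit-identical.

What the generator does **not** emulate: probe-level noise, batch effects,
correlated gene-gene structure beyond the planted means, heavy-tailed or
count-like intensity distributions, missingness, or clinical confounding.
Passing recovery tests therefore shows the machinery is correct and
calibrated under the planted model, not that real cohorts will separate this
cleanly. Effect sizes are calibration choices, not estimates of any real
cohort: no effect-size or variance figures were available for the cohorts
this design targets.

## Numerical and calibration choices

- Correlation distances are clipped at 0 to absorb ~1e-16 rounding
  negatives; UPGMA, cophenetic and tree-cutting use `scipy.cluster.hierarchy`
  and are verified against naive O(n³) re-implementations to 1e-10.
- Gene/subtype t-tests with zero variance in both groups and equal means
  return t = 0, p = 1 with a warning (no evidence either way).
- Fisher p-values come from the exact hypergeometric tail and are verified
  against full enumeration for all tables with margins ≤ 12.
- Calibration tests use planted (expression-independent) labels: clustering
  on the candidate genes and then t-testing the same genes against the
  resulting clusters is circular (selection bias) and anti-conservative, so
  the ~α allocation rate under the null holds only for independent labels.
  This circularity is inherent to the replicated design and is a known
  limitation of its error control.
- The null cross-validated AUC check uses an independent-label fixture of
  n = 210 samples, where the [0.35, 0.65] acceptance band spans ≈3.5
  binomial SDs of a null AUC; at much smaller n the band would be narrower
  than the null sampling noise and the check uninformative.
- TSV artifacts are written with a fixed `%.12g` float format so that equal
  configs and seeds produce byte-identical outputs; expression round-trips
  use `%.17g` (exact for doubles).

## Known limitations

- k is a parameter (default 3), not selected from the data; no consensus
  clustering or gap statistic.
- Raw p < 0.05 allocation performs no multiple-testing control by default.
- One-vs-rest SVM decision scores are uncalibrated; argmax across
  independently trained binary SVMs is a heuristic, adequate for the
  deviation-feature geometry but not a probability.
- Cross-platform harmonization is symbol-intersection plus re-z-scoring
  only; no batch-effect correction.
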