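# copdsubtype

Molecular subtyping of expression cohorts from a candidate-gene list, with
pathway deviation scoring, per-subtype SVM predictors, and cross-cohort
validation. The package targets the COPD setting — stratifying patients
whose clinical phenotypes are too heterogeneous to subtype directly, using
blood expression of disease candidate genes — but every stage is generic
over a gene×sample matrix, a gene list, a GMT pathway annotation, and a
clinical table.

## What it computes

Given a z-normalized expression matrix restricted to candidate genes, the
pipeline:

1. **discovers subtypes** by average-linkage (UPGMA) hierarchical clustering
   of samples under correlation distance d = 1 − r, assessed by the
   cophenetic correlation coefficient and cut into k clusters (default 3);
2. **allocates genes** to subtypes by Welch subtype-vs-rest t-tests
   (membership at p < 0.05, possibly in several subtypes, with a *primary*
   flag at the largest |t|), and intersects the per-subtype sets into the
   common gene set;
3. **enriches pathways** per subtype with one-sided Fisher's exact tests
   (BH-adjusted), partitioning them into common and subtype-unique;
4. **scores pathway deviation** per subtype, A(P) = (1/N) Σᵢ (X̄ᵢ − Ȳᵢ)²
   over the N differential genes of the subtype in pathway P, where X̄ᵢ is
   the subtype mean and Ȳᵢ the cohort mean of gene i;
5. **tests clinical indicators** (FEV1, FEV1/FVC, age by one-way ANOVA; sex
   by chi-square) across subtypes;
6. **trains one-vs-rest linear SVMs** (C = 1) on per-sample deviation
   features d_s(P) = (1/N) Σᵢ (x_{is} − Ȳᵢ)², evaluated by stratified
   5-fold cross-validated ROC/AUC; and
7. **validates on an independent cohort**: harmonize to shared genes,
   cluster the new cohort, predict it with the trained SVMs, match cluster
   numbers to model classes (Hungarian), and report per-class consistency
   ratios (diagonal / cluster total) with 10,000-draw permutation p-values.

A fully seeded synthetic-cohort generator (`copdsubtype.simulate`) plants
subtype structure, pathway enrichment and subtype-linked clinical
covariates, so the entire pipeline is testable without any downloads.

See `docs/methods.md` for the statistical details and design decisions.

## Worked example

```python
from copdsubtype import simulate as sim, cluster as cl, allocation as al
from copdsubtype.preprocess import zscore_rows, subset_to_candidates

config = sim.SynthConfig(seed=7)          # 229 samples, 213 candidates, k=3
expression, clinical, truth = sim.generate_cohort(config)

z, _ = zscore_rows(expression)
candidates = subset_to_candidates(z, truth.candidate_genes)

subtyper = cl.HierarchicalSubtyper(n_subtypes=3).fit(candidates.T)
assignment = subtyper.assignment_
print("subtype sizes:", assignment.counts().to_dict())
print("cophenetic correlation: %.3f" % subtyper.cophenetic_coefficient_)

table = al.differential_t_test(candidates, assignment)
gene_sets = al.allocate_genes(table, alpha=0.05)
print("per-subtype gene set sizes:", {c: len(g) for c, g in gene_sets.per_subtype.items()})
print("common genes:", len(gene_sets.common))
```

prints

```
subtype sizes: {1: 98, 2: 78, 3: 53}
cophenetic correlation: 0.970
per-subtype gene set sizes: {1: 162, 2: 162, 3: 161}
common genes: 160
```

The three planted subtypes are recovered with their exact sizes; the high
cophenetic coefficient says the dendrogram faithfully represents the
pairwise distances; the heavily overlapping per-subtype gene sets share a
160-gene core that is differential in every subtype.

The same analysis runs from the shell:

```bash
copdsubtype simulate --seed 7 --outdir data/
copdsubtype run-all --config config.yaml       # paths + parameters in YAML
```

where the stage subcommands (`preprocess`, `subtype`, `allocate`, `enrich`,
`deviate`, `clinical`, `train`, `validate`) run prefixes of the pipeline and
`run-all` writes every artifact (subtype labels, allocation table,
enrichment, deviation scores, ROC curves, confusion matrix, permutation
test) plus a checksummed manifest under the output directory.

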