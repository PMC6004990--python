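"""Synthetic expression cohorts with planted molecular subtypes.

Emulates the structure of a blood-expression COPD cohort: a gene x sample
matrix in which a subset of disease candidate genes carries subtype-specific
mean shifts, pathway annotations that may be enriched for those informative
genes, and clinical covariates (FEV1, FEV1/FVC, age, sex) whose distributions
differ by subtype. Everything is driven by one integer seed through
independent per-stage substreams, so e.g. adding pathways never perturbs the
expression draws.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# substream ids: one root seed, deterministic per-stage generators
_EXPRESSION, _CLINICAL, _PATHWAYS, _VALIDATION = 0, 1, 2, 3


def _substream(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the discovery-cohort shape the pipeline targets: 229
    samples, 213 candidate genes, three subtypes with proportions 98:53:78.
    ``effect_size`` is the mean shift of an informative gene in its signature
    subtype, in units of ``noise_sd``.
    """

    n_genes: int = 1000
    n_candidate_genes: int = 213
    n_samples: int = 229
    k_subtypes: int = 3
    subtype_proportions: tuple = (98 / 229, 53 / 229, 78 / 229)
    effect_size: float = 2.0
    frac_informative: float = 0.75
    noise_sd: float = 1.0
    n_pathways: int = 50
    pathway_size_range: tuple = (10, 80)
    clinical_shift: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_samples < 1 or self.n_pathways < 1:
            raise ValueError("n_genes, n_samples and n_pathways must be positive")
        if not (1 <= self.n_candidate_genes <= self.n_genes):
            raise ValueError("n_candidate_genes must be in [1, n_genes]")
        if self.k_subtypes < 2:
            raise ValueError("k_subtypes must be >= 2")
        props = tuple(float(p) for p in self.subtype_proportions)
        if len(props) != self.k_subtypes:
            raise ValueError("subtype_proportions must have length k_subtypes")
        if any(p < 0 for p in props):
            raise ValueError("subtype_proportions must be nonnegative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"subtype_proportions must sum to 1 (got {sum(props)!r})")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not (0.0 <= self.frac_informative <= 1.0):
            raise ValueError("frac_informative must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.pathway_size_range
        if lo < 2:
            raise ValueError("pathway_size_range min must be >= 2")
        if hi > self.n_genes:
            raise ValueError("pathway_size_range max must be <= n_genes")
        if lo > hi:
            raise ValueError("pathway_size_range must be (min, max) with min <= max")
        object.__setattr__(self, "subtype_proportions", props)
        object.__setattr__(self, "pathway_size_range", (int(lo), int(hi)))


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort.

    ``subtype_means`` holds the per-gene mean of every subtype (columns are
    subtype labels 1..k); ``baseline_means`` is the shared per-gene baseline
    used as the control/global mean in validation cohorts.
    """

    labels: pd.Series
    informative_genes: frozenset
    subtype_means: pd.DataFrame
    baseline_means: pd.Series
    noise_sd: float
    candidate_genes: tuple

    def __post_init__(self):
        labels = set(self.labels.unique())
        k = self.subtype_means.shape[1]
        if not labels <= set(range(0, k + 1)):
            raise ValueError("labels must lie in {1..k} (0 reserved for controls)")
        if not self.informative_genes <= set(self.candidate_genes):
            raise ValueError("every informative gene must be a candidate gene")


def _subtype_counts(proportions: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder apportionment of n samples to the subtypes."""
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def generate_cohort(config: SynthConfig):
    """Generate a discovery cohort.

    Returns ``(expression, clinical, truth)``: a genes x samples DataFrame, a
    clinical table indexed by sample (FEV1, FEV1_FVC, age, sex), and the
    :class:`GroundTruth`. Each informative candidate gene has one signature
    subtype whose mean is shifted by ``effect_size * noise_sd``; all other
    gene/subtype means sit at the gene's baseline.
    """
    rng = _substream(config.seed, _EXPRESSION)
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    candidates = tuple(genes[: config.n_candidate_genes])

    n_inf = int(round(config.frac_informative * config.n_candidate_genes))
    informative = frozenset(rng.choice(candidates, size=n_inf, replace=False)) if n_inf else frozenset()

    baseline = pd.Series(rng.normal(0.0, 1.0, size=config.n_genes), index=genes, name="baseline")
    k = config.k_subtypes
    means = pd.DataFrame(
        np.repeat(baseline.values[:, None], k, axis=1), index=genes, columns=range(1, k + 1)
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in sorted(informative):
        sig = int(rng.integers(1, k + 1))
        means.iat[gene_pos[g], sig - 1] += config.effect_size * config.noise_sd

    counts = _subtype_counts(config.subtype_proportions, config.n_samples)
    labels = np.repeat(np.arange(1, k + 1), counts)
    labels = labels[rng.permutation(config.n_samples)]
    labels = pd.Series(labels, index=samples, name="subtype")

    mu = means.values[:, labels.values - 1]
    values = mu + rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_samples))
    expression = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)

    clinical = _generate_clinical(config, labels, _substream(config.seed, _CLINICAL))
    truth = GroundTruth(
        labels=labels,
        informative_genes=informative,
        subtype_means=means,
        baseline_means=baseline,
        noise_sd=config.noise_sd,
        candidate_genes=candidates,
    )
    return expression, clinical, truth


# clinical scales: FEV1 as % predicted, FEV1/FVC as a ratio. Subtype 2 is the
# "severe" subtype (lower lung function); females over-represented outside
# subtype 1 when clinical_shift > 0, matching the reported pattern.
_FEV1_MEAN, _FEV1_SD = 55.0, 15.0
_RATIO_MEAN, _RATIO_SD = 0.55, 0.08
_AGE_MEAN, _AGE_SD = 63.0, 8.0
_FEMALE_BASE = 0.35


def _generate_clinical(config: SynthConfig, labels: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    n = len(labels)
    severe = 2 if config.k_subtypes >= 2 else 1
    is_severe = (labels.values == severe).astype(float)
    fev1 = rng.normal(_FEV1_MEAN - config.clinical_shift * _FEV1_SD * is_severe, _FEV1_SD)
    ratio = rng.normal(_RATIO_MEAN - config.clinical_shift * _RATIO_SD * is_severe, _RATIO_SD)
    age = rng.normal(_AGE_MEAN, _AGE_SD, size=n)
    p_female = np.where(
        labels.values == 1, _FEMALE_BASE, min(_FEMALE_BASE + 0.5 * config.clinical_shift, 0.9)
    )
    sex = np.where(rng.random(n) < p_female, "female", "male")
    return pd.DataFrame(
        {
            "FEV1": np.clip(fev1, 5.0, None),
            "FEV1_FVC": np.clip(ratio, 0.05, 1.0),
            "age": np.clip(age, 18.0, None),
            "sex": sex,
        },
        index=pd.Index(labels.index, name="sample"),
    )


def generate_pathway_annotation(
    config: SynthConfig,
    gene_universe: Sequence[str],
    informative_genes: frozenset | set,
    enriched_fraction: float = 0.3,
    enrichment_strength: float = 0.5,
) -> dict:
    """Generate ``n_pathways`` gene sets over ``gene_universe``.

    A fraction ``enriched_fraction`` of the pathways is planted with
    informative genes: roughly ``enrichment_strength`` of their members are
    drawn from ``informative_genes``, the rest uniformly from the remaining
    universe. With ``enriched_fraction=0`` membership is uniform, so
    over-representation p-values for the informative genes are null.

    Returns a mapping ``pathway_id -> (description, frozenset of members)``.
    """
    universe = list(dict.fromkeys(gene_universe))
    if not universe:
        raise ValueError("gene_universe must be nonempty")
    lo, hi = config.pathway_size_range
    if hi > len(universe):
        raise ValueError(
            f"pathway_size_range max {hi} exceeds universe size {len(universe)}"
        )
    if not (0.0 <= enriched_fraction <= 1.0):
        raise ValueError("enriched_fraction must lie in [0, 1]")
    rng = _substream(config.seed, _PATHWAYS)
    informative = sorted(set(informative_genes) & set(universe))
    other = sorted(set(universe) - set(informative))
    n_enriched = int(round(enriched_fraction * config.n_pathways)) if informative else 0
    collection = {}
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched:
            n_from_inf = min(max(1, int(round(enrichment_strength * size))), len(informative), size)
            members = list(rng.choice(informative, size=n_from_inf, replace=False))
            pool = other if len(other) >= size - n_from_inf else sorted(set(universe) - set(members))
            members += list(rng.choice(pool, size=size - n_from_inf, replace=False))
            desc = "synthetic pathway (planted enrichment)"
        else:
            members = list(rng.choice(universe, size=size, replace=False))
            desc = "synthetic pathway"
        collection[f"PATH{i:04d}"] = (desc, frozenset(members))
    return collection


def generate_validation_cohort(
    config: SynthConfig,
    discovery_truth: GroundTruth,
    n_controls: int = 57,
    n_samples: Optional[int] = None,
    gene_fraction: float = 1.0,
    control_means: Optional[pd.Series] = None,
):
    """Generate an independent cohort from the discovery subtype-mean model.

    ``n_samples`` disease samples (default 560) are drawn with the configured
    subtype proportions, plus ``n_controls`` control samples whose mean vector
    is ``control_means`` (default: the discovery baseline). ``gene_fraction``
    keeps a random subset of the gene universe to emulate a different array
    platform. Control samples carry label 0 in the returned ground truth.
    """
    if n_controls < 0:
        raise ValueError("n_controls must be nonnegative")
    if not (0.0 < gene_fraction <= 1.0):
        raise ValueError("gene_fraction must lie in (0, 1]")
    n_samples = 560 if n_samples is None else int(n_samples)
    if n_samples < 0 or n_samples + n_controls == 0:
        raise ValueError("need at least one sample")
    rng = _substream(config.seed, _VALIDATION)
    means = discovery_truth.subtype_means
    genes = list(means.index)
    if gene_fraction < 1.0:
        keep = max(2, int(round(gene_fraction * len(genes))))
        kept = rng.choice(genes, size=keep, replace=False)
        genes = [g for g in means.index if g in set(kept)]  # preserve order
    means = means.loc[genes]
    control_mu = (
        discovery_truth.baseline_means.loc[genes]
        if control_means is None
        else control_means.loc[genes]
    )

    k = means.shape[1]
    counts = _subtype_counts(config.subtype_proportions, n_samples)
    labels = np.concatenate([np.repeat(np.arange(1, k + 1), counts), np.zeros(n_controls, int)])
    labels = labels[rng.permutation(len(labels))]
    sample_ids = [f"V{i:04d}" for i in range(len(labels))]
    labels = pd.Series(labels, index=sample_ids, name="subtype")

    mu = np.where(
        labels.values[None, :] == 0,
        control_mu.values[:, None],
        means.values[:, np.clip(labels.values - 1, 0, k - 1)],
    )
    values = mu + rng.normal(0.0, discovery_truth.noise_sd, size=(len(genes), len(labels)))
    expression = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)

    clinical = _generate_clinical(config, labels, rng)
    # controls: near-normal spirometry
    is_control = labels.values == 0
    clinical.loc[is_control, "FEV1"] = np.clip(rng.normal(92.0, 10.0, is_control.sum()), 5.0, None)
    clinical.loc[is_control, "FEV1_FVC"] = np.clip(
        rng.normal(0.79, 0.05, is_control.sum()), 0.05, 1.0
    )

    truth = GroundTruth(
        labels=labels,
        informative_genes=frozenset(g for g in discovery_truth.informative_genes if g in set(genes)),
        subtype_means=means,
        baseline_means=control_mu.rename("baseline"),
        noise_sd=discovery_truth.noise_sd,
        candidate_genes=tuple(g for g in discovery_truth.candidate_genes if g in set(genes)),
    )
    return expression, clinical, truth


def write_cohort(
    outdir,
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    truth: GroundTruth,
    pathways: Optional[Mapping] = None,
    prefix: str = "discovery",
) -> dict:
    """Write a generated cohort in the formats the pipeline reads.

    Emits expression TSV, clinical TSV, candidate gene list, ground-truth
    labels TSV and (optionally) a GMT file; returns the path map.
    """
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["expression"] = outdir / f"{prefix}_expression.tsv"
    _io.write_expression_table(expression, paths["expression"])
    paths["clinical"] = outdir / f"{prefix}_clinical.tsv"
    _io.write_clinical_table(clinical, paths["clinical"])
    paths["candidates"] = outdir / f"{prefix}_candidates.txt"
    _io.write_gene_list(truth.candidate_genes, paths["candidates"])
    paths["truth"] = outdir / f"{prefix}_true_labels.tsv"
    truth.labels.rename("true_label").to_frame().to_csv(paths["truth"], sep="\t")
    if pathways is not None:
        paths["gmt"] = outdir / f"{prefix}_pathways.gmt"
        _io.write_gmt(pathways, paths["gmt"])
    return paths
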