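"""Cross-cohort validation: confusion matrix, consistency ratios, permutation test.

A model trained on the discovery cohort predicts subtypes for an independent
cohort; the cohort is also clustered on its own, and agreement between the
two labelings is summarized in a predicted x clustered confusion matrix.
Cluster numbers are arbitrary, so they are matched to model classes by a
Hungarian assignment maximizing the diagonal before any ratio is computed.
The per-class consistency ratio is diagonal count / column (cluster) total;
its significance is assessed by permuting the predicted labels uniformly
across samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .preprocess import zscore_rows

logger = logging.getLogger(__name__)


def harmonize_features(discovery: pd.DataFrame, validation: pd.DataFrame):
    """Restrict both genes x samples matrices to their shared genes (discovery
    order) and re-z-score the validation cohort within itself."""
    shared = [g for g in discovery.index if g in set(validation.index)]
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared genes between cohorts; need at least 2")
    logger.info("harmonize_features: %d shared genes retained", len(shared))
    val, report = zscore_rows(validation.loc[shared])
    shared = [g for g in shared if g in set(val.index)]  # drop zero-variance genes from both
    return discovery.loc[shared], val.loc[shared]


@dataclass
class ConfusionMatrix:
    """Predicted (rows) x clustered (columns) counts."""

    counts: pd.DataFrame
    alignment: Optional[dict] = None  # original cluster label -> model class

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ConfusionMatrix":
        counts = counts.astype(int)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        return cls(counts=counts)


def align_cluster_labels(cluster_labels: pd.Series, predicted_labels: pd.Series) -> pd.Series:
    """Relabel clusters to best match the predicted classes (Hungarian, max diagonal)."""
    cluster_labels, predicted_labels = _check_samples(cluster_labels, predicted_labels)
    counts = pd.crosstab(predicted_labels, cluster_labels)
    classes = sorted(set(counts.index) | set(counts.columns))
    square = counts.reindex(index=classes, columns=classes, fill_value=0)
    rows, cols = linear_sum_assignment(-square.to_numpy())
    mapping = {classes[c]: classes[r] for r, c in zip(rows, cols) if classes[c] in counts.columns}
    logger.info("align_cluster_labels: cluster -> model class mapping %s", mapping)
    return cluster_labels.map(mapping).rename(cluster_labels.name)


def _check_samples(cluster_labels: pd.Series, predicted_labels: pd.Series):
    cluster_labels = pd.Series(cluster_labels)
    predicted_labels = pd.Series(predicted_labels)
    extra = set(cluster_labels.index) ^ set(predicted_labels.index)
    if extra:
        raise ValueError(
            f"cluster and predicted labels cover different samples; difference: {sorted(extra)[:5]}"
        )
    return cluster_labels, predicted_labels.loc[cluster_labels.index]


def build_confusion_matrix(
    cluster_labels: pd.Series, predicted_labels: pd.Series, align: bool = True
) -> ConfusionMatrix:
    """Counts[r][c] = number of samples predicted r and clustered c."""
    cluster_labels, predicted_labels = _check_samples(cluster_labels, predicted_labels)
    alignment = None
    if align:
        aligned = align_cluster_labels(cluster_labels, predicted_labels)
        alignment = dict(sorted(set(zip(cluster_labels, aligned))))
        cluster_labels = aligned
    classes = sorted(set(cluster_labels) | set(predicted_labels))
    counts = (
        pd.crosstab(predicted_labels, cluster_labels)
        .reindex(index=classes, columns=classes, fill_value=0)
        .rename_axis(index="predicted", columns="cluster")
    )
    return ConfusionMatrix(counts=counts, alignment=alignment)


def consistency_ratios(cm: ConfusionMatrix) -> pd.Series:
    """Per-class diagonal / column-total agreement, as percent rounded to one decimal."""
    totals = cm.column_totals
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise ValueError(f"cluster classes with zero samples: {zero}")
    shared = [c for c in cm.counts.columns if c in cm.counts.index]
    ratios = {c: round(100.0 * cm.counts.at[c, c] / totals[c], 1) for c in shared}
    return pd.Series(ratios, name="consistency_ratio_percent")


@dataclass
class PermutationResult:
    observed: pd.Series  # per class, ratio in [0, 1]
    pvalues: pd.Series
    n_permutations: int
    seed: int

    def __post_init__(self):
        lower = 1.0 / (self.n_permutations + 1)
        if ((self.pvalues < lower - 1e-12) | (self.pvalues > 1.0)).any():
            raise ValueError("permutation p-values outside (0, 1] bounds")


def permutation_significance(
    cluster_labels: pd.Series,
    predicted_labels: pd.Series,
    n_permutations: int = 10000,
    seed: int = 0,
    mode: str = "permute",
) -> PermutationResult:
    """Monte-Carlo significance of each class's consistency ratio.

    The null reshuffles the predicted labels across samples (``mode="permute"``,
    preserving both marginals) or resamples them with replacement
    (``mode="resample"``); p = (1 + #{null ratio >= observed}) / (n_perm + 1).
    Class vocabularies are assumed already aligned (see
    :func:`align_cluster_labels`).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if mode not in ("permute", "resample"):
        raise ValueError("mode must be 'permute' or 'resample'")
    cluster_labels, predicted_labels = _check_samples(cluster_labels, predicted_labels)
    clust = cluster_labels.to_numpy()
    pred = predicted_labels.to_numpy()
    classes = sorted(set(clust))
    masks = {c: clust == c for c in classes}
    denom = {c: masks[c].sum() for c in classes}
    if any(d == 0 for d in denom.values()):
        raise ValueError("every cluster class needs at least one sample")
    observed = {c: (pred[masks[c]] == c).mean() for c in classes}
    rng = np.random.default_rng(seed)
    exceed = {c: 0 for c in classes}
    n = len(pred)
    for _ in range(n_permutations):
        null = rng.permutation(pred) if mode == "permute" else rng.choice(pred, size=n, replace=True)
        for c in classes:
            if (null[masks[c]] == c).mean() >= observed[c]:
                exceed[c] += 1
    pvalues = {c: (1 + exceed[c]) / (n_permutations + 1) for c in classes}
    return PermutationResult(
        observed=pd.Series(observed),
        pvalues=pd.Series(pvalues, name="permutation_p"),
        n_permutations=n_permutations,
        seed=seed,
    )


def write_confusion_tsv(cm: ConfusionMatrix, path) -> None:
    """TSV mirroring the published layout: count rows, then Total and Ratio rows."""
    out = cm.counts.copy().astype(object)
    totals = cm.column_totals
    ratios = consistency_ratios(cm)
    out.loc["Total"] = totals
    out.loc["Ratio"] = [
        f"{ratios[c]:.1f}%" if c in ratios.index else "" for c in out.columns
    ]
    out.to_csv(path, sep="\t")
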