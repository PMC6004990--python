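"""Molecular subtype discovery by average-linkage hierarchical clustering.

Samples are clustered on candidate-gene expression with UPGMA (average
linkage); the dendrogram is assessed by the cophenetic correlation
coefficient and cut into k subtypes. The default inter-sample distance is
1 - Pearson correlation, the community default for expression profiles;
Euclidean distance is available as an alternative.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

_METRICS = ("correlation", "euclidean")


@dataclass
class Dendrogram:
    """An agglomerative merge history: scipy linkage matrix plus leaf ids."""

    linkage: np.ndarray  # (n-1, 4): left, right, height, size
    leaf_ids: tuple

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


@dataclass
class SubtypeAssignment:
    """Sample -> subtype labels (1..k) with the tree that produced them."""

    labels: pd.Series
    k: int
    cophenetic_coefficient: Optional[float] = None
    dendrogram: Optional[Dendrogram] = None

    def __post_init__(self):
        found = set(self.labels.unique())
        if found != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k} with no empty subtype, got {sorted(found)}")

    def counts(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def compute_distance(matrix: pd.DataFrame, metric: str = "correlation") -> pd.DataFrame:
    """Pairwise sample distances from a gene x sample matrix.

    ``correlation`` gives d = 1 - Pearson r between sample columns (range
    [0, 2]); ``euclidean`` the standard L2 norm.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.to_numpy().T  # samples in rows
    if metric == "correlation":
        sds = X.std(axis=1)
        if (sds == 0).any():
            bad = matrix.columns[np.flatnonzero(sds == 0)[0]]
            raise ValueError(
                f"sample {bad!r} has zero variance across genes; correlation distance undefined"
            )
    condensed = pdist(X, metric=metric)
    condensed = np.maximum(condensed, 0.0)  # guard tiny negative rounding
    dist = squareform(condensed)
    return pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns)


def average_linkage_tree(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA merge sequence: inter-cluster distance is the unweighted mean
    of all cross-pair distances."""
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to build a tree")
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=Z, leaf_ids=tuple(dist.index))


def cophenetic_coefficient(tree: Dendrogram, dist: pd.DataFrame) -> float:
    """Pearson correlation between original and cophenetic (tree-implied) distances."""
    if tree.n_leaves < 3:
        raise ValueError("cophenetic correlation undefined for fewer than 3 samples")
    if tuple(dist.index) != tree.leaf_ids:
        raise ValueError("distance matrix samples do not match the tree's leaves")
    condensed = squareform(dist.to_numpy(), checks=False)
    coeff, _ = hierarchy.cophenet(tree.linkage, condensed)
    return float(coeff)


def cophenetic_distances(tree: Dendrogram) -> pd.DataFrame:
    """Square matrix of cophenetic distances (height of the lowest common merge)."""
    condensed = hierarchy.cophenet(tree.linkage)
    return pd.DataFrame(squareform(condensed), index=tree.leaf_ids, columns=tree.leaf_ids)


def cut_to_subtypes(tree: Dendrogram, k: int, dist: Optional[pd.DataFrame] = None) -> SubtypeAssignment:
    """Cut the dendrogram into exactly k subtypes.

    Labels are renumbered 1..k in decreasing cluster size; ties broken by the
    smallest member position in the leaf order, so numbering is reproducible.
    """
    n = tree.n_leaves
    if not (2 <= k <= n):
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    raw = hierarchy.cut_tree(tree.linkage, n_clusters=k).ravel()
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series(
        [relabel[c] for c in raw], index=pd.Index(tree.leaf_ids, name="sample"), name="subtype"
    )
    coeff = cophenetic_coefficient(tree, dist) if dist is not None and n >= 3 else None
    return SubtypeAssignment(labels=labels, k=k, cophenetic_coefficient=coeff, dendrogram=tree)


def to_newick(tree: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string with merge heights as
    branch lengths (leaf branch = height of its first merge)."""
    Z = tree.linkage
    n = tree.n_leaves

    def height(node: int) -> float:
        return 0.0 if node < n else Z[node - n, 2]

    def render(node: int, parent_height: float) -> str:
        length = parent_height - height(node)
        if node < n:
            return f"{tree.leaf_ids[node]}:{length:.10g}"
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{length:.10g}"

    root = n + Z.shape[0] - 1
    h = height(root)
    left, right = int(Z[-1, 0]), int(Z[-1, 1])
    return f"({render(left, h)},{render(right, h)});"


class HierarchicalSubtyper(BaseEstimator, ClusterMixin):
    """Average-linkage subtype discovery as a scikit-learn clusterer.

    Parameters
    ----------
    n_subtypes : int, default 3
        Number of subtypes to cut the dendrogram into.
    metric : {"correlation", "euclidean"}, default "correlation"
        Inter-sample distance.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Subtype labels in 1..k, numbered by decreasing cluster size.
    assignment_ : SubtypeAssignment
        Labels plus dendrogram and cophenetic coefficient.
    linkage_ : ndarray
        scipy linkage matrix of the fitted tree.
    cophenetic_coefficient_ : float
        Pearson correlation of original vs cophenetic distances.
    """

    def __init__(self, n_subtypes: int = 3, metric: str = "correlation"):
        self.n_subtypes = n_subtypes
        self.metric = metric

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            sample_ids = list(X.index)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            sample_ids = [f"S{i:04d}" for i in range(values.shape[0])]
        if values.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x genes)")
        if not np.isfinite(values).all():
            raise ValueError("X contains non-finite values")
        expr = pd.DataFrame(values.T, columns=sample_ids)
        dist = compute_distance(expr, metric=self.metric)
        tree = average_linkage_tree(dist)
        assignment = cut_to_subtypes(tree, self.n_subtypes, dist=dist)
        self.assignment_ = assignment
        self.dendrogram_ = tree
        self.linkage_ = tree.linkage
        self.cophenetic_coefficient_ = assignment.cophenetic_coefficient
        self.labels_ = assignment.labels.to_numpy()
        return self
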