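"""Allocation of candidate genes to molecular subtypes.

Each gene is tested subtype-vs-rest with Welch's two-sample t-test (two
sided). A gene joins every subtype where p < alpha — overlapping membership,
with the single best subtype (largest |t|) flagged "primary" — and the
cross-subtype common gene set is the intersection of the per-subtype sets.
No multiple-testing correction is applied by default (raw p < 0.05 rule);
Benjamini-Hochberg is available via ``correction="fdr_bh"``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cluster import SubtypeAssignment

logger = logging.getLogger(__name__)


@dataclass
class AllocationTable:
    """Long-format per-(gene, subtype) results: t, p, mean_diff (+ flags)."""

    table: pd.DataFrame
    alpha: float = 0.05

    def for_subtype(self, subtype: int) -> pd.DataFrame:
        return self.table[self.table["subtype"] == subtype]


@dataclass
class SubtypeGeneSets:
    per_subtype: dict  # subtype -> frozenset of gene symbols
    common: frozenset

    def __post_init__(self):
        for c, genes in self.per_subtype.items():
            if not self.common <= genes:
                raise ValueError(f"common set not contained in subtype {c} set")


def _coerce_labels(assignment) -> pd.Series:
    if isinstance(assignment, SubtypeAssignment):
        return assignment.labels
    return pd.Series(assignment)


def differential_t_test(matrix: pd.DataFrame, assignment) -> AllocationTable:
    """Welch t-test of every gene, each subtype vs all remaining samples.

    Genes with zero variance in both groups and equal means get t=0, p=1
    with a logged warning (no evidence either way).
    """
    labels = _coerce_labels(assignment)
    missing = [s for s in matrix.columns if s not in labels.index]
    if missing:
        raise ValueError(f"samples without subtype label: {missing[:5]}")
    labels = labels.loc[matrix.columns]
    X = matrix.to_numpy(dtype=float)
    rows = []
    n_degenerate = 0
    for c in sorted(labels.unique()):
        mask = (labels == c).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"subtype {c} needs >=2 samples on both sides of the split")
        a, b = X[:, mask], X[:, ~mask]
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        t, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
        mean_diff = a.mean(axis=1) - b.mean(axis=1)
        degenerate = ~np.isfinite(t)
        if degenerate.any():
            n_degenerate += int(degenerate.sum())
            t[degenerate] = 0.0
            p[degenerate] = 1.0
        rows.append(
            pd.DataFrame(
                {"gene": matrix.index, "subtype": c, "t": t, "p": p, "mean_diff": mean_diff}
            )
        )
    if n_degenerate:
        logger.warning(
            "differential_t_test: %d gene/subtype pairs had zero variance in both groups; "
            "t set to 0, p to 1",
            n_degenerate,
        )
    return AllocationTable(table=pd.concat(rows, ignore_index=True))


def allocate_genes(
    table: AllocationTable, alpha: Optional[float] = None, correction: Optional[str] = None
) -> SubtypeGeneSets:
    """Apply the p < alpha membership rule and flag each gene's primary subtype.

    Adds ``allocated``/``primary`` columns to the table in place. With
    ``correction="fdr_bh"``, significance uses BH-adjusted p-values computed
    per subtype across genes.
    """
    alpha = table.alpha if alpha is None else alpha
    df = table.table
    pcol = "p"
    if correction == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        df["p_adj"] = np.nan
        for c in df["subtype"].unique():
            mask = df["subtype"] == c
            df.loc[mask, "p_adj"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
        pcol = "p_adj"
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    df["allocated"] = df[pcol] < alpha
    df["primary"] = False
    sig = df[df["allocated"]]
    if not sig.empty:
        idx = sig.assign(abs_t=sig["t"].abs()).groupby("gene")["abs_t"].idxmax()
        df.loc[idx.to_numpy(), "primary"] = True
    per_subtype = {
        int(c): frozenset(df[(df["subtype"] == c) & df["allocated"]]["gene"])
        for c in sorted(df["subtype"].unique())
    }
    return SubtypeGeneSets(per_subtype=per_subtype, common=intersect_gene_sets(per_subtype))


def intersect_gene_sets(sets) -> frozenset:
    """Exact intersection of the per-subtype gene sets."""
    if isinstance(sets, SubtypeGeneSets):
        sets = sets.per_subtype
    values = list(sets.values())
    if len(values) < 2:
        raise ValueError("need gene sets for at least 2 subtypes")
    common = frozenset(values[0])
    for s in values[1:]:
        common &= s
    return common


class SubtypeGeneAllocator(BaseEstimator):
    """Estimator wrapper: fit(X samples x genes, y subtype labels).

    Attributes: ``allocation_table_``, ``gene_sets_``, ``common_genes_``.
    """

    def __init__(self, alpha: float = 0.05, correction: Optional[str] = None):
        self.alpha = alpha
        self.correction = correction

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        labels = pd.Series(np.asarray(y), index=X.index)
        table = differential_t_test(X.T, labels)
        table.alpha = self.alpha
        self.gene_sets_ = allocate_genes(table, alpha=self.alpha, correction=self.correction)
        self.allocation_table_ = table
        self.common_genes_ = self.gene_sets_.common
        return self
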