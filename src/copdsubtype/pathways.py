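"""Pathway enrichment and the pathway deviation score.

Enrichment is one-sided (over-representation) Fisher's exact per pathway,
Benjamini-Hochberg adjusted across pathways within one query; pathways are
then partitioned into those enriched in every subtype (common) and those
enriched in exactly one (unique).

The deviation score of pathway P in subtype c is

    A(P) = (1/N) * sum_i (Xbar_i - Ybar_i)^2

over the N differential genes of the subtype that lie in P, where Xbar_i is
gene i's mean within the subtype's samples and Ybar_i its mean over all
samples. On z-scored input Ybar_i = 0, so A(P) reduces to the mean squared
subtype mean — a per-pathway measure of how far a subtype's expression
deviates from the cohort.
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .allocation import SubtypeGeneSets
from .cluster import SubtypeAssignment

logger = logging.getLogger(__name__)


def fisher_enrichment(
    query,
    pathways: Mapping,
    universe,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Over-representation test of ``query`` against every pathway.

    Pathway members are intersected with ``universe`` before testing; the
    2x2 table per pathway is (in pathway, not in pathway) x (in query, not in
    query) over the universe. Returns records sorted by p, with BH-adjusted
    p-values and an ``enriched`` flag (adjusted p < alpha by default).
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query gene set")
    outside = query - universe
    if outside:
        logger.warning("fisher_enrichment: %d query genes outside the universe dropped", len(outside))
        query &= universe
        if not query:
            raise ValueError("query has no genes in the universe")
    M, n = len(universe), len(query)
    records = []
    for pid, (desc, members) in pathways.items():
        pw = frozenset(members) & universe
        if not pw:
            logger.info("fisher_enrichment: pathway %s has no genes in the universe; skipped", pid)
            continue
        K = len(pw)
        k = len(pw & query)
        table = [[k, n - k], [K - k, M - K - (n - k)]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        records.append(
            {"pathway_id": pid, "description": desc, "k": k, "n": n, "K": K, "M": M,
             "odds_ratio": odds, "p": p}
        )
    if not records:
        raise ValueError("no pathway overlaps the universe")
    result = pd.DataFrame.from_records(records)
    result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
    result["enriched"] = (result["p_adj"] if use_adjusted else result["p"]) < alpha
    return result.sort_values("p", kind="mergesort").reset_index(drop=True)


def partition_pathways(per_subtype_records: Mapping[int, pd.DataFrame]):
    """Split enriched pathways into common (enriched in every subtype) and
    unique (enriched in exactly one)."""
    if len(per_subtype_records) < 2:
        raise ValueError("need enrichment records for at least 2 subtypes")
    enriched = {
        c: frozenset(df.loc[df["enriched"], "pathway_id"]) for c, df in per_subtype_records.items()
    }
    subtypes = sorted(enriched)
    common = frozenset.intersection(*enriched.values())
    unique = {
        c: frozenset(p for p in enriched[c] if all(p not in enriched[o] for o in subtypes if o != c))
        for c in subtypes
    }
    return common, unique


def deviation_score(
    matrix: pd.DataFrame,
    assignment,
    pathway_genes,
    subtype_genes,
    subtype: int,
) -> Optional[dict]:
    """Deviation score of one pathway in one subtype.

    Scores the N = |pathway ∩ subtype's differential genes ∩ matrix| genes;
    returns ``None`` (with a logged reason) when N = 0.
    """
    labels = assignment.labels if isinstance(assignment, SubtypeAssignment) else pd.Series(assignment)
    genes = sorted(frozenset(pathway_genes) & frozenset(subtype_genes) & frozenset(matrix.index))
    if not genes:
        logger.info("deviation_score: no usable genes for subtype %s in this pathway; skipped", subtype)
        return None
    labels = labels.loc[matrix.columns]
    in_subtype = (labels == subtype).to_numpy()
    if not in_subtype.any():
        raise ValueError(f"no samples carry subtype label {subtype}")
    sub = matrix.loc[genes]
    x_bar = sub.loc[:, in_subtype].mean(axis=1)
    y_bar = sub.mean(axis=1)
    diffs = (x_bar - y_bar).to_numpy()
    return {
        "N": len(genes),
        "A": float(np.mean(diffs**2)),
        "genes": tuple(genes),
        "subtype_means": x_bar,
        "cohort_means": y_bar,
    }


def deviation_score_table(
    matrix: pd.DataFrame,
    assignment,
    pathways: Mapping,
    gene_sets: SubtypeGeneSets,
    pathway_ids=None,
) -> pd.DataFrame:
    """Deviation scores for every (pathway, subtype) pair with N >= 1.

    Returns a long DataFrame (pathway_id, subtype, N, A).
    """
    ids = list(pathways) if pathway_ids is None else list(pathway_ids)
    rows = []
    for pid in ids:
        _, members = pathways[pid]
        for c, subtype_genes in gene_sets.per_subtype.items():
            row = deviation_score(matrix, assignment, members, subtype_genes, c)
            if row is not None:
                rows.append({"pathway_id": pid, "subtype": c, "N": row["N"], "A": row["A"]})
    return pd.DataFrame(rows, columns=["pathway_id", "subtype", "N", "A"])


def plot_deviation_profiles(table: pd.DataFrame, path) -> None:
    """Line plot of deviation scores, one line per subtype across pathways."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = table.pivot(index="pathway_id", columns="subtype", values="A").sort_index()
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(wide)), 4))
    for c in wide.columns:
        ax.plot(range(len(wide)), wide[c], marker="o", label=f"subtype {c}")
    ax.set_xticks(range(len(wide)))
    ax.set_xticklabels(wide.index, rotation=90, fontsize=7)
    ax.set_ylabel("deviation score A(P)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
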