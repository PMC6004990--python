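"""Expression preprocessing: probe collapsing, per-gene z-scoring, candidate subsetting.

The working scale of the whole pipeline is the per-gene z-score (sample SD,
n-1 denominator). Input is assumed already background-corrected and
summarized (e.g. RMA output); the fixed order of operations is
collapse -> z-score -> subset.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import validate_expression

logger = logging.getLogger(__name__)


def collapse_probes(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe x sample matrix to gene symbols by averaging probe rows.

    A probe mapping to several symbols contributes its row to each of them;
    probes absent from the annotation are dropped with a logged count.
    """
    validate_expression(matrix, context="probe matrix")
    ann = annotation.drop_duplicates(subset=["probe_id", "gene_symbol"])
    usable = ann[ann["probe_id"].isin(matrix.index)]
    if usable.empty:
        raise ValueError("no probe in the matrix appears in the annotation")
    n_unannotated = (~matrix.index.isin(set(ann["probe_id"]))).sum()
    if n_unannotated:
        logger.info("collapse_probes: dropping %d unannotated probes", n_unannotated)
    expanded = matrix.loc[usable["probe_id"].to_numpy()]
    expanded.index = usable["gene_symbol"].to_numpy()
    collapsed = expanded.groupby(level=0).mean()
    collapsed = collapsed[matrix.columns]  # conserve sample order
    collapsed.index.name = "gene"
    return collapsed


def zscore_rows(matrix: pd.DataFrame, tol: float = 0.0):
    """Z-score each gene row to mean 0, sample SD 1 (ddof=1).

    Zero-variance rows are dropped and listed in the returned report, a
    DataFrame with columns (gene, mean, sd, dropped).
    """
    validate_expression(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    dropped = sds <= tol
    report = pd.DataFrame(
        {"gene": matrix.index, "mean": means.values, "sd": sds.values, "dropped": dropped.values}
    ).reset_index(drop=True)
    if dropped.all():
        raise ValueError("every row has zero variance; nothing to normalize")
    if dropped.any():
        logger.info("zscore_rows: dropping %d zero-variance genes", int(dropped.sum()))
    kept = matrix.loc[~dropped]
    z = kept.sub(means[~dropped], axis=0).div(sds[~dropped], axis=0)
    return z, report


def subset_to_candidates(matrix: pd.DataFrame, candidates) -> pd.DataFrame:
    """Restrict rows to the candidate genes present in the matrix (their order)."""
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise ValueError("empty candidate gene list")
    present = [g for g in candidates if g in matrix.index]
    missing = len(candidates) - len(present)
    if missing:
        logger.warning("subset_to_candidates: %d candidate genes absent from the matrix", missing)
    if len(present) < 2:
        raise ValueError(
            f"only {len(present)} candidate genes found in the matrix; need at least 2"
        )
    return matrix.loc[present]
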