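"""Association of clinical indicators with molecular subtypes.

Continuous indicators (FEV1, FEV1/FVC, age) are compared across subtypes by
one-way fixed-effects ANOVA; sex by a chi-square test of independence on the
k x 2 subtype-by-sex table (no continuity correction). ANOVA on a 0/1 coding
of sex is available behind ``method="anova"`` for strict replication of
pipelines that treated sex that way. Missing values are dropped per variable
with logged counts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import SubtypeAssignment

logger = logging.getLogger(__name__)

CONTINUOUS_VARIABLES = ("FEV1", "FEV1_FVC", "age")


@dataclass
class AssociationResult:
    variable: str
    test: str
    statistic: float
    pvalue: float
    summary: pd.DataFrame  # per-subtype mean/sd/n (continuous) or counts (categorical)
    expected: pd.DataFrame | None = None  # chi-square expected counts

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _aligned(clinical: pd.DataFrame, assignment) -> pd.Series:
    labels = assignment.labels if isinstance(assignment, SubtypeAssignment) else pd.Series(assignment)
    missing = [s for s in clinical.index if s not in labels.index]
    if missing:
        raise ValueError(f"clinical samples without subtype label: {missing[:5]}")
    return labels.loc[clinical.index]


def continuous_association(
    clinical: pd.DataFrame, assignment, variable: str
) -> AssociationResult:
    """One-way ANOVA of a continuous clinical variable across subtypes."""
    if variable not in clinical.columns:
        raise ValueError(f"clinical table has no column {variable!r}")
    labels = _aligned(clinical, assignment)
    values = pd.to_numeric(clinical[variable], errors="raise")
    keep = values.notna()
    n_missing = int((~keep).sum())
    if n_missing:
        logger.info("continuous_association(%s): dropping %d missing values", variable, n_missing)
    values, labels = values[keep], labels[keep]
    groups = []
    summary_rows = []
    for c in sorted(labels.unique()):
        g = values[labels == c].to_numpy()
        if len(g) < 2:
            raise ValueError(f"subtype {c} has fewer than 2 non-missing values for {variable}")
        groups.append(g)
        summary_rows.append({"subtype": c, "n": len(g), "mean": g.mean(), "sd": g.std(ddof=1)})
    f, p = stats.f_oneway(*groups)
    return AssociationResult(
        variable=variable,
        test="one-way ANOVA",
        statistic=float(f),
        pvalue=float(p),
        summary=pd.DataFrame(summary_rows),
    )


def categorical_association(
    clinical: pd.DataFrame, assignment, variable: str = "sex", method: str = "chi2"
) -> AssociationResult:
    """Subtype-by-category independence test (chi-square, no continuity correction)."""
    if variable not in clinical.columns:
        raise ValueError(f"clinical table has no column {variable!r}")
    labels = _aligned(clinical, assignment)
    values = clinical[variable]
    keep = values.notna()
    n_missing = int((~keep).sum())
    if n_missing:
        logger.info("categorical_association(%s): dropping %d missing values", variable, n_missing)
    values, labels = values[keep], labels[keep]
    counts = pd.crosstab(labels, values)
    if (
        counts.shape[0] < 2
        or counts.shape[1] < 2
        or (counts.sum(axis=0) == 0).any()
        or (counts.sum(axis=1) == 0).any()
    ):
        raise ValueError(
            "a subtype or category has zero total; merge categories before testing"
        )
    if method == "chi2":
        chi2, p, _, expected = stats.chi2_contingency(counts.to_numpy(), correction=False)
        return AssociationResult(
            variable=variable,
            test="chi-square independence",
            statistic=float(chi2),
            pvalue=float(p),
            summary=counts,
            expected=pd.DataFrame(expected, index=counts.index, columns=counts.columns),
        )
    if method == "anova":
        if counts.shape[1] != 2:
            raise ValueError("ANOVA coding requires a binary category")
        binary = (values == counts.columns[1]).astype(float)
        groups = [binary[labels == c].to_numpy() for c in sorted(labels.unique())]
        f, p = stats.f_oneway(*groups)
        return AssociationResult(
            variable=variable,
            test="one-way ANOVA on 0/1 coding",
            statistic=float(f),
            pvalue=float(p),
            summary=counts,
        )
    raise ValueError(f"unknown method {method!r}")


def association_report(clinical: pd.DataFrame, assignment) -> pd.DataFrame:
    """All standard clinical associations as one tidy table."""
    results = [
        continuous_association(clinical, assignment, v)
        for v in CONTINUOUS_VARIABLES
        if v in clinical.columns
    ]
    if "sex" in clinical.columns:
        results.append(categorical_association(clinical, assignment, "sex"))
    return pd.DataFrame(
        [{"variable": r.variable, "test": r.test, "statistic": r.statistic, "p": r.pvalue}
         for r in results]
    )
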