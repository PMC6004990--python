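"""Readers and writers for the pipeline's file formats.

Expression matrices travel as TSV/CSV with genes in rows and a header row of
sample ids; gene sets as GMT; clinical covariates as TSV; candidate genes as a
plain text list. Parsers validate strictly and never silently drop records —
every skip is logged with a reason. Gene symbols are matched case-sensitively
throughout.
"""
from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SEX_NORMALIZATION = {
    "male": "male",
    "m": "male",
    "female": "female",
    "f": "female",
}

CLINICAL_COLUMNS = ("FEV1", "FEV1_FVC", "age", "sex")
# accepted header aliases, matched after lowercasing and stripping
_CLINICAL_ALIASES = {
    "fev1": "FEV1",
    "fev1_fvc": "FEV1_FVC",
    "fev1/fvc": "FEV1_FVC",
    "fev1fvc": "FEV1_FVC",
    "age": "age",
    "sex": "sex",
    "gender": "sex",
}


def _detect_sep(path: Path, dialect: Optional[str]) -> str:
    if dialect == "tab":
        return "\t"
    if dialect == "comma":
        return ","
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tab' or 'comma'")
    if str(path).endswith(".csv"):
        return ","
    with open(path) as fh:
        first = fh.readline()
    return "," if ("," in first and "\t" not in first) else "\t"


def validate_expression(matrix: pd.DataFrame, context: str = "expression matrix") -> pd.DataFrame:
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()[:5]
        raise ValueError(
            f"{context}: duplicate row ids {dups}; if these are probes mapping to one "
            "gene, collapse them first with preprocess.collapse_probes"
        )
    if matrix.columns.duplicated().any():
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{context}: duplicate sample ids {dups}")
    return matrix


def read_expression_table(path, dialect: Optional[str] = None) -> pd.DataFrame:
    """Read a gene x sample table (first column = gene/probe ids, header = sample ids)."""
    path = Path(path)
    sep = _detect_sep(path, dialect)
    with open(path) as fh:
        header = next(csv.reader(fh, delimiter=sep))
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        seen, dups = set(), []
        for s in sample_ids:
            if s in seen:
                dups.append(s)
            seen.add(s)
        raise ValueError(f"{path}: duplicate sample ids in header: {sorted(set(dups))[:5]}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.columns = sample_ids
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        original = raw[col]
        bad = converted.isna() & ~original.isna() & (original.str.strip().str.lower() != "nan")
        if bad.any():
            row = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric value {original[bad].iloc[0]!r} at row {row!r}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    matrix = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    matrix.index.name = raw.index.name or "gene"
    return validate_expression(matrix, context=str(path))


def write_expression_table(matrix: pd.DataFrame, path, float_format: str = "%.17g") -> None:
    validate_expression(matrix)
    matrix.to_csv(path, sep="\t", float_format=float_format)


def read_gmt(path) -> dict:
    """Read a GMT file into ``{pathway_id: (description, frozenset(members))}``.

    Duplicate members within a line are deduplicated with a logged warning;
    a line with fewer than three fields is a parse error.
    """
    collection: dict = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member "
                    f"(got {len(fields)} fields)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = frozenset(members)
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: %d duplicate members in set %s deduplicated",
                    path, lineno, len(members) - len(unique), name,
                )
            if name in collection:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {name!r}")
            collection[name] = (desc, unique)
    if not collection:
        logger.warning("%s: empty GMT file, returning empty collection", path)
    return collection


def write_gmt(collection: Mapping, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_clinical_table(path) -> pd.DataFrame:
    """Read the per-sample clinical table (FEV1, FEV1/FVC, age, sex).

    The first column holds sample ids. Sex tokens are normalized
    case-insensitively to {male, female}; extra columns are preserved.
    """
    path = Path(path)
    sep = _detect_sep(path, None)
    table = pd.read_csv(path, sep=sep, index_col=0)
    rename = {}
    for col in table.columns:
        alias = _CLINICAL_ALIASES.get(str(col).strip().lower())
        if alias and alias not in rename.values():
            rename[col] = alias
    table = table.rename(columns=rename)
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory clinical columns {missing}")
    if table.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    sex = table["sex"].astype(str).str.strip().str.lower().map(_SEX_NORMALIZATION)
    bad = table["sex"].notna() & sex.isna()
    if bad.any():
        raise ValueError(
            f"{path}: unknown sex token {table.loc[bad, 'sex'].iloc[0]!r}; "
            "expected one of male/m/female/f"
        )
    table["sex"] = sex
    for col in ("FEV1", "FEV1_FVC", "age"):
        table[col] = pd.to_numeric(table[col], errors="raise")
    if (table["FEV1_FVC"].dropna() < 0).any():
        raise ValueError(f"{path}: FEV1_FVC must be nonnegative")
    if (table["age"].dropna() < 0).any():
        raise ValueError(f"{path}: age must be nonnegative")
    table.index.name = "sample"
    return table


def write_clinical_table(table: pd.DataFrame, path, float_format: str = "%.12g") -> None:
    table.to_csv(path, sep="\t", float_format=float_format)


def read_gene_list(path) -> list:
    """Read a plain-text gene list: one symbol per line, '#' starts a comment."""
    genes = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            symbol = line.split("#", 1)[0].strip()
            if not symbol:
                continue
            if symbol in seen:
                logger.warning("%s: duplicate gene symbol %s skipped", path, symbol)
                continue
            seen.add(symbol)
            genes.append(symbol)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_probe_annotation(path) -> pd.DataFrame:
    """Read a probe -> gene symbol mapping (TSV/CSV, columns probe_id, gene_symbol)."""
    path = Path(path)
    sep = _detect_sep(path, None)
    ann = pd.read_csv(path, sep=sep, dtype=str)
    cols = {str(c).strip().lower(): c for c in ann.columns}
    try:
        ann = ann.rename(columns={cols["probe_id"]: "probe_id", cols["gene_symbol"]: "gene_symbol"})
    except KeyError as exc:
        raise ValueError(f"{path}: annotation needs probe_id and gene_symbol columns") from exc
    ann = ann[["probe_id", "gene_symbol"]].dropna()
    n_dup = ann.duplicated().sum()
    if n_dup:
        logger.warning("%s: %d fully duplicated (probe, gene) pairs dropped", path, n_dup)
        ann = ann.drop_duplicates()
    return ann.reset_index(drop=True)
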