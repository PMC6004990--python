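"""End-to-end orchestration of the subtyping analysis.

``run_pipeline`` executes preprocess -> subtype -> allocate -> enrich+deviate
-> clinical -> train/CV -> (optional) cross-cohort validation from one
declarative config, writes every artifact as TSV/JSON under the output
directory, and records a manifest with per-stage checksums. Reruns with the
same config and seed produce byte-identical TSVs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import allocation as alloc_mod
from . import classify as classify_mod
from . import clinical as clinical_mod
from . import cluster as cluster_mod
from . import io as io_mod
from . import pathways as pathways_mod
from . import preprocess as pre_mod
from . import validate as validate_mod

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.12g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    expression: Path
    candidates: Path
    gmt: Path
    clinical: Optional[Path] = None
    annotation: Optional[Path] = None
    validation_expression: Optional[Path] = None
    output_dir: Path = Path("results")
    metric: str = "correlation"
    k: int = 3
    alpha: float = 0.05
    enrichment_alpha: float = 0.05
    enrichment_adjusted: bool = True
    C: float = 1.0
    folds: int = 5
    n_permutations: int = 10000
    seed: int = 0
    run_clinical: bool = True
    run_train: bool = True
    run_validation: bool = True
    plots: bool = False

    def __post_init__(self):
        for name in ("expression", "candidates", "gmt", "clinical", "annotation",
                     "validation_expression", "output_dir"):
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(self, name, Path(value))
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        for name in ("expression", "candidates", "gmt"):
            if not getattr(self, name).exists():
                raise FileNotFoundError(f"{name} file not found: {getattr(self, name)}")
        for name in ("clinical", "annotation", "validation_expression"):
            value = getattr(self, name)
            if value is not None and not value.exists():
                raise FileNotFoundError(f"{name} file not found: {value}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    def snapshot(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in out.items()}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT, index=index)
    return path


def preprocess_stage(expression: pd.DataFrame, candidates, annotation=None):
    """collapse (optional) -> z-score -> candidate subset."""
    if annotation is not None:
        expression = pre_mod.collapse_probes(expression, annotation)
    z, report = pre_mod.zscore_rows(expression)
    candidate_matrix = pre_mod.subset_to_candidates(z, candidates)
    return z, candidate_matrix, report


def subtype_stage(candidate_matrix: pd.DataFrame, k: int, metric: str):
    dist = cluster_mod.compute_distance(candidate_matrix, metric=metric)
    tree = cluster_mod.average_linkage_tree(dist)
    return cluster_mod.cut_to_subtypes(tree, k, dist=dist)


def feature_gene_lists(pathway_collection, gene_sets, matrix_genes, pathway_ids):
    """Per-pathway gene lists for featurization: pathway ∩ allocated genes,
    falling back to pathway ∩ matrix genes for pathways with no allocated gene."""
    allocated = frozenset().union(*gene_sets.per_subtype.values()) if gene_sets.per_subtype else frozenset()
    matrix_genes = frozenset(matrix_genes)
    lists = {}
    for pid in pathway_ids:
        members = frozenset(pathway_collection[pid][1])
        genes = members & allocated & matrix_genes
        if not genes:
            genes = members & matrix_genes
        if genes:
            lists[pid] = tuple(sorted(genes))
    return lists


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.snapshot(), "version": __version__, "stages": []}
    state: dict = {}

    stages = [
        ("preprocess", _stage_preprocess),
        ("subtype", _stage_subtype),
        ("allocate", _stage_allocate),
        ("enrich", _stage_enrich),
        ("deviate", _stage_deviate),
    ]
    if config.run_clinical and config.clinical is not None:
        stages.append(("clinical", _stage_clinical))
    if config.run_train:
        stages.append(("train", _stage_train))
    if config.run_validation and config.validation_expression is not None:
        stages.append(("validate", _stage_validate))

    for name, fn in stages:
        start = time.perf_counter()
        try:
            outputs = fn(config, state, outdir)
        except Exception as exc:  # abort with stage name, keep partial outputs
            (outdir / "FAILED").write_text(f"{name}: {exc}\n")
            raise PipelineError(name, exc) from exc
        manifest["stages"].append(
            {
                "name": name,
                "outputs": {str(p.name): _sha256(p) for p in outputs},
                "seconds": round(time.perf_counter() - start, 3),
            }
        )
        logger.info("stage %s done (%d outputs)", name, len(outputs))

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _stage_preprocess(config, state, outdir):
    expression = io_mod.read_expression_table(config.expression)
    candidates = io_mod.read_gene_list(config.candidates)
    annotation = (
        io_mod.read_probe_annotation(config.annotation) if config.annotation is not None else None
    )
    z, candidate_matrix, report = preprocess_stage(expression, candidates, annotation)
    state.update(z=z, candidate_matrix=candidate_matrix, candidates=candidates)
    return [
        _write_tsv(candidate_matrix, outdir / "candidate_matrix.tsv"),
        _write_tsv(report, outdir / "normalization_report.tsv", index=False),
    ]


def _stage_subtype(config, state, outdir):
    assignment = subtype_stage(state["candidate_matrix"], config.k, config.metric)
    state["assignment"] = assignment
    (outdir / "dendrogram.nwk").write_text(cluster_mod.to_newick(assignment.dendrogram) + "\n")
    summary = pd.DataFrame(
        {
            "subtype": assignment.counts().index,
            "n_samples": assignment.counts().values,
            "cophenetic_coefficient": assignment.cophenetic_coefficient,
        }
    )
    return [
        _write_tsv(assignment.labels.to_frame(), outdir / "subtypes.tsv"),
        _write_tsv(summary, outdir / "subtype_summary.tsv", index=False),
        outdir / "dendrogram.nwk",
    ]


def _stage_allocate(config, state, outdir):
    table = alloc_mod.differential_t_test(state["candidate_matrix"], state["assignment"])
    table.alpha = config.alpha
    gene_sets = alloc_mod.allocate_genes(table, alpha=config.alpha)
    state.update(allocation=table, gene_sets=gene_sets)
    sets_df = pd.DataFrame(
        [
            {"subtype": c, "n_genes": len(genes), "genes": ",".join(sorted(genes))}
            for c, genes in gene_sets.per_subtype.items()
        ]
        + [{"subtype": "common", "n_genes": len(gene_sets.common),
            "genes": ",".join(sorted(gene_sets.common))}]
    )
    return [
        _write_tsv(table.table, outdir / "allocation_table.tsv", index=False),
        _write_tsv(sets_df, outdir / "subtype_gene_sets.tsv", index=False),
    ]


def _stage_enrich(config, state, outdir):
    pathway_collection = io_mod.read_gmt(config.gmt)
    pathway_genes = frozenset().union(*(m for _, m in pathway_collection.values()))
    universe = frozenset(state["z"].index) & pathway_genes
    records = {}
    frames = []
    for c, genes in state["gene_sets"].per_subtype.items():
        query = frozenset(genes) & universe
        if not query:
            logger.warning("enrich: subtype %s has no allocated genes in the universe", c)
            continue
        df = pathways_mod.fisher_enrichment(
            query, pathway_collection, universe,
            alpha=config.enrichment_alpha, use_adjusted=config.enrichment_adjusted,
        )
        records[c] = df
        frames.append(df.assign(subtype=c))
    if len(records) >= 2:
        common, unique = pathways_mod.partition_pathways(records)
    else:
        common, unique = frozenset(), {}
    state.update(pathway_collection=pathway_collection, enrichment=records,
                 common_pathways=common, unique_pathways=unique)
    partition = pd.DataFrame(
        [{"pathway_id": p, "status": "common", "subtype": ""} for p in sorted(common)]
        + [
            {"pathway_id": p, "status": "unique", "subtype": c}
            for c, ps in unique.items()
            for p in sorted(ps)
        ]
    )
    outputs = [
        _write_tsv(pd.concat(frames, ignore_index=True), outdir / "enrichment.tsv", index=False),
        _write_tsv(partition, outdir / "pathway_partition.tsv", index=False),
    ]
    return outputs


def _stage_deviate(config, state, outdir):
    table = pathways_mod.deviation_score_table(
        state["candidate_matrix"],
        state["assignment"],
        state["pathway_collection"],
        state["gene_sets"],
        pathway_ids=sorted(state["common_pathways"]) or None,
    )
    state["deviation"] = table
    outputs = [_write_tsv(table, outdir / "deviation_scores.tsv", index=False)]
    if config.plots and not table.empty:
        plot = outdir / "deviation_profiles.png"
        pathways_mod.plot_deviation_profiles(table, plot)
        outputs.append(plot)
    return outputs


def _stage_clinical(config, state, outdir):
    clinical = io_mod.read_clinical_table(config.clinical)
    shared = [s for s in state["assignment"].labels.index if s in clinical.index]
    report = clinical_mod.association_report(clinical.loc[shared], state["assignment"])
    state["clinical_report"] = report
    return [_write_tsv(report, outdir / "clinical_associations.tsv", index=False)]


def _select_feature_pathways(state) -> list:
    """Features come from the common pathways; fall back to any enriched
    pathway, then to all pathways, logging the choice."""
    if state["common_pathways"]:
        return sorted(state["common_pathways"])
    enriched = frozenset().union(
        *(frozenset(df.loc[df["enriched"], "pathway_id"]) for df in state["enrichment"].values())
    ) if state["enrichment"] else frozenset()
    if enriched:
        logger.warning("train: no common pathways; using the union of enriched pathways")
        return sorted(enriched)
    logger.warning("train: no enriched pathways; using every pathway as a feature")
    return sorted(state["pathway_collection"])


def _stage_train(config, state, outdir):
    z = state["z"]
    if config.validation_expression is not None and config.run_validation:
        # share the feature gene universe with the validation cohort up front
        validation = io_mod.read_expression_table(config.validation_expression)
        z, val_z = validate_mod.harmonize_features(z, validation)
        state["validation_z"] = val_z
        state["z_harmonized"] = z
    pathway_ids = _select_feature_pathways(state)
    lists = feature_gene_lists(state["pathway_collection"], state["gene_sets"], z.index, pathway_ids)
    if not lists:
        raise ValueError("no pathway retained usable feature genes")
    featurizer = classify_mod.PathwayDeviationFeaturizer(lists)
    features = featurizer.fit(z.T).transform(z.T)
    labels = state["assignment"].labels
    model = classify_mod.train_classifier(features, labels, C=config.C)
    cv = classify_mod.cross_validate_roc(
        features, labels, folds=config.folds, seed=config.seed, C=config.C
    )
    state.update(featurizer=featurizer, features=features, model=model, cv=cv)
    model_path = outdir / "svm_model.json"
    model.save(model_path)
    cv_summary = pd.DataFrame(
        {
            "subtype": list(cv.auc),
            "auc": [cv.auc[c] for c in cv.auc],
            "cv_accuracy": [cv.accuracy[c] for c in cv.auc],
        }
    )
    outputs = [model_path, _write_tsv(cv_summary, outdir / "cv_summary.tsv", index=False)]
    for c, (fpr, tpr) in cv.roc.items():
        roc_df = pd.DataFrame({"fpr": fpr, "tpr": tpr})
        outputs.append(_write_tsv(roc_df, outdir / f"roc_subtype{c}.tsv", index=False))
    return outputs


def _stage_validate(config, state, outdir):
    if "validation_z" not in state:
        validation = io_mod.read_expression_table(config.validation_expression)
        _, state["validation_z"] = validate_mod.harmonize_features(state["z"], validation)
    val_z = state["validation_z"]
    val_candidates = pre_mod.subset_to_candidates(val_z, state["candidates"])
    val_assignment = subtype_stage(val_candidates, config.k, config.metric)

    featurizer = state["featurizer"]
    val_features = featurizer.transform(val_z.T)
    predicted = classify_mod.predict_labels(state["model"], val_features)

    aligned_clusters = validate_mod.align_cluster_labels(val_assignment.labels, predicted)
    cm = validate_mod.build_confusion_matrix(aligned_clusters, predicted, align=False)
    ratios = validate_mod.consistency_ratios(cm)
    perm = validate_mod.permutation_significance(
        aligned_clusters, predicted, n_permutations=config.n_permutations, seed=config.seed
    )
    state.update(validation_assignment=val_assignment, validation_predicted=predicted,
                 confusion=cm, ratios=ratios, permutation=perm)
    perm_df = pd.DataFrame(
        {
            "class": perm.pvalues.index,
            "observed_ratio": perm.observed.values,
            "p": perm.pvalues.values,
            "n_permutations": perm.n_permutations,
        }
    )
    confusion_path = outdir / "confusion_matrix.tsv"
    validate_mod.write_confusion_tsv(cm, confusion_path)
    return [
        _write_tsv(val_assignment.labels.to_frame(), outdir / "validation_clusters.tsv"),
        _write_tsv(predicted.to_frame(), outdir / "validation_predictions.tsv"),
        confusion_path,
        _write_tsv(perm_df, outdir / "permutation_test.tsv", index=False),
    ]
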