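"""Per-sample pathway-deviation features and one-vs-rest linear SVM subtype models.

A sample s gets one feature per pathway P,

    d_s(P) = (1/N) * sum_i (x_{is} - Ybar_i)^2,

the sample-level analog of the subtype deviation score, with the reference
means Ybar_i taken from the training cohort (near zero on z-scored data).
Note the subtype average of d_s(P) does not generally equal the subtype
score A(P): A(P) squares the mean while d averages squares (Jensen gap).

Subtype predictors are soft-margin linear SVMs (C = 1 by default), one per
subtype against the rest; multi-class prediction is the argmax of the
per-subtype decision scores with ties broken toward the lower-numbered
subtype. Performance is measured by stratified 5-fold cross-validation with
out-of-fold decision scores pooled into one ROC per subtype.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

_MODEL_FORMAT_VERSION = 1


class PathwayDeviationFeaturizer(BaseEstimator, TransformerMixin):
    """Transform samples x genes expression into samples x pathways deviation features.

    Parameters
    ----------
    pathway_gene_lists : mapping pathway_id -> iterable of gene symbols
        Gene list per feature column (typically pathway ∩ allocated genes).
    reference_means : Series (gene -> mean), optional
        Reference expression per gene. Learned from the training cohort's
        column means when not supplied, and stored for reuse on new cohorts.
    """

    def __init__(self, pathway_gene_lists=None, reference_means=None):
        self.pathway_gene_lists = pathway_gene_lists
        self.reference_means = reference_means

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))

    def fit(self, X, y=None):
        if not self.pathway_gene_lists:
            raise ValueError("pathway_gene_lists must be a nonempty mapping")
        X = self._as_frame(X)
        genes = X.columns
        if self.reference_means is None:
            self.reference_means_ = X.mean(axis=0)
        else:
            self.reference_means_ = pd.Series(self.reference_means).reindex(genes)
            if self.reference_means_.isna().any():
                missing = genes[self.reference_means_.isna()].tolist()[:5]
                raise ValueError(f"reference_means missing genes {missing}")
        self.gene_lists_ = {}
        for pid, members in self.pathway_gene_lists.items():
            usable = [g for g in dict.fromkeys(members) if g in set(genes)]
            if not usable:
                logger.warning(
                    "PathwayDeviationFeaturizer: pathway %s has no usable genes; column skipped", pid
                )
                continue
            self.gene_lists_[pid] = tuple(usable)
        if not self.gene_lists_:
            raise ValueError("no pathway retained any usable gene")
        self.feature_names_out_ = tuple(self.gene_lists_)
        return self

    def transform(self, X) -> pd.DataFrame:
        X = self._as_frame(X)
        centered = X.sub(self.reference_means_.reindex(X.columns), axis=1)
        if centered.isna().any().any():
            raise ValueError("X lacks genes required by the fitted feature schema")
        sq = centered**2
        features = {
            pid: sq[list(genes)].mean(axis=1) for pid, genes in self.gene_lists_.items()
        }
        return pd.DataFrame(features, index=X.index)


def sample_deviation_features(
    matrix: pd.DataFrame, pathway_gene_lists: Mapping, reference_means=None
) -> pd.DataFrame:
    """Functional form over a genes x samples matrix; returns samples x pathways."""
    feat = PathwayDeviationFeaturizer(pathway_gene_lists, reference_means)
    Xt = matrix.T
    return feat.fit(Xt).transform(Xt)


class SubtypeClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-rest linear SVM over pathway-deviation features.

    Attributes after fit: ``classes_``, ``coef_`` (k x p), ``intercept_``,
    ``feature_names_``. Decision scores are w_c . x + b_c per subtype;
    ``predict`` takes the argmax (ties to the lower-numbered subtype).
    """

    def __init__(self, C: float = 1.0, class_weight=None):
        self.C = C
        self.class_weight = class_weight

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = tuple(X.columns)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            self.feature_names_ = tuple(range(values.shape[1]))
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to train")
        counts = pd.Series(y).value_counts()
        if (counts < 2).any():
            raise ValueError("every class needs at least 2 samples")
        self.classes_ = classes
        coefs, intercepts = [], []
        for c in classes:
            svc = SVC(kernel="linear", C=self.C, class_weight=self.class_weight)
            svc.fit(values, (y == c).astype(int))
            coefs.append(svc.coef_[0])
            intercepts.append(svc.intercept_[0])
        self.coef_ = np.vstack(coefs)
        self.intercept_ = np.asarray(intercepts)
        return self

    def _values(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names_ if f not in X.columns]
            if missing:
                raise ValueError(f"feature schema mismatch; missing pathways: {missing}")
            return X[list(self.feature_names_)].to_numpy(dtype=float)
        values = np.asarray(X, dtype=float)
        if values.shape[1] != self.coef_.shape[1]:
            raise ValueError(
                f"expected {self.coef_.shape[1]} features, got {values.shape[1]}"
            )
        return values

    def decision_function(self, X) -> np.ndarray:
        return self._values(X) @ self.coef_.T + self.intercept_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]  # argmax: first max -> lower label

    def with_control_class(self, features: pd.DataFrame, control_samples, label: int = 0):
        """Return a copy extended with a control-vs-rest SVM.

        A model trained on a disease-only discovery cohort has no control
        class; this refits one binary SVM on an external cohort's features
        using a supplied list of known control samples, and appends its
        decision scores as an extra class.
        """
        control_samples = [s for s in control_samples if s in features.index]
        if len(control_samples) < 2:
            raise ValueError("need at least 2 known control samples")
        if label in self.classes_:
            raise ValueError(f"class label {label} already present in the model")
        values = self._values(features)
        y = features.index.isin(control_samples).astype(int)
        svc = SVC(kernel="linear", C=self.C, class_weight=self.class_weight)
        svc.fit(values, y)
        extended = SubtypeClassifier(C=self.C, class_weight=self.class_weight)
        extended.feature_names_ = self.feature_names_
        extended.classes_ = np.concatenate([[label], self.classes_])
        extended.coef_ = np.vstack([svc.coef_[0], self.coef_])
        extended.intercept_ = np.concatenate([svc.intercept_, self.intercept_])
        order = np.argsort(extended.classes_)
        extended.classes_ = extended.classes_[order]
        extended.coef_ = extended.coef_[order]
        extended.intercept_ = extended.intercept_[order]
        return extended

    def to_dict(self) -> dict:
        return {
            "format_version": _MODEL_FORMAT_VERSION,
            "C": self.C,
            "classes": [int(c) for c in self.classes_],
            "feature_names": [str(f) for f in self.feature_names_],
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, payload: dict) -> "SubtypeClassifier":
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        model = cls(C=payload["C"])
        model.classes_ = np.asarray(payload["classes"])
        model.feature_names_ = tuple(payload["feature_names"])
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        model.intercept_ = np.asarray(payload["intercept"], dtype=float)
        return model

    @classmethod
    def load(cls, path) -> "SubtypeClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_classifier(features: pd.DataFrame, labels, C: float = 1.0) -> SubtypeClassifier:
    """Fit one-vs-rest linear SVMs on a samples x pathways feature table."""
    labels = labels.labels if hasattr(labels, "labels") else pd.Series(labels)
    y = labels.loc[features.index].to_numpy()
    return SubtypeClassifier(C=C).fit(features, y)


@dataclass
class CvResult:
    """Per-subtype pooled-ROC cross-validation results."""

    roc: dict  # subtype -> (fpr, tpr)
    auc: dict  # subtype -> float
    accuracy: dict  # subtype -> mean binary accuracy of the one-vs-rest model
    overall_accuracy: float
    fold_assignment: pd.Series
    seed: int
    scores: pd.DataFrame = field(repr=False, default=None)  # pooled OOF decision scores


def cross_validate_roc(
    features: pd.DataFrame, labels, folds: int = 5, seed: int = 0, C: float = 1.0
) -> CvResult:
    """Stratified k-fold CV; out-of-fold decision scores pooled per subtype."""
    labels = labels.labels if hasattr(labels, "labels") else pd.Series(labels)
    y = labels.loc[features.index].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smallest class size ({counts.min()})"
        )
    X = features.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.full((len(y), len(classes)), np.nan)
    fold_of = np.empty(len(y), dtype=int)
    for fold, (train, test) in enumerate(skf.split(X, y)):
        model = SubtypeClassifier(C=C).fit(X[train], y[train])
        scores[test] = model.decision_function(X[test])[:, _index_of(model.classes_, classes)]
        fold_of[test] = fold
    roc, aucs, accs = {}, {}, {}
    for j, c in enumerate(classes):
        positive = (y == c).astype(int)
        fpr, tpr, _ = roc_curve(positive, scores[:, j])
        roc[int(c)] = (fpr, tpr)
        aucs[int(c)] = float(auc(fpr, tpr))
        accs[int(c)] = float(np.mean((scores[:, j] > 0).astype(int) == positive))
    predicted = classes[np.argmax(scores, axis=1)]
    return CvResult(
        roc=roc,
        auc=aucs,
        accuracy=accs,
        overall_accuracy=float(np.mean(predicted == y)),
        fold_assignment=pd.Series(fold_of, index=features.index, name="fold"),
        seed=seed,
        scores=pd.DataFrame(scores, index=features.index, columns=classes),
    )


def _index_of(model_classes: np.ndarray, classes: np.ndarray) -> np.ndarray:
    pos = {c: i for i, c in enumerate(model_classes)}
    return np.asarray([pos[c] for c in classes])


def predict_labels(model: SubtypeClassifier, features: pd.DataFrame) -> pd.Series:
    """Apply a trained model; label = argmax decision score, ties logged."""
    scores = model.decision_function(features)
    best = np.max(scores, axis=1, keepdims=True)
    n_ties = int((np.sum(scores == best, axis=1) > 1).sum())
    if n_ties:
        logger.info("predict_labels: %d samples had tied scores; lower-numbered subtype used", n_ties)
    labels = model.classes_[np.argmax(scores, axis=1)]
    return pd.Series(labels, index=features.index, name="predicted_subtype")
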