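"""Pathway-deviation features and one-vs-rest SVM subtype models."""
import numpy as np
import pandas as pd
import pytest

from copdsubtype import classify as cf

from _oracles import mann_whitney_auc


def _separable_toy():
    X = pd.DataFrame(
        {"f1": [0.0, 0.1, 1.0, 1.1], "f2": [0.0, 0.1, 1.0, 0.9]},
        index=[f"S{i}" for i in range(4)],
    )
    y = pd.Series([1, 1, 2, 2], index=X.index)
    return X, y


class TestPathwayDeviationFeaturizer:
    def test_sample_at_reference_scores_zero(self):
        genes = ["g1", "g2", "g3"]
        X = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], columns=genes, index=["a", "b"])
        ref = pd.Series([1.0, 2.0, 3.0], index=genes)
        feats = cf.PathwayDeviationFeaturizer({"P": genes}, reference_means=ref).fit(X).transform(X)
        assert feats.loc["a", "P"] == pytest.approx(0.0)

    def test_single_gene_arithmetic(self):
        X = pd.DataFrame({"g": [2.0]}, index=["a"])
        ref = pd.Series({"g": 0.0})
        feats = cf.PathwayDeviationFeaturizer({"P": ["g"]}, reference_means=ref).fit(X).transform(X)
        assert feats.loc["a", "P"] == pytest.approx(4.0)  # (2-0)^2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(15)]
        X = pd.DataFrame(rng.normal(size=(8, 15)), columns=genes)
        lists = {
            f"P{j}": list(rng.choice(genes, rng.integers(2, 8), replace=False)) for j in range(4)
        }
        feat = cf.PathwayDeviationFeaturizer(lists).fit(X)
        out = feat.transform(X)
        ref = X.mean(axis=0)
        for pid, members in feat.gene_lists_.items():
            for s in X.index:
                expected = np.mean([(X.at[s, g] - ref[g]) ** 2 for g in members])
                assert out.at[s, pid] == pytest.approx(expected, abs=1e-12)

    def test_unusable_pathway_skipped_with_warning(self, caplog):
        X = pd.DataFrame({"g": [1.0, 2.0]})
        with caplog.at_level("WARNING"):
            feat = cf.PathwayDeviationFeaturizer({"ok": ["g"], "empty": ["nope"]}).fit(X)
        assert feat.feature_names_out_ == ("ok",)
        assert "skipped" in caplog.text

    def test_all_features_nonnegative(self, high_sep_cohort):
        expr, _, truth = high_sep_cohort
        lists = {"P1": list(truth.candidate_genes[:10]), "P2": list(truth.candidate_genes[10:25])}
        feats = cf.sample_deviation_features(expr, lists)
        assert (feats.to_numpy() >= 0).all()
        assert list(feats.index) == list(expr.columns)


class TestSubtypeClassifier:
    def test_separable_toy_training_accuracy(self):
        X, y = _separable_toy()
        model = cf.SubtypeClassifier().fit(X, y)
        assert (model.predict(X) == y.to_numpy()).all()

    def test_single_class_rejected(self):
        X, _ = _separable_toy()
        with pytest.raises(ValueError, match="2 classes"):
            cf.SubtypeClassifier().fit(X, [1, 1, 1, 1])

    def test_schema_mismatch_lists_missing(self):
        X, y = _separable_toy()
        model = cf.SubtypeClassifier().fit(X, y)
        with pytest.raises(ValueError, match="f2"):
            model.predict(X[["f1"]])

    def test_all_zero_row_deterministic(self):
        X, y = _separable_toy()
        model = cf.SubtypeClassifier().fit(X, y)
        zero = pd.DataFrame({"f1": [0.0], "f2": [0.0]})
        assert model.predict(zero)[0] == model.predict(zero)[0]

    def test_serialization_round_trip(self, tmp_path):
        X, y = _separable_toy()
        model = cf.SubtypeClassifier(C=2.0).fit(X, y)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = cf.SubtypeClassifier.load(path)
        assert np.allclose(loaded.decision_function(X), model.decision_function(X))
        assert loaded.C == 2.0

    def test_control_class_refit_extends_model(self):
        # deviation-like features: each subtype deviates on its own pathway,
        # controls deviate on none
        X = pd.DataFrame(
            {"f1": [4.0, 4.2, 0.1, 0.0], "f2": [0.1, 0.0, 4.0, 4.1]},
            index=[f"S{i}" for i in range(4)],
        )
        y = pd.Series([1, 1, 2, 2], index=X.index)
        model = cf.SubtypeClassifier().fit(X, y)
        ext = pd.DataFrame(
            {"f1": [4.1, 0.2, 0.1, 0.0], "f2": [0.2, 4.2, 0.0, 0.1]},
            index=[f"V{i}" for i in range(4)],
        )
        extended = model.with_control_class(ext, ["V2", "V3"], label=0)
        assert list(extended.classes_) == [0, 1, 2]
        assert extended.predict(ext).tolist() == [1, 2, 0, 0]
        with pytest.raises(ValueError, match="already present"):
            extended.with_control_class(ext, ["V2", "V3"], label=0)

    def test_feature_scaling_keeps_separable_accuracy(self):
        X, y = _separable_toy()
        scaled = X * 7.5
        model = cf.SubtypeClassifier().fit(scaled, y)
        assert (model.predict(scaled) == y.to_numpy()).all()


class TestCrossValidation:
    def _clustered_data(self, seed=0, n_per=20, k=3):
        rng = np.random.default_rng(seed)
        centers = np.eye(k) * 4
        X = np.vstack([rng.normal(centers[c], 1.0, size=(n_per, k)) for c in range(k)])
        y = np.repeat(np.arange(1, k + 1), n_per)
        idx = [f"S{i}" for i in range(len(y))]
        return pd.DataFrame(X, index=idx), pd.Series(y, index=idx)

    def test_folds_exceeding_smallest_class_rejected(self):
        X, y = self._clustered_data(n_per=4)
        with pytest.raises(ValueError, match="smallest class"):
            cf.cross_validate_roc(X, y, folds=5)

    def test_separable_data_auc_one(self):
        rng = np.random.default_rng(1)
        X, y = self._clustered_data(seed=1)
        X = X * 10  # near-perfect separation
        result = cf.cross_validate_roc(X, y, folds=5, seed=0)
        assert all(a >= 0.99 for a in result.auc.values())

    def test_pooled_auc_equals_mann_whitney(self):
        X, y = self._clustered_data(seed=3, n_per=12)
        result = cf.cross_validate_roc(X, y, folds=4, seed=5)
        for c in result.auc:
            scores = result.scores[c].to_numpy()
            pos = scores[(y == c).to_numpy()]
            neg = scores[(y != c).to_numpy()]
            assert result.auc[c] == pytest.approx(mann_whitney_auc(pos, neg), abs=1e-10)

    def test_roc_endpoints_and_monotonicity(self):
        X, y = self._clustered_data(seed=4, n_per=10)
        result = cf.cross_validate_roc(X, y, folds=5, seed=1)
        for fpr, tpr in result.roc.values():
            assert (fpr[0], tpr[0]) == (0.0, 0.0)
            assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
            assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()

    def test_same_seed_reproducible(self):
        X, y = self._clustered_data(seed=6)
        a = cf.cross_validate_roc(X, y, folds=5, seed=9)
        b = cf.cross_validate_roc(X, y, folds=5, seed=9)
        assert a.auc == b.auc
        pd.testing.assert_series_equal(a.fold_assignment, b.fold_assignment)

    def test_predict_labels_on_training_toy(self):
        X, y = _separable_toy()
        model = cf.SubtypeClassifier().fit(X, y)
        predicted = cf.predict_labels(model, X)
        assert (predicted == y).all()
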