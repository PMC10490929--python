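"""AUC computation, in-fold feature selection and the bootstrap harness."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vascrisk.classify import (
    ClassifierEval,
    DEFrequencySelector,
    FeatureTable,
    VarianceSelector,
    build_feature_table,
    build_labels,
    compute_auc,
    evaluate_model,
    pick_best_model,
)
from vascrisk.data import ValidationError

from oracles import auc_pairs


class TestComputeAuc:
    def test_worked_example(self):
        assert compute_auc([0.9, 0.6, 0.7, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert compute_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        assert compute_auc([0.1, 0.2], [1, 1]) is None

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            n = int(rng.integers(4, 40))
            scores = rng.choice(np.round(rng.normal(size=n), 1), size=n)
            labels = rng.integers(0, 2, size=n)
            ours = compute_auc(scores, labels)
            ref = auc_pairs(scores, labels)
            if ref is None:
                assert ours is None
            else:
                assert ours == pytest.approx(ref, abs=1e-12)


class TestPickBest:
    def _ev(self, name, auc):
        return ClassifierEval("se", name, "sel", [auc], auc)

    def test_argmax(self):
        best = pick_best_model([self._ev("a", 0.60), self._ev("b", 0.75), self._ev("c", 0.70)])
        assert best.model_name == "b"

    def test_tie_lexicographic(self):
        best = pick_best_model([self._ev("zeta", 0.70), self._ev("alpha", 0.70)])
        assert best.model_name == "alpha"

    def test_single_and_empty(self):
        only = self._ev("x", 0.5)
        assert pick_best_model([only]) is only
        with pytest.raises(ValidationError):
            pick_best_model([])


def _toy_features(n_rows=20, n_genes=6, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"C{i:02d}" for i in range(n_rows)]
    cols = [f"lfc|SMC|G{g}" for g in range(n_genes)] + [f"expr|SMC|G{g}" for g in range(n_genes)]
    X = pd.DataFrame(rng.normal(size=(n_rows, len(cols))), index=ids, columns=cols)
    prov = pd.Series(
        ["fold_change"] * n_genes + ["expression"] * n_genes, index=cols
    )
    de_fdr = pd.DataFrame(
        rng.uniform(size=(n_rows, n_genes)), index=ids, columns=[f"SMC|G{g}" for g in range(n_genes)]
    )
    return FeatureTable(X=X, provenance=prov), de_fdr


class TestSelectors:
    def test_de_frequency_threshold(self):
        features, de_fdr = _toy_features()
        de_fdr.iloc[:, :] = 1.0
        de_fdr.loc[de_fdr.index[:2], "SMC|G0"] = 0.01   # DE in 2 of 20 -> 0.10
        de_fdr.loc[de_fdr.index[:1], "SMC|G1"] = 0.01   # DE in 1 of 20 -> 0.05
        sel = DEFrequencySelector(de_fdr, min_fraction=0.10, fallback_k=3)
        cols = sel.select(features.X.index, features)
        assert cols == ["lfc|SMC|G0", "expr|SMC|G0"]

    def test_selection_sees_only_training_rows(self):
        """A gene DE only in held-out treatments must not be selected."""
        features, de_fdr = _toy_features()
        de_fdr.iloc[:, :] = 1.0
        train_ids = features.X.index[:10]
        held_out = features.X.index[10:]
        de_fdr.loc[held_out, "SMC|G5"] = 0.001          # DE only outside training
        de_fdr.loc[train_ids[:5], "SMC|G2"] = 0.001     # DE in half the training rows
        sel = DEFrequencySelector(de_fdr, min_fraction=0.10)
        cols = sel.select(train_ids, features)
        assert "lfc|SMC|G2" in cols
        assert all("G5" not in c for c in cols)

    def test_empty_selection_falls_back_to_variance(self, caplog):
        features, de_fdr = _toy_features()
        de_fdr.iloc[:, :] = 1.0
        sel = DEFrequencySelector(de_fdr, fallback_k=4)
        cols = sel.select(features.X.index, features)
        assert len(cols) == 4
        assert cols == VarianceSelector(4).select(features.X.index, features)

    def test_max_features_cap_keeps_most_frequent(self):
        features, de_fdr = _toy_features()
        de_fdr.iloc[:, :] = 1.0
        de_fdr["SMC|G0"] = 0.01     # DE everywhere
        de_fdr.loc[de_fdr.index[:10], "SMC|G1"] = 0.01
        sel = DEFrequencySelector(de_fdr, max_features=2)
        cols = sel.select(features.X.index, features)
        assert cols == ["lfc|SMC|G0", "expr|SMC|G0"]


class TestEvaluateModel:
    def test_seeded_determinism(self):
        features, de_fdr = _toy_features(n_rows=24)
        labels = pd.Series(([0, 1] * 12), index=features.X.index, name="se")
        sel = DEFrequencySelector(de_fdr, fallback_k=6)
        ev1 = evaluate_model(features, labels, "ridge", sel, n_boot=5, seed=3)
        ev2 = evaluate_model(features, labels, "ridge", sel, n_boot=5, seed=3)
        assert ev1.boot_aucs == ev2.boot_aucs
        assert len(ev1.boot_aucs) == 5
        assert ev1.mean_auc == pytest.approx(np.nanmean(ev1.boot_aucs))

    def test_learnable_signal_beats_null(self):
        rng = np.random.default_rng(1)
        features, de_fdr = _toy_features(n_rows=40, seed=1)
        y = rng.integers(0, 2, size=40)
        X = features.X.copy()
        X.iloc[:, 0] = 3.0 * y + rng.normal(0, 0.3, size=40)  # informative, high variance
        features = FeatureTable(X=X, provenance=features.provenance)
        labels = pd.Series(y, index=X.index, name="se")
        sel = VarianceSelector(6)
        ev = evaluate_model(features, labels, "ridge", sel, n_boot=20, seed=2)
        null = evaluate_model(features, labels, "ridge", sel, n_boot=20, seed=2,
                              permute_labels=True)
        assert ev.mean_auc > 0.8 > null.mean_auc

    def test_label_copy_feature_invisible_to_de_selector(self):
        """A leaked label-copy feature that is never DE cannot inflate the
        null because selection only admits DE-frequent genes."""
        rng = np.random.default_rng(9)
        features, de_fdr = _toy_features(n_rows=30, seed=4)
        y = rng.integers(0, 2, size=30)
        X = features.X.copy()
        X["lfc|SMC|LEAK"] = y.astype(float)
        prov = pd.concat([features.provenance, pd.Series({"lfc|SMC|LEAK": "fold_change"})])
        features = FeatureTable(X=X, provenance=prov)
        de_fdr = de_fdr.copy()
        de_fdr["SMC|LEAK"] = 1.0                      # never DE
        de_fdr.iloc[:, :6] = 0.01                     # all real genes DE
        labels = pd.Series(y, index=X.index, name="se")
        sel = DEFrequencySelector(de_fdr)
        cols = sel.select(X.index, features)
        assert all("LEAK" not in c for c in cols)
        ev = evaluate_model(features, labels, "ridge", sel, n_boot=30, seed=5,
                            permute_labels=True)
        assert 0.4 < ev.mean_auc < 0.6

    def test_roc_curve_monotone(self):
        features, de_fdr = _toy_features(n_rows=24)
        labels = pd.Series(([0, 1] * 12), index=features.X.index, name="se")
        ev = evaluate_model(features, labels, "knn", VarianceSelector(6), n_boot=5, seed=1)
        fpr = [p[0] for p in ev.roc_curve]
        tpr = [p[1] for p in ev.roc_curve]
        assert fpr == sorted(fpr)
        assert tpr == sorted(tpr)
        assert ev.roc_curve[0] == (0.0, 0.0) and ev.roc_curve[-1] == (1.0, 1.0)

    def test_too_few_labels_rejected(self):
        features, de_fdr = _toy_features(n_rows=6)
        labels = pd.Series([1, 1, 1, 1, 1, 0], index=features.X.index, name="se")
        with pytest.raises(ValidationError):
            evaluate_model(features, labels, "ridge", VarianceSelector(3), n_boot=2, seed=0)


class TestBuildFeatureTable:
    def test_shapes_and_provenance(self, small_db):
        database, _, _ = small_db
        features, de_fdr = build_feature_table(database)
        n = database.n_compounds
        assert features.X.shape[0] == n
        assert set(features.provenance.unique()) == {"fold_change", "expression"}
        assert de_fdr.shape[0] == n
        # one lfc + one expr column per (cell type, gene)
        assert features.X.shape[1] == 2 * de_fdr.shape[1]

    def test_labels_exclude_unknown(self, small_db):
        database, _, _ = small_db
        se = database.side_effect_names()[0]
        labels = build_labels(database, se)
        assert set(labels.unique()) <= {0, 1}
        with pytest.raises(ValidationError):
            build_labels(database, "never-heard-of-it")
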