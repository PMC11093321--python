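import numpy as np
import pandas as pd
import pytest

from hotspotnet.network_scores import ALL_SCORE_NAMES, ScoreTable
from hotspotnet.hotspot_ml import (
    FeatureScheme,
    assemble_feature_table,
    feature_columns,
    load_bundle,
    predict_scores,
    read_site_labels,
    roc_auc,
    save_bundle,
    split_by_protein,
    train_ensemble,
    write_site_labels,
)


def toy_score_table(protein_id, source_tag, n, seed=0):
    rng = np.random.default_rng(seed)
    return ScoreTable(
        protein_id=protein_id,
        source_tag=source_tag,
        scores={name: rng.random(n) for name in ALL_SCORE_NAMES},
    )


def toy_labels(proteins, sites_each=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for pid in proteins:
        for r in range(1, sites_each + 1):
            rows.append((pid, r, int(rng.integers(0, 2))))
    df = pd.DataFrame(rows, columns=["protein_id", "residue_index", "label"])
    # guarantee both classes
    df.loc[0, "label"] = 1
    df.loc[1, "label"] = 0
    return df


class TestAssemble:
    def test_single_source_gives_twenty_columns(self):
        tables = [toy_score_table(p, "src1", 10, s) for s, p in enumerate(["a", "b"])]
        labels = toy_labels(["a", "b"])
        out = assemble_feature_table(tables, labels, FeatureScheme("s1", ("src1",)))
        assert len(feature_columns(out)) == 20
        assert len(out) == 8

    def test_three_sources_give_sixty_columns(self):
        tables = [
            toy_score_table(p, src, 10, hash((p, src)) % 1000)
            for p in ["a", "b"]
            for src in ["src1", "src2", "src3"]
        ]
        labels = toy_labels(["a", "b"])
        scheme = FeatureScheme("s6", ("src1", "src2", "src3"))
        out = assemble_feature_table(tables, labels, scheme)
        assert len(feature_columns(out)) == 60

    def test_external_columns_appended(self):
        tables = [
            toy_score_table(p, src, 10)
            for p in ["a", "b"]
            for src in ["src1", "src2", "src3"]
        ]
        labels = toy_labels(["a", "b"])
        ext_cols = [f"lm{k}" for k in range(5)]
        ext = labels[["protein_id", "residue_index"]].copy()
        for c in ext_cols:
            ext[c] = 0.1
        scheme = FeatureScheme("s8", ("src1", "src2", "src3"), external=tuple(ext_cols))
        out = assemble_feature_table(tables, labels, scheme, external=ext)
        assert len(feature_columns(out)) == 65

    def test_percentile_values_used(self):
        table = toy_score_table("a", "src1", 10, seed=3)
        labels = pd.DataFrame(
            {"protein_id": ["a", "a"], "residue_index": [2, 5], "label": [1, 0]}
        )
        out = assemble_feature_table([table], labels, FeatureScheme("s1", ("src1",)))
        assert out.loc[0, "src1:W1"] == table.percentiles["W1"][1]
        assert out.loc[1, "src1:W1"] == table.percentiles["W1"][4]

    def test_out_of_range_site_lists_offender(self):
        table = toy_score_table("a", "src1", 5)
        labels = pd.DataFrame(
            {"protein_id": ["a"], "residue_index": [9], "label": [1]}
        )
        with pytest.raises(ValueError, match=r"\('a', 9\)"):
            assemble_feature_table([table], labels, FeatureScheme("s1", ("src1",)))

    def test_missing_source_rejected(self):
        table = toy_score_table("a", "src1", 5)
        labels = toy_labels(["a"])
        with pytest.raises(ValueError, match="src2"):
            assemble_feature_table([table], labels, FeatureScheme("s", ("src1", "src2")))

    def test_labels_tsv_round_trip(self, tmp_path):
        labels = toy_labels(["a", "b"])
        path = tmp_path / "labels.tsv"
        write_site_labels(labels, path)
        assert "deleterious" in path.read_text()
        reloaded = read_site_labels(path)
        pd.testing.assert_frame_equal(
            reloaded[["protein_id", "residue_index", "label"]],
            labels[["protein_id", "residue_index", "label"]],
        )


class TestSplit:
    def _table(self, n_proteins=10):
        tables = [toy_score_table(f"p{k}", "src1", 8, k) for k in range(n_proteins)]
        labels = toy_labels([f"p{k}" for k in range(n_proteins)])
        return assemble_feature_table(tables, labels, FeatureScheme("s1", ("src1",)))

    def test_fraction_mode_partitions_proteins(self):
        table = self._table()
        train, test = split_by_protein(table, train_fraction=0.7, seed=5)
        train_p = set(train["protein_id"])
        test_p = set(test["protein_id"])
        assert len(train_p) == 7 and len(test_p) == 3
        assert not train_p & test_p

    def test_fraction_mode_deterministic(self):
        table = self._table()
        a = split_by_protein(table, train_fraction=0.7, seed=5)
        b = split_by_protein(table, train_fraction=0.7, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_explicit_all_proteins_rejected(self):
        table = self._table(3)
        with pytest.raises(ValueError, match="degenerate"):
            split_by_protein(table, train_proteins=["p0", "p1", "p2"])

    def test_absent_train_protein_rejected(self):
        table = self._table(3)
        with pytest.raises(ValueError, match="absent"):
            split_by_protein(table, train_proteins=["p0", "nope"])


def separable_table(n_proteins=6, sites=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_proteins):
        for r in range(1, sites + 1):
            label = int(rng.integers(0, 2))
            rows.append((f"p{k}", r, label, label * 0.5 + rng.random() * 0.3, rng.random()))
    return pd.DataFrame(
        rows, columns=["protein_id", "residue_index", "label", "good", "noise"]
    )


class TestTrainEnsemble:
    def test_separable_data_reaches_perfect_training_auc(self):
        table = separable_table()
        bundle = train_ensemble(table, "rf", tuning_trials=2, seed=0)
        prob = predict_scores(bundle, table)
        assert roc_auc(prob, table["label"].to_numpy()).auc == 1.0

    def test_permuted_labels_give_chance_level_cv(self):
        rng = np.random.default_rng(1)
        table = separable_table(n_proteins=10, sites=20, seed=1)
        table["good"] = rng.random(len(table))  # destroy the signal
        table["label"] = rng.permutation(table["label"].to_numpy())
        bundle = train_ensemble(table, "xgb", tuning_trials=2, seed=1)
        assert 0.35 <= bundle.cv_auc <= 0.65

    def test_same_seed_reproduces_hyperparameters_and_predictions(self):
        table = separable_table()
        a = train_ensemble(table, "gb", tuning_trials=3, seed=7)
        b = train_ensemble(table, "gb", tuning_trials=3, seed=7)
        assert a.hyperparameters == b.hyperparameters
        np.testing.assert_array_equal(predict_scores(a, table), predict_scores(b, table))

    def test_single_class_rejected(self):
        table = separable_table()
        table["label"] = 1
        with pytest.raises(ValueError, match="both classes"):
            train_ensemble(table, "rf", tuning_trials=1, seed=0)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            train_ensemble(separable_table(), "svm", tuning_trials=1, seed=0)


class TestPredict:
    def test_probabilities_in_range(self):
        table = separable_table()
        bundle = train_ensemble(table, "rf", tuning_trials=1, seed=0)
        prob = predict_scores(bundle, table)
        assert prob.shape == (len(table),)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_reordered_columns_align_by_name(self):
        table = separable_table()
        bundle = train_ensemble(table, "rf", tuning_trials=1, seed=0)
        shuffled = table[["protein_id", "residue_index", "label", "noise", "good"]]
        np.testing.assert_array_equal(
            predict_scores(bundle, table), predict_scores(bundle, shuffled)
        )

    def test_column_mismatch_names_offenders(self):
        table = separable_table()
        bundle = train_ensemble(table, "rf", tuning_trials=1, seed=0)
        with pytest.raises(ValueError, match="missing.*noise"):
            predict_scores(bundle, table.drop(columns=["noise"]))

    def test_bundle_round_trip(self, tmp_path):
        table = separable_table()
        bundle = train_ensemble(table, "xgb", tuning_trials=2, seed=3)
        path = tmp_path / "model.joblib"
        save_bundle(bundle, path)
        reloaded = load_bundle(path)
        assert reloaded.hyperparameters == bundle.hyperparameters
        assert reloaded.feature_names == bundle.feature_names
        np.testing.assert_array_equal(
            predict_scores(reloaded, table), predict_scores(bundle, table)
        )


def pairwise_auc_oracle(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        res = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_inverted_ranking(self):
        res = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([0, 0, 1, 1]))
        assert res.auc == 0.0

    def test_full_tie_is_half(self):
        assert roc_auc(np.array([0.5, 0.5]), np.array([1, 0])).auc == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert abs(
                roc_auc(scores, labels).auc - pairwise_auc_oracle(scores, labels)
            ) < 1e-12

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(5 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_curve_is_monotone_and_anchored(self):
        rng = np.random.default_rng(4)
        scores, labels = rng.random(30), rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        pts = roc_auc(scores, labels).roc_points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)
        assert roc_auc(scores, labels).auc == pytest.approx(
            np.trapezoid(pts[:, 1], pts[:, 0]), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))
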