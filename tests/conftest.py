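import numpy as np
import pytest

from hotspotnet.contact_maps import ContactMap
from hotspotnet.hotspot_ml import (
    FeatureScheme,
    assemble_feature_table,
    feature_columns,
    predict_scores,
    roc_auc,
    split_by_protein,
    train_ensemble,
)
from hotspotnet.network_scores import score_protein
from hotspotnet.synthetic import generate_cohort


def make_random_map(rng, n, density=1.0, protein_id="p", source_tag="synthetic"):
    """Random symmetric zero-diagonal contact map, optionally sparsified."""
    P = rng.random((n, n))
    if density < 1.0:
        P *= rng.random((n, n)) < density
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 0.0)
    return ContactMap(protein_id=protein_id, P=P, source_tag=source_tag)


def make_chain_map(weights, protein_id="chain"):
    """Map whose only contacts are the given successive-pair probabilities."""
    n = len(weights) + 1
    P = np.zeros((n, n))
    for i, w in enumerate(weights):
        P[i, i + 1] = P[i + 1, i] = w
    return ContactMap(protein_id=protein_id, P=P)


@pytest.fixture
def map_factory():
    return make_random_map


@pytest.fixture(scope="session")
def e2e_results():
    """Full synthetic-cohort pipeline shared by the end-to-end tests.

    Generates the default cohort (30 proteins of 40-80 residues, three
    logit-noise sigma=1 sources, label slope 6 / intercept -1.5), scores every
    corrupted map, assembles the combined 3x20-score feature table and its
    7-score ablation, splits by protein, and trains all three algorithms.
    """
    seed = 1
    cohort = generate_cohort(seed=seed)
    tables = [
        score_protein(cmap)
        for protein in cohort.proteins
        for cmap in protein.corrupted_maps.values()
    ]
    sources = tuple(sorted(cohort.proteins[0].corrupted_maps))
    full = assemble_feature_table(
        tables, cohort.labels, FeatureScheme("combined", sources, "full")
    )
    core = assemble_feature_table(
        tables, cohort.labels, FeatureScheme("combined-core", sources, "core")
    )
    train_full, test_full = split_by_protein(full, train_fraction=0.7, seed=seed)
    train_core, test_core = split_by_protein(core, train_fraction=0.7, seed=seed)
    y_test = test_full["label"].to_numpy()

    results = {}
    for algo in ("rf", "gb", "xgb"):
        bundle = train_ensemble(train_full, algo, tuning_trials=16, seed=seed)
        prob = predict_scores(bundle, test_full)
        results[algo] = {
            "cv_auc": bundle.cv_auc,
            "test_auc": roc_auc(prob, y_test).auc,
        }
    core_bundle = train_ensemble(train_core, "rf", tuning_trials=16, seed=seed)
    core_auc = roc_auc(predict_scores(core_bundle, test_core), y_test).auc

    best_single = max(
        roc_auc(test_full[col].to_numpy(), y_test).auc
        for col in feature_columns(test_full)
    )
    designated = max(results, key=lambda a: results[a]["cv_auc"])
    return {
        "bayes_auc": cohort.bayes_auc(),
        "results": results,
        "designated": designated,
        "combined_auc": results[designated]["test_auc"],
        "best_single_auc": best_single,
        "core7_auc": core_auc,
        "full_rf_auc": results["rf"]["test_auc"],
        "n_pos": int(y_test.sum()),
        "n_neg": int((1 - y_test).sum()),
        "n_test": len(y_test),
    }
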