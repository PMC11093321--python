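"""Site-level classification of deleterious vs neutral variant positions.

Feature tables have one row per labelled site (protein, 1-based residue
position, binary label) and one column per percentile-normalized network
score, namespaced ``"{source_tag}:{score_name}"``.  Models are tree ensembles
(random forest, gradient boosting, XGBoost) tuned by seeded random search
under protein-grouped cross-validation, so no protein contributes sites to
both the tuning folds' train and validation sides.  Evaluation is by ROC/AUC
with the operating point chosen by Youden's J.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GroupKFold

from .network_scores import ALL_SCORE_NAMES, CORE_SCORE_NAMES, ScoreTable

__all__ = [
    "ID_COLUMNS",
    "FeatureScheme",
    "ClassifierBundle",
    "EvalResult",
    "assemble_feature_table",
    "feature_columns",
    "split_by_protein",
    "train_ensemble",
    "predict_scores",
    "roc_auc",
    "save_bundle",
    "load_bundle",
    "read_site_labels",
    "write_site_labels",
]

ID_COLUMNS = ("protein_id", "residue_index", "label")

BUNDLE_FORMAT_VERSION = 1

ALGORITHMS = ("rf", "gb", "xgb")


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureScheme:
    """Named column subset combining score sources into one feature set.

    ``sources`` lists the contact-map source tags whose scores enter the
    table; ``score_set`` is ``"full"`` (all 20 scores) or ``"core"`` (the 7
    degree/GNM scores, the fast ablation); ``external`` names extra per-site
    columns (e.g. protein-language-model variant scores) appended verbatim.
    """

    name: str
    sources: tuple[str, ...]
    score_set: str = "full"
    external: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.score_set not in ("full", "core"):
            raise ValueError(f"score_set must be 'full' or 'core', got {self.score_set!r}")
        if not self.sources:
            raise ValueError("scheme needs at least one source")

    @property
    def score_names(self) -> tuple[str, ...]:
        return ALL_SCORE_NAMES if self.score_set == "full" else CORE_SCORE_NAMES

    @property
    def column_names(self) -> list[str]:
        cols = [f"{src}:{score}" for src in self.sources for score in self.score_names]
        cols.extend(self.external)
        return cols


def _normalize_labels(labels: pd.DataFrame) -> pd.DataFrame:
    labels = labels.copy()
    required = {"protein_id", "residue_index", "label"}
    missing = required - set(labels.columns)
    if missing:
        raise ValueError(f"label table missing columns {sorted(missing)}")
    if labels["label"].dtype == object:
        mapping = {"deleterious": 1, "neutral": 0}
        unknown = set(labels["label"]) - set(mapping)
        if unknown:
            raise ValueError(f"unknown label values {sorted(unknown)}")
        labels["label"] = labels["label"].map(mapping)
    labels["label"] = labels["label"].astype(int)
    if not labels["label"].isin((0, 1)).all():
        raise ValueError("labels must be binary (deleterious=1 / neutral=0)")
    dup = labels.duplicated(subset=["protein_id", "residue_index"])
    if dup.any():
        raise ValueError("duplicate (protein_id, residue_index) in labels")
    return labels


def assemble_feature_table(
    score_tables: Iterable[ScoreTable],
    labels: pd.DataFrame,
    scheme: FeatureScheme,
    external: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the per-site feature table for a scheme.

    ``score_tables`` must cover every labelled protein for every source in
    the scheme; percentile values (not raw scores) populate the features.
    ``external`` supplies the scheme's external columns, keyed by
    (protein_id, residue_index).
    """
    labels = _normalize_labels(labels)
    by_key: dict[tuple[str, str], ScoreTable] = {}
    for table in score_tables:
        by_key[(table.protein_id, table.source_tag)] = table

    proteins = labels["protein_id"].unique()
    for src in scheme.sources:
        absent = [p for p in proteins if (p, src) not in by_key]
        if absent:
            raise ValueError(f"no '{src}' score table for proteins {sorted(absent)}")

    # validate residue indices against protein lengths (1-based positions)
    offenders = []
    for pid, grp in labels.groupby("protein_id"):
        n = by_key[(pid, scheme.sources[0])].n_residues
        bad = grp.loc[(grp["residue_index"] < 1) | (grp["residue_index"] > n)]
        offenders.extend((pid, int(r)) for r in bad["residue_index"])
    if offenders:
        raise ValueError(f"labelled sites outside protein length: {offenders}")

    out = labels[["protein_id", "residue_index", "label"]].reset_index(drop=True)
    for src in scheme.sources:
        for score in scheme.score_names:
            col = np.empty(len(out))
            for pid, grp in out.groupby("protein_id"):
                table = by_key[(pid, src)]
                if score not in table.percentiles:
                    raise ValueError(f"score {score!r} missing from {pid}/{src}")
                vec = table.percentiles[score]
                col[grp.index] = vec[grp["residue_index"].to_numpy() - 1]
            out[f"{src}:{score}"] = col
    if scheme.external:
        if external is None:
            raise ValueError(f"scheme {scheme.name!r} needs external columns {scheme.external}")
        missing = set(scheme.external) - set(external.columns)
        if missing:
            raise ValueError(f"external table missing columns {sorted(missing)}")
        merged = out.merge(
            external[["protein_id", "residue_index", *scheme.external]],
            on=["protein_id", "residue_index"],
            how="left",
            validate="one_to_one",
        )
        if merged[list(scheme.external)].isna().any().any():
            raise ValueError("external columns missing for some labelled sites")
        out = merged
    if out[feature_columns(out)].isna().any().any():
        raise ValueError("NaN feature values are not allowed")
    return out


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns (everything except the id columns)."""
    return [c for c in table.columns if c not in ID_COLUMNS]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_by_protein(
    table: pd.DataFrame,
    train_proteins: Iterable[str] | None = None,
    train_fraction: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition sites into train/test with no protein on both sides.

    Either pass an explicit ``train_proteins`` list (deterministic) or a
    ``train_fraction`` in (0, 1), which shuffles the sorted protein list with
    the given seed and takes the first ``round(fraction * n)`` proteins.
    """
    proteins = sorted(table["protein_id"].unique())
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins to split")
    if (train_proteins is None) == (train_fraction is None):
        raise ValueError("pass exactly one of train_proteins / train_fraction")
    if train_proteins is not None:
        chosen = list(train_proteins)
        absent = sorted(set(chosen) - set(proteins))
        if absent:
            raise ValueError(f"train proteins absent from table: {absent}")
    else:
        if not (0.0 < train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(proteins))
        k = int(round(train_fraction * len(proteins)))
        k = min(max(k, 1), len(proteins) - 1)
        chosen = shuffled[:k]
    train_mask = table["protein_id"].isin(chosen)
    train = table.loc[train_mask].reset_index(drop=True)
    test = table.loc[~train_mask].reset_index(drop=True)
    if len(train) == 0 or len(test) == 0:
        raise ValueError("degenerate split: one partition is empty")
    return train, test


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class ClassifierBundle:
    """A fitted tree-ensemble with everything needed to reuse it."""

    algorithm: str
    hyperparameters: dict
    feature_names: list[str]
    training_seed: int
    model: object
    cv_auc: float = float("nan")


def _draw_hyperparameters(algorithm: str, rng: np.random.Generator) -> dict:
    params = {
        "max_depth": int(rng.integers(2, 17)),
        "n_estimators": int(rng.integers(50, 801)),
    }
    if algorithm in ("rf", "gb"):
        params["max_features"] = float(rng.uniform(0.1, 1.0))
    else:  # xgb
        params["reg_alpha"] = float(10.0 ** rng.uniform(-4, 1))
        params["reg_lambda"] = float(10.0 ** rng.uniform(-4, 1))
    return params


def _make_model(algorithm: str, params: Mapping, seed: int, class_weight: str | None):
    if algorithm == "rf":
        return RandomForestClassifier(
            random_state=seed, n_jobs=1, class_weight=class_weight, **params
        )
    if algorithm == "gb":
        # GradientBoostingClassifier has no class_weight; rebalancing is the
        # caller's responsibility for this algorithm.
        return GradientBoostingClassifier(random_state=seed, **params)
    if algorithm == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            verbosity=0,
            **params,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def train_ensemble(
    train: pd.DataFrame,
    algorithm: str,
    tuning_trials: int = 20,
    seed: int = 0,
    class_weight: str | None = None,
) -> ClassifierBundle:
    """Tune and fit a tree ensemble on a site feature table.

    Hyper-parameters are drawn by seeded random search (``tuning_trials``
    candidates) over per-algorithm spaces — RF/GB: ``max_depth`` in [2, 16],
    ``n_estimators`` in [50, 800], ``max_features`` in (0.1, 1]; XGB replaces
    ``max_features`` with log-uniform ``reg_alpha``/``reg_lambda`` in
    [1e-4, 10].  Each candidate is scored by mean ROC-AUC under
    protein-grouped k-fold CV (k = min(5, #proteins)).  The winner is chosen
    by the one-standard-error rule: among candidates whose mean CV AUC lies
    within one standard error of the best, the least complex (smallest
    ``max_depth``, then fewest ``n_estimators``) is selected — with a handful
    of grouped folds the plain CV maximum is noisy and systematically favours
    over-deep trees.  The winner is refit on all training rows.  Fully
    deterministic given the seed.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if tuning_trials < 1:
        raise ValueError("tuning_trials must be >= 1")
    cols = feature_columns(train)
    if not cols:
        raise ValueError("feature table has no feature columns")
    X = train[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN feature values are not allowed")
    y = train["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    groups = train["protein_id"].to_numpy()
    n_groups = len(np.unique(groups))
    k = min(5, n_groups)
    if k < 2:
        raise ValueError("grouped CV needs at least 2 proteins in the training set")
    splitter = GroupKFold(n_splits=k)
    folds = list(splitter.split(X, y, groups))

    rng = np.random.default_rng(seed)
    trials: list[tuple[dict, float, float]] = []  # (params, mean_auc, se_auc)
    for _ in range(tuning_trials):
        params = _draw_hyperparameters(algorithm, rng)
        fold_aucs = []
        for train_idx, val_idx in folds:
            y_val = y[val_idx]
            if len(np.unique(y_val)) < 2 or len(np.unique(y[train_idx])) < 2:
                continue  # a fold can be single-class on tiny cohorts
            model = _make_model(algorithm, params, seed, class_weight)
            model.fit(X[train_idx], y[train_idx])
            prob = model.predict_proba(X[val_idx])[:, 1]
            fold_aucs.append(roc_auc_score(y_val, prob))
        if not fold_aucs:
            raise ValueError("every CV fold was single-class; cohort too small")
        mean_auc = float(np.mean(fold_aucs))
        se_auc = float(np.std(fold_aucs, ddof=1) / np.sqrt(len(fold_aucs))) if len(fold_aucs) > 1 else 0.0
        trials.append((params, mean_auc, se_auc))

    # one-standard-error rule: least complex candidate within 1 SE of the best
    top_mean, top_se = max(((m, s) for _, m, s in trials), key=lambda t: t[0])
    eligible = [(p, m) for p, m, _ in trials if m >= top_mean - top_se]
    best_params, best_auc = min(
        eligible, key=lambda t: (t[0]["max_depth"], t[0]["n_estimators"], -t[1])
    )

    model = _make_model(algorithm, best_params, seed, class_weight)
    model.fit(X, y)
    return ClassifierBundle(
        algorithm=algorithm,
        hyperparameters=dict(best_params),
        feature_names=list(cols),
        training_seed=seed,
        model=model,
        cv_auc=best_auc,
    )


def predict_scores(bundle: ClassifierBundle, table: pd.DataFrame) -> np.ndarray:
    """Per-site deleterious probability, aligning columns by name."""
    cols = feature_columns(table)
    missing = sorted(set(bundle.feature_names) - set(cols))
    extra = sorted(set(cols) - set(bundle.feature_names))
    if missing or extra:
        raise ValueError(
            f"feature columns do not match the bundle (missing {missing}, extra {extra})"
        )
    X = table[bundle.feature_names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN feature values are not allowed")
    return bundle.model.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalResult:
    """ROC curve with its area and a Youden-J operating point."""

    roc_points: np.ndarray  # (k, 2) columns (fpr, tpr), from (0,0) to (1,1)
    auc: float
    sensitivity: float
    specificity: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
        }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> EvalResult:
    """ROC curve and trapezoidal AUC of a score against binary site labels.

    The trapezoidal area equals the tie-corrected Mann-Whitney statistic (the
    probability that a random deleterious site outscores a random neutral one,
    counting ties as 1/2).  Sensitivity and specificity are reported at the
    threshold maximizing Youden's J = sensitivity + specificity - 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    return EvalResult(
        roc_points=np.column_stack([fpr, tpr]),
        auc=auc,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        threshold=float(thresholds[best]),
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_bundle(bundle: ClassifierBundle, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": BUNDLE_FORMAT_VERSION,
            "algorithm": bundle.algorithm,
            "hyperparameters": bundle.hyperparameters,
            "feature_names": bundle.feature_names,
            "training_seed": bundle.training_seed,
            "cv_auc": bundle.cv_auc,
            "model": bundle.model,
        },
        path,
    )


def load_bundle(path: str | Path) -> ClassifierBundle:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise ValueError(f"unsupported bundle format version {version!r}")
    return ClassifierBundle(
        algorithm=payload["algorithm"],
        hyperparameters=payload["hyperparameters"],
        feature_names=payload["feature_names"],
        training_seed=payload["training_seed"],
        model=payload["model"],
        cv_auc=payload["cv_auc"],
    )


def read_site_labels(path: str | Path) -> pd.DataFrame:
    """Read a labels TSV (protein_id, residue_index, label deleterious/neutral)."""
    df = pd.read_csv(path, sep="\t")
    return _normalize_labels(df)


def write_site_labels(labels: pd.DataFrame, path: str | Path) -> None:
    out = _normalize_labels(labels).copy()
    out["label"] = out["label"].map({1: "deleterious", 0: "neutral"})
    out.to_csv(path, sep="\t", index=False)
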