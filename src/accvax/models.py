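"""Classifier families, feature ranking, training and scoring.

Six supervised families are supported, each at the hyperparameter settings
used for the bacterial immunogenicity models: PLS-based discriminant
analysis (component count chosen by internal cross-validation, response
thresholded at 0.5), k-nearest-neighbour with k=1 and 1/distance weighting,
an RBF support vector machine (gamma=100, cost=1), random forest, the random
subspace method with 1-NN base learners (subspace size 0.4), and extreme
gradient boosting (max depth 4, eta 1, 150 rounds).

Feature selection is ranking-based: each ACC feature receives an information
gain score computed after supervised entropy-based (MDL) discretization, and
features scoring strictly above the threshold (default 0) are kept.  Ranking
is always fit on training data only, so selection is leakage-free by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from scipy.special import expit
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .data import LabeledDataset

__all__ = [
    "ALGORITHMS",
    "DEFAULT_HYPERPARAMETERS",
    "ModelConfig",
    "FeatureRanking",
    "TrainedModel",
    "FeatureContractError",
    "rank_features",
    "information_gain_scores",
    "train_model",
    "predict_scores",
    "save_model",
    "load_model",
    "grid_search",
]

ALGORITHMS = ("pls_da", "knn", "svm_rbf", "rf", "rsm_knn", "xgboost")

#: Reported settings per family; anything not reported uses the conventional
#: implementation default and is recorded in the training fingerprint.
DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "pls_da": {"max_components": 10, "cv_folds": 5, "threshold": 0.5},
    "knn": {"k": 1, "weights": "distance"},
    "svm_rbf": {"gamma": 100.0, "cost": 1.0},
    "rf": {"n_estimators": 100, "max_features": "sqrt"},
    "rsm_knn": {"k": 1, "subspace_size": 0.4, "n_estimators": 10},
    "xgboost": {"max_depth": 4, "eta": 1.0, "n_rounds": 150},
}

# Families whose distance/projection geometry needs zero-mean unit-variance
# features; tree ensembles see raw ACC values.  The RBF machine also runs on
# raw features: its reported gamma of 100 matches the raw ACC scale (mean
# lagged products of E-descriptor values, magnitude ~1e-2), where squared
# distances between proteins are of order 1e-2.
_SCALED_FAMILIES = frozenset({"pls_da", "knn", "rsm_knn"})

_DEFAULT_FEATURE_SELECTION = {algo: algo == "rf" for algo in ALGORITHMS}


class FeatureContractError(ValueError):
    """Prediction-time features violate the model's ordering tag or width."""


@dataclass
class ModelConfig:
    """Configuration of one classifier family.

    ``hyperparameters`` overrides are merged over the family defaults;
    ``use_feature_selection`` defaults to True only for the random forest
    family (the setting its reported results used).
    """

    algorithm: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    use_feature_selection: bool | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        unknown = set(self.hyperparameters) - set(merged)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.algorithm}: {sorted(unknown)}")
        merged.update(self.hyperparameters)
        self.hyperparameters = merged
        if self.use_feature_selection is None:
            self.use_feature_selection = _DEFAULT_FEATURE_SELECTION[self.algorithm]

    def to_dict(self) -> dict[str, Any]:
        return {
            "algorithm": self.algorithm,
            "hyperparameters": dict(self.hyperparameters),
            "use_feature_selection": self.use_feature_selection,
            "seed": self.seed,
        }


@dataclass
class FeatureRanking:
    """Per-feature relevance scores; selection keeps scores strictly above threshold."""

    scores: np.ndarray
    method: str
    threshold: float = 0.0

    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.scores > self.threshold)


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to score new feature rows."""

    config: ModelConfig
    estimator: Any
    scaler: StandardScaler | None
    selected_features: np.ndarray
    feature_ordering_tag: str
    n_features_in: int
    fingerprint: dict[str, Any]

    def metadata(self) -> dict[str, Any]:
        return {
            "config": self.config.to_dict(),
            "feature_ordering_tag": self.feature_ordering_tag,
            "n_features_in": self.n_features_in,
            "selected_features": self.selected_features.tolist(),
            "fingerprint": self.fingerprint,
        }


# ---------------------------------------------------------------------------
# Information-gain ranking with supervised (MDL) discretization
# ---------------------------------------------------------------------------

def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _best_cut(xs: np.ndarray, ys: np.ndarray) -> tuple[int, float] | None:
    """Best binary split position (index of the right half's first element).

    Only positions between distinct feature values are candidates; returns
    the position minimizing the class-entropy of the two halves, or None if
    the segment has no admissible cut.
    """
    n = len(xs)
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    candidates = np.flatnonzero(xs[1:] != xs[:-1]) + 1
    if candidates.size == 0:
        return None
    best_pos, best_h = -1, np.inf
    for pos in candidates:
        left = cum[pos - 1]
        right = total - left
        h = (pos / n) * _entropy_from_counts(left) + ((n - pos) / n) * _entropy_from_counts(right)
        if h < best_h:
            best_pos, best_h = int(pos), float(h)
    return best_pos, best_h


def _mdl_accepts(ys: np.ndarray, pos: int, weighted_entropy: float) -> bool:
    """Fayyad-Irani MDL stopping criterion for one candidate binary split."""
    n = len(ys)
    h_all = _entropy_from_counts(np.bincount(ys, minlength=2))
    gain = h_all - weighted_entropy
    left, right = ys[:pos], ys[pos:]
    c = len(np.unique(ys))
    c1 = len(np.unique(left))
    c2 = len(np.unique(right))
    h1 = _entropy_from_counts(np.bincount(left, minlength=2))
    h2 = _entropy_from_counts(np.bincount(right, minlength=2))
    delta = np.log2(3.0**c - 2.0) - (c * h_all - c1 * h1 - c2 * h2)
    return gain > (np.log2(n - 1) + delta) / n


def _mdl_cuts(xs: np.ndarray, ys: np.ndarray, lo: int, hi: int, cuts: list[int]) -> None:
    segment_x, segment_y = xs[lo:hi], ys[lo:hi]
    if hi - lo < 2:
        return
    found = _best_cut(segment_x, segment_y)
    if found is None:
        return
    pos, h = found
    if not _mdl_accepts(segment_y, pos, h):
        return
    cuts.append(lo + pos)
    _mdl_cuts(xs, ys, lo, lo + pos, cuts)
    _mdl_cuts(xs, ys, lo + pos, hi, cuts)


def _info_gain_one(x: np.ndarray, y: np.ndarray) -> float:
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    cuts: list[int] = []
    _mdl_cuts(xs, ys, 0, len(xs), cuts)
    if not cuts:
        return 0.0
    boundaries = [0, *sorted(cuts), len(xs)]
    cond = 0.0
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        counts = np.bincount(ys[lo:hi], minlength=2)
        cond += (hi - lo) / len(xs) * _entropy_from_counts(counts)
    return max(0.0, _entropy_from_counts(np.bincount(ys, minlength=2)) - cond)


def information_gain_scores(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Information gain of each feature after MDL-based supervised discretization.

    A feature that the MDL criterion refuses to split (including any constant
    feature) scores exactly 0; a feature that separates the classes perfectly
    scores the full label entropy.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    return np.array([_info_gain_one(X[:, j], y) for j in range(X.shape[1])])


_RANKERS = {"info_gain": information_gain_scores}


def rank_features(dataset: LabeledDataset, method: str = "info_gain",
                  threshold: float = 0.0) -> FeatureRanking:
    """Score every feature with the chosen ranker (deterministic).

    Requires a labeled dataset with at least two records per class.
    """
    if method not in _RANKERS:
        raise ValueError(f"unknown ranking method {method!r}; available: {sorted(_RANKERS)}")
    if dataset.labels is None:
        raise ValueError("feature ranking requires labels")
    counts = np.bincount(dataset.labels, minlength=2)
    if (counts < 2).any():
        raise ValueError("feature ranking requires at least 2 records per class")
    scores = _RANKERS[method](dataset.features, dataset.labels)
    return FeatureRanking(scores=scores, method=method, threshold=threshold)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _make_knn(k: int, weights: str) -> KNeighborsClassifier:
    return KNeighborsClassifier(n_neighbors=k, weights=weights)


def _fit_pls_da(X: np.ndarray, y: np.ndarray, hp: dict[str, Any], seed: int):
    """PLS regression on a {0,1} response; component count by internal CV."""
    max_ncomp = int(min(hp["max_components"], X.shape[1], X.shape[0] - 2))
    max_ncomp = max(max_ncomp, 1)
    folds = int(min(hp["cv_folds"], np.bincount(y).min()))
    best_ncomp, best_acc = 1, -1.0
    if folds >= 2 and max_ncomp > 1:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
        for ncomp in range(1, max_ncomp + 1):
            correct = 0
            for train_idx, val_idx in splits:
                pls = PLSRegression(n_components=ncomp, scale=False)
                pls.fit(X[train_idx], y[train_idx].astype(float))
                pred = pls.predict(X[val_idx]).ravel() >= hp["threshold"]
                correct += int((pred == y[val_idx].astype(bool)).sum())
            acc = correct / len(y)
            if acc > best_acc:
                best_ncomp, best_acc = ncomp, acc
    model = PLSRegression(n_components=best_ncomp, scale=False)
    model.fit(X, y.astype(float))
    return model, best_ncomp


def _build_estimator(config: ModelConfig, n_features: int):
    hp = config.hyperparameters
    algo = config.algorithm
    if algo == "knn":
        return _make_knn(int(hp["k"]), hp["weights"])
    if algo == "svm_rbf":
        return SVC(C=float(hp["cost"]), gamma=float(hp["gamma"]), kernel="rbf",
                   probability=True, random_state=config.seed)
    if algo == "rf":
        return RandomForestClassifier(n_estimators=int(hp["n_estimators"]),
                                      max_features=hp["max_features"],
                                      random_state=config.seed, n_jobs=1)
    if algo == "rsm_knn":
        return BaggingClassifier(
            estimator=_make_knn(int(hp["k"]), "distance"),
            n_estimators=int(hp["n_estimators"]),
            max_features=float(hp["subspace_size"]),
            bootstrap=False, bootstrap_features=False,
            random_state=config.seed, n_jobs=1)
    if algo == "xgboost":
        return XGBClassifier(max_depth=int(hp["max_depth"]),
                             learning_rate=float(hp["eta"]),
                             n_estimators=int(hp["n_rounds"]),
                             objective="binary:logistic",
                             eval_metric="logloss",
                             random_state=config.seed, n_jobs=1)
    raise AssertionError(algo)


def train_model(config: ModelConfig, dataset: LabeledDataset) -> TrainedModel:
    """Fit one classifier family on a labeled dataset.

    When ``config.use_feature_selection`` is set, the information-gain
    ranking is fit on this dataset only (training data) and the estimator
    sees the selected subset.  Standardization statistics, for families that
    use them, likewise come from this dataset only.
    """
    if dataset.labels is None:
        raise ValueError("training requires a labeled dataset")
    if not dataset.feature_ordering_tag:
        raise ValueError("training requires a feature ordering tag")
    counts = np.bincount(dataset.labels, minlength=2)
    if (counts == 0).any():
        raise ValueError("training requires both classes to be present")

    if config.use_feature_selection:
        ranking = rank_features(dataset)
        selected = ranking.selected()
        if selected.size == 0:
            raise ValueError("feature selection removed every feature; nothing to train on")
    else:
        selected = np.arange(dataset.n_features)

    X = dataset.features[:, selected]
    y = dataset.labels

    scaler = None
    if config.algorithm in _SCALED_FAMILIES:
        scaler = StandardScaler()
        X = scaler.fit_transform(X)

    extra: dict[str, Any] = {}
    if config.algorithm == "pls_da":
        estimator, ncomp = _fit_pls_da(X, y, config.hyperparameters, config.seed)
        extra["pls_components"] = ncomp
    else:
        estimator = _build_estimator(config, X.shape[1])
        estimator.fit(X, y)

    fingerprint = {
        "n_records": int(len(y)),
        "class_counts": {"0": int(counts[0]), "1": int(counts[1])},
        "n_features_used": int(X.shape[1]),
        **extra,
    }
    return TrainedModel(
        config=config,
        estimator=estimator,
        scaler=scaler,
        selected_features=np.sort(selected),
        feature_ordering_tag=dataset.feature_ordering_tag,
        n_features_in=dataset.n_features,
        fingerprint=fingerprint,
    )


def _extract_features(model: TrainedModel,
                      features: LabeledDataset | np.ndarray) -> np.ndarray:
    if isinstance(features, LabeledDataset):
        if features.feature_ordering_tag != model.feature_ordering_tag:
            raise FeatureContractError(
                f"feature ordering tag mismatch: model expects "
                f"{model.feature_ordering_tag!r}, got {features.feature_ordering_tag!r}")
        X = features.features
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
    if X.shape[1] != model.n_features_in:
        raise FeatureContractError(
            f"feature width mismatch: model expects {model.n_features_in} "
            f"pre-selection features, got {X.shape[1]}")
    return X


def predict_scores(model: TrainedModel,
                   features: LabeledDataset | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class score in [0, 1] and binary label for each record.

    The score is the family's native positive-class confidence (vote
    fraction, distance-weighted neighbour fraction, calibrated SVM margin,
    boosted-logistic output, or a monotone squashing of the PLS response);
    the label is ``score >= 0.5``.
    """
    X = _extract_features(model, features)[:, model.selected_features]
    if model.scaler is not None:
        X = model.scaler.transform(X)

    if model.config.algorithm == "pls_da":
        threshold = float(model.config.hyperparameters["threshold"])
        response = model.estimator.predict(X).ravel()
        # strictly monotone map of the continuous response into [0, 1] with
        # the classification threshold landing exactly at score 0.5
        scores = expit(2.0 * (response - threshold))
    else:
        proba = model.estimator.predict_proba(X)
        positive_column = int(np.flatnonzero(model.estimator.classes_ == 1)[0])
        scores = proba[:, positive_column]
    scores = np.clip(scores, 0.0, 1.0)
    labels = (scores >= 0.5).astype(int)
    return scores, labels


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_ARCHIVE_FORMAT = "accvax-model-v1"


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model as a versioned joblib archive."""
    payload = {
        "format": _ARCHIVE_FORMAT,
        "metadata_json": json.dumps(model.metadata(), sort_keys=True),
        "estimator": model.estimator,
        "scaler": model.scaler,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path, expect_ordering_tag: str | None = None) -> TrainedModel:
    """Load a persisted model, refusing incompatible archives or ordering tags."""
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != _ARCHIVE_FORMAT:
        raise ValueError(f"{path}: not an {_ARCHIVE_FORMAT} archive")
    meta = json.loads(payload["metadata_json"])
    tag = meta["feature_ordering_tag"]
    if expect_ordering_tag is not None and tag != expect_ordering_tag:
        raise FeatureContractError(
            f"{path}: archive ordering tag {tag!r} does not match expected "
            f"{expect_ordering_tag!r}")
    config = ModelConfig(**meta["config"])
    return TrainedModel(
        config=config,
        estimator=payload["estimator"],
        scaler=payload["scaler"],
        selected_features=np.asarray(meta["selected_features"], dtype=int),
        feature_ordering_tag=tag,
        n_features_in=int(meta["n_features_in"]),
        fingerprint=meta["fingerprint"],
    )


# ---------------------------------------------------------------------------
# Hyperparameter grid utility
# ---------------------------------------------------------------------------

def grid_search(base_config: ModelConfig, dataset: LabeledDataset,
                param_grid: dict[str, list], k_folds: int = 5,
                seed: int = 0) -> tuple[ModelConfig, list[dict[str, Any]]]:
    """Exhaustive small-grid search by cross-validated ROC area.

    Returns the best configuration and a table of every point tried.  Meant
    for modest grids (e.g. gamma/cost of the RBF machine); the reported
    settings are the defaults, so this is a convenience, not a requirement.
    """
    from itertools import product

    from .evaluation import cross_validate

    names = sorted(param_grid)
    results: list[dict[str, Any]] = []
    best_config, best_aroc = base_config, -np.inf
    for combo in product(*(param_grid[name] for name in names)):
        overrides = dict(zip(names, combo))
        config = ModelConfig(
            algorithm=base_config.algorithm,
            hyperparameters={**base_config.hyperparameters, **overrides},
            use_feature_selection=base_config.use_feature_selection,
            seed=base_config.seed,
        )
        metrics, _ = cross_validate(config, dataset, k_folds=k_folds, seed=seed)
        results.append({**overrides, "aroc": metrics.aroc})
        if metrics.aroc is not None and metrics.aroc > best_aroc:
            best_config, best_aroc = config, metrics.aroc
    return best_config, results
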