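"""Seven-classifier training with 10-fold CV model selection, the
intersection-of-seven ensemble, and scaled permutation feature importance.

Model selection: the training rows are split into k random (unstratified)
folds; every hyperparameter setting in an algorithm's grid is trained on k-1
folds and scored by F1 on the held fold; the setting with the best mean F1
wins, ties broken by grid order. The winning setting is then refitted on the
full training set.

Prediction scores are the positive-class probability where the estimator
provides one, and a rank-preserving logistic squashing of the decision margin
for the SVMs; either way 0.5 is the decision boundary and the threshold is
inclusive (score >= 0.5 -> true).
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, FeatureContractError, LncSiftError

logger = logging.getLogger(__name__)

ALGORITHM_NAMES = (
    "logistic_regression",
    "knn",
    "decision_tree",
    "random_forest",
    "naive_bayes",
    "linear_svm",
    "rbf_svm",
)

LABEL_COLUMN = "label"
DEFAULT_FOLDS = 10


@dataclass
class AlgorithmSpec:
    """One of the seven algorithms plus its hyperparameter grid."""

    name: str
    grid: dict[str, list]

    def __post_init__(self) -> None:
        if self.name not in ALGORITHM_NAMES:
            raise ConfigurationError(
                f"unknown algorithm {self.name!r}; expected one of {ALGORITHM_NAMES}"
            )
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ConfigurationError(f"{self.name}: hyperparameter grid is empty")

    def settings(self) -> list[dict]:
        """Grid settings in deterministic order (itertools product of the
        grid's insertion order); this order breaks mean-F1 ties."""
        keys = list(self.grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]


def default_algorithm_specs() -> list[AlgorithmSpec]:
    """The seven algorithms with small default grids (config-overridable)."""
    return [
        AlgorithmSpec("logistic_regression", {"C": [0.1, 1.0, 10.0]}),
        AlgorithmSpec("knn", {"n_neighbors": [5, 15, 51]}),
        AlgorithmSpec("decision_tree", {"max_depth": [None, 5, 10]}),
        AlgorithmSpec(
            "random_forest", {"n_estimators": [100, 300], "max_depth": [None, 10]}
        ),
        AlgorithmSpec("naive_bayes", {"var_smoothing": [1e-9]}),
        AlgorithmSpec("linear_svm", {"C": [0.1, 1.0]}),
        AlgorithmSpec("rbf_svm", {"C": [1.0, 10.0], "gamma": ["scale", 0.1]}),
    ]


def make_estimator(name: str, params: dict, seed: int = 0):
    """Instantiate a scikit-learn estimator for one grid setting."""
    if name == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "naive_bayes":
        return GaussianNB(**params)
    if name == "linear_svm":
        return LinearSVC(random_state=seed, **params)
    if name == "rbf_svm":
        return SVC(kernel="rbf", random_state=seed, **params)
    raise ConfigurationError(f"unknown algorithm {name!r}")


def _split_xy(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if LABEL_COLUMN not in data.columns:
        raise ConfigurationError(f"labeled table must have a {LABEL_COLUMN!r} column")
    feature_names = [c for c in data.columns if c != LABEL_COLUMN]
    X = data[feature_names].to_numpy(dtype=float)
    y = data[LABEL_COLUMN].to_numpy(dtype=int)
    if np.isnan(X).any():
        bad = np.where(np.isnan(X).any(axis=1))[0]
        raise FeatureContractError(f"NaN feature values in rows: {bad[:10].tolist()}")
    return X, y, feature_names


def _scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    # margin-based models: logistic squashing of the decision value keeps the
    # ranking (all that AUROC needs) and puts the boundary at 0.5
    return expit(estimator.decision_function(X))


@dataclass
class CVResult:
    """Per-setting mean/sd of F1 across folds and the selected setting."""

    algorithm: str
    settings: list[dict]
    mean_f1: list[float]
    sd_f1: list[float]
    selected_index: int

    @property
    def selected_setting(self) -> dict:
        return self.settings[self.selected_index]

    @property
    def selected_mean_f1(self) -> float:
        return self.mean_f1[self.selected_index]


def cross_validate_select(
    data: pd.DataFrame,
    spec: AlgorithmSpec,
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
    stratified: bool = False,
) -> CVResult:
    """Select the grid setting with the best mean F1 over k random folds."""
    X, y, _ = _split_xy(data)
    if len(y) < k:
        raise ConfigurationError(f"need at least k={k} rows, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise ConfigurationError("cross-validation needs both classes present")
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    folds = list(splitter.split(X, y))
    settings = spec.settings()
    means, sds = [], []
    for params in settings:
        scores = []
        for train_idx, test_idx in folds:
            est = make_estimator(spec.name, params, seed=seed)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[train_idx], y[train_idx])
                pred = (_scores(est, X[test_idx]) >= 0.5).astype(int)
                scores.append(f1_score(y[test_idx], pred, zero_division=0))
            except ValueError as exc:
                logger.warning(
                    "%s %s failed on a fold (%s); scored F1=0", spec.name, params, exc
                )
                scores.append(0.0)
        means.append(float(np.mean(scores)))
        sds.append(float(np.std(scores)))
    selected = int(np.argmax(means))  # argmax returns the first max: grid order
    return CVResult(spec.name, settings, means, sds, selected)


@dataclass
class TrainedModel:
    """A fitted classifier with its selected hyperparameters and metadata."""

    algorithm: str
    params: dict
    estimator: object
    feature_names: list[str]
    n_training_rows: int
    seed: int

    def predict_frame(self, features: pd.DataFrame) -> pd.DataFrame:
        X = _check_features(features, self.feature_names)
        s = _scores(self.estimator, X)
        return pd.DataFrame(
            {"label": (s >= 0.5).astype(int), "score": s}, index=features.index
        )

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "algorithm": self.algorithm,
            "params": {
                k: (None if v is None else v) for k, v in self.params.items()
            },
            "feature_names": self.feature_names,
            "n_training_rows": self.n_training_rows,
            "seed": self.seed,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
        joblib.dump(self.estimator, directory / "estimator.joblib")

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        estimator = joblib.load(directory / "estimator.joblib")
        return cls(
            algorithm=meta["algorithm"],
            params=meta["params"],
            estimator=estimator,
            feature_names=meta["feature_names"],
            n_training_rows=meta["n_training_rows"],
            seed=meta["seed"],
        )


def _check_features(features: pd.DataFrame, expected: Sequence[str]) -> np.ndarray:
    cols = [c for c in features.columns if c != LABEL_COLUMN]
    if cols != list(expected):
        raise FeatureContractError(
            f"feature columns {cols} do not match the training order {list(expected)}"
        )
    X = features[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = np.where(np.isnan(X).any(axis=1))[0]
        raise FeatureContractError(f"NaN feature values in rows: {bad[:10].tolist()}")
    return X


def train_final(
    data: pd.DataFrame, spec: AlgorithmSpec, params: dict, seed: int = 0
) -> TrainedModel:
    """Fit the selected setting on the whole training table."""
    X, y, feature_names = _split_xy(data)
    if len(np.unique(y)) < 2:
        raise LncSiftError("cannot train on single-class data")
    est = make_estimator(spec.name, params, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return TrainedModel(
        algorithm=spec.name,
        params=params,
        estimator=est,
        feature_names=feature_names,
        n_training_rows=len(y),
        seed=seed,
    )


def train_selected(
    data: pd.DataFrame,
    spec: AlgorithmSpec,
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
    stratified: bool = False,
) -> tuple[TrainedModel, CVResult]:
    """Convenience: CV-select then refit on the full table."""
    cv = cross_validate_select(data, spec, k=k, seed=seed, stratified=stratified)
    return train_final(data, spec, cv.selected_setting, seed=seed), cv


def predict(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Per-row (label, score); label = (score >= 0.5), boundary inclusive."""
    return model.predict_frame(features)


@dataclass
class EnsembleModel:
    """All seven trained models; positive only on unanimous agreement."""

    members: list[TrainedModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.algorithm for m in self.members]
        if sorted(names) != sorted(ALGORITHM_NAMES):
            raise ConfigurationError(
                f"ensemble needs exactly one model per algorithm in "
                f"{ALGORITHM_NAMES}; got {names}"
            )
        orders = {tuple(m.feature_names) for m in self.members}
        if len(orders) != 1:
            raise ConfigurationError("ensemble members disagree on feature order")

    def save(self, directory) -> None:
        directory = Path(directory)
        for m in self.members:
            m.save(directory / m.algorithm)

    @classmethod
    def load(cls, directory) -> "EnsembleModel":
        directory = Path(directory)
        return cls([TrainedModel.load(directory / name) for name in ALGORITHM_NAMES])


def ensemble_predict(ens: EnsembleModel, features: pd.DataFrame) -> pd.Series:
    """1 iff every member predicts 1 (exact intersection of positive sets)."""
    votes = np.column_stack(
        [m.predict_frame(features)["label"].to_numpy() for m in ens.members]
    )
    return pd.Series(votes.all(axis=1).astype(int), index=features.index, name="label")


def train_ensemble(
    data: pd.DataFrame,
    specs: Sequence[AlgorithmSpec] | None = None,
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
    stratified: bool = False,
) -> tuple[EnsembleModel, dict[str, CVResult]]:
    specs = list(specs) if specs is not None else default_algorithm_specs()
    members, cvs = [], {}
    for spec in specs:
        model, cv = train_selected(data, spec, k=k, seed=seed, stratified=stratified)
        members.append(model)
        cvs[spec.name] = cv
    return EnsembleModel(members), cvs


def permutation_importance(
    model: TrainedModel,
    data: pd.DataFrame,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation feature importance, scaled so the top feature is 1.0.

    Raw importance of a feature is the mean drop in F1 (over ``n_repeats``
    shuffles of that column) relative to the unshuffled baseline. Negative raw
    scores are floored at 0 before dividing by the maximum; if no feature has
    positive raw importance the result is all zeros with a warning.
    """
    if n_repeats < 1:
        raise ConfigurationError("n_repeats must be >= 1")
    X, y, feature_names = _split_xy(data)
    if feature_names != model.feature_names:
        raise FeatureContractError(
            f"feature columns {feature_names} do not match the training order "
            f"{model.feature_names}"
        )
    rng = np.random.default_rng(seed)
    baseline = f1_score(y, (_scores(model.estimator, X) >= 0.5), zero_division=0)
    raw = np.zeros(len(feature_names))
    for j in range(len(feature_names)):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            f1 = f1_score(y, (_scores(model.estimator, Xp) >= 0.5), zero_division=0)
            drops.append(baseline - f1)
        raw[j] = np.mean(drops)
    raw = np.maximum(raw, 0.0)
    top = raw.max()
    if top <= 0:
        logger.warning("no feature has positive permutation importance")
        return {name: 0.0 for name in feature_names}
    return {name: float(v / top) for name, v in zip(feature_names, raw)}
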