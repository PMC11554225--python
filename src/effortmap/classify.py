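"""Random-forest fishing classifier and speed-cutoff baselines.

The forest follows the standard bagging recipe: K trees, each grown on a
bootstrap sample of size N (the training size), each split choosing the
best of m randomly drawn candidate features, nodes grown down to a minimum
size; class predictions are the majority vote of the trees' class votes,
with exact ties resolved toward *fishing* (conservative for value
attribution).  Generalisation error is tracked out-of-bag (OOB): each
sample is scored by the trees whose bootstrap missed it.

Backed by :class:`sklearn.ensemble.RandomForestClassifier`; the vote over
trees is taken explicitly over the fitted ensemble so the prediction
contract is the vote, not sklearn's probability averaging.

Cross-validation is grouped by trip: adjacent 1-minute pings are
near-duplicates, so ungrouped folds leak and inflate scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold

from .features import FEATURE_NAMES

DEFAULT_SPEED_CUTOFF_KN = 5.0

#: Published speed bands (knots) usually associated with fishing, by gear.
GEAR_SPEED_PRESETS = {
    "scallop_dredge": (2.5, 6.0),
    "otter_trawl": (2.0, 4.0),
    "sink_gillnet": (0.1, 1.3),
}


@dataclass
class ForestConfig:
    """Hyperparameters of the forest.

    ``m_try=None`` means sqrt(p), the usual classification default;
    ``max_depth=None`` grows trees until ``min_node_size``.
    """

    n_trees: int = 300
    max_depth: int | None = None
    m_try: int | None = None
    min_node_size: int = 1
    seed: int = 0


@dataclass
class Metrics:
    """Binary classification metrics from the 2x2 confusion table."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self):
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self):
        return (self.tp + self.tn) / self.n

    @property
    def balanced_accuracy(self):
        rec_pos = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        rec_neg = self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0
        return (rec_pos + rec_neg) / 2.0

    def as_dict(self):
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
        }


@dataclass
class FittedForest:
    config: ForestConfig
    selected_features: list
    estimator: RandomForestClassifier
    oob_error: float
    feature_importances: dict = field(default_factory=dict)


def _make_estimator(config: ForestConfig, p: int, oob: bool = True):
    m = config.m_try if config.m_try is not None else "sqrt"
    if isinstance(m, int) and not 1 <= m <= p:
        raise ValueError(f"m_try={m} outside [1, {p}]")
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features=m,
        min_samples_leaf=config.min_node_size,
        bootstrap=True,
        oob_score=oob,
        random_state=config.seed,
        n_jobs=1,
    )


def train(
    features: pd.DataFrame,
    labels,
    config: ForestConfig | None = None,
    feature_names: list | None = None,
) -> FittedForest:
    """Fit the forest on labelled feature vectors.

    ``features`` must contain every column in ``feature_names`` (default:
    the full candidate set) with no missing values; ``labels`` is boolean
    fishing truth.  Single-class input raises ``ValueError``.  Returns the
    fitted ensemble with OOB error and normalised feature importances.
    """
    config = config or ForestConfig()
    names = list(feature_names or FEATURE_NAMES)
    X = features[names].to_numpy(float)
    y = np.asarray(labels, dtype=bool)
    if np.isnan(X).any():
        raise ValueError("missing feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    est = _make_estimator(config, p=len(names))
    with warnings.catch_warnings():
        # few trees can leave some samples with no OOB vote; fine for small K
        warnings.simplefilter("ignore", UserWarning)
        est.fit(X, y)
    imp = est.feature_importances_
    s = imp.sum()
    imp = imp / s if s > 0 else np.full_like(imp, 1.0 / len(imp))
    return FittedForest(
        config=config,
        selected_features=names,
        estimator=est,
        oob_error=float(1.0 - est.oob_score_),
        feature_importances=dict(zip(names, imp.tolist())),
    )


def predict(model: FittedForest, features: pd.DataFrame):
    """Majority vote over the ensemble's trees.

    Returns ``(labels, vote_fraction)`` where ``vote_fraction`` is the share
    of trees voting *fishing*; exact 0.5 ties classify as fishing.  A
    missing feature column raises ``KeyError``.
    """
    missing = [c for c in model.selected_features if c not in features.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    X = features[model.selected_features].to_numpy(float)
    fish_idx = list(model.estimator.classes_).index(True)
    votes = np.zeros(len(X))
    for tree in model.estimator.estimators_:
        votes += tree.predict(X) == model.estimator.classes_[fish_idx]
    frac = votes / len(model.estimator.estimators_)
    return frac >= 0.5, frac


def tune(
    features: pd.DataFrame,
    labels,
    groups,
    n_trees_grid=(50, 150, 300),
    max_depth_grid=(8, None),
    cv_folds: int = 5,
    base: ForestConfig | None = None,
    feature_names: list | None = None,
) -> ForestConfig:
    """Pick ``(n_trees, max_depth)`` by grouped cross-validated AUC.

    Folds are grouped by trip so no trip contributes pings to both sides of
    a split.  Folds whose training side has one class are skipped with a
    warning.  Ties (identical mean AUC) break toward fewer trees, then
    shallower depth.
    """
    base = base or ForestConfig()
    names = list(feature_names or FEATURE_NAMES)
    X = features[names].to_numpy(float)
    y = np.asarray(labels, dtype=bool)
    groups = np.asarray(groups)
    n_groups = len(np.unique(groups))
    cv = GroupKFold(n_splits=min(cv_folds, n_groups))

    grid = [(k, d) for k in n_trees_grid for d in max_depth_grid]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    scores = {}
    for k, d in grid:
        cfg = ForestConfig(n_trees=k, max_depth=d, m_try=base.m_try,
                           min_node_size=base.min_node_size, seed=base.seed)
        fold_scores = []
        for tr, te in cv.split(X, y, groups):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                warnings.warn("tune: single-class fold skipped")
                continue
            est = _make_estimator(cfg, p=len(names), oob=False)
            est.fit(X[tr], y[tr])
            proba = est.predict_proba(X[te])[:, list(est.classes_).index(True)]
            fold_scores.append(roc_auc_score(y[te], proba))
        scores[(k, d)] = float(np.mean(fold_scores)) if fold_scores else -np.inf

    best = max(scores.values())
    ties = [kd for kd, s in scores.items() if s >= best - 1e-12]
    k, d = min(ties, key=lambda kd: (kd[0], np.inf if kd[1] is None else kd[1]))
    return ForestConfig(n_trees=k, max_depth=d, m_try=base.m_try,
                        min_node_size=base.min_node_size, seed=base.seed)


def select_features(
    features: pd.DataFrame,
    labels,
    groups,
    config: ForestConfig | None = None,
    candidates: list | None = None,
    tolerance: float = 0.005,
    cv_folds: int = 5,
):
    """Recursive feature elimination with grouped cross-validation.

    Repeatedly drops the least-important feature, recording the grouped-CV
    accuracy at each subset size, then returns the smallest subset whose
    accuracy is within ``tolerance`` of the best.  Returns
    ``(selected, curve)`` with the curve as a list of
    ``(size, accuracy, subset)`` from p down to 1, and the selected subset
    ordered by importance (descending) at the final refit.
    """
    config = config or ForestConfig()
    current = list(candidates or FEATURE_NAMES)
    if len(current) < 2:
        raise ValueError("need at least 2 candidate features")
    y = np.asarray(labels, dtype=bool)
    groups = np.asarray(groups)
    cv = GroupKFold(n_splits=min(cv_folds, len(np.unique(groups))))

    curve = []
    while current:
        X = features[current].to_numpy(float)
        accs = []
        for tr, te in cv.split(X, y, groups):
            if len(np.unique(y[tr])) < 2:
                continue
            est = _make_estimator(config, p=len(current), oob=False)
            est.fit(X[tr], y[tr])
            accs.append(float((est.predict(X[te]) == y[te]).mean()))
        acc = float(np.mean(accs)) if accs else np.nan
        curve.append((len(current), acc, list(current)))
        if len(current) == 1:
            break
        est = _make_estimator(config, p=len(current), oob=False)
        est.fit(X, y)
        drop = current[int(np.argmin(est.feature_importances_))]
        current = [c for c in current if c != drop]

    best = max(acc for _, acc, _ in curve)
    chosen = min(
        (size, subset) for size, acc, subset in curve if acc >= best - tolerance
    )
    subset = chosen[1]
    est = _make_estimator(config, p=len(subset), oob=False)
    est.fit(features[subset].to_numpy(float), y)
    order = np.argsort(est.feature_importances_)[::-1]
    return [subset[i] for i in order], curve


def speed_cutoff(sog, cutoff: float = DEFAULT_SPEED_CUTOFF_KN):
    """Baseline rule: fishing iff speed over ground <= cutoff knots.

    Exactly at the cutoff counts as fishing (speeds above the cutoff
    indicate non-fishing activity).
    """
    return np.asarray(sog, dtype=float) <= cutoff


def evaluate(predicted, truth) -> Metrics:
    """Confusion-table metrics of predicted vs true fishing labels."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("length mismatch between predictions and truth")
    return Metrics(
        tp=int((predicted & truth).sum()),
        fp=int((predicted & ~truth).sum()),
        fn=int((~predicted & truth).sum()),
        tn=int((~predicted & ~truth).sum()),
    )


def save_model(model: FittedForest, path):
    """Persist estimator (joblib) plus a JSON sidecar with config, selected
    features, importances and OOB error."""
    path = str(path)
    joblib.dump(model.estimator, path)
    meta = {
        "format_version": 1,
        "config": asdict(model.config),
        "selected_features": model.selected_features,
        "oob_error": model.oob_error,
        "feature_importances": model.feature_importances,
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path) -> FittedForest:
    path = str(path)
    est = joblib.load(path)
    with open(path + ".json") as fh:
        meta = json.load(fh)
    return FittedForest(
        config=ForestConfig(**meta["config"]),
        selected_features=meta["selected_features"],
        estimator=est,
        oob_error=meta["oob_error"],
        feature_importances=meta["feature_importances"],
    )
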