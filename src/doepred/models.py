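"""Nested cross-validated gradient-boosted DOE models.

Each DOE class (activator / inhibitor / other) gets a one-vs-rest binary
XGBoost model trained under nested 8-fold cross-validation: the outer
loop holds out one fold; within each outer training set an inner 8-fold
split yields eight models, each early-stopped on its inner validation
fold; all eight predict the outer holdout and their probabilities are
averaged.  Every item therefore receives exactly one holdout prediction
per class from models that never saw its row in training or validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._streams import stream

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "make_cv_plan",
    "check_no_leakage",
    "NestedCVClassifier",
    "train_nested",
    "novelty_split_train",
    "write_run_log",
]


@dataclass(frozen=True)
class CVPlan:
    """Fold bookkeeping for nested cross-validation.

    ``outer[i]`` is item i's outer fold; ``inner[i, o]`` is its inner fold
    within outer round ``o`` (or -1 when the item is in round o's holdout).
    """

    items: np.ndarray
    outer: np.ndarray
    inner: np.ndarray  # shape (n_items, k_outer)
    k_outer: int
    k_inner: int
    seed: int

    def holdout(self, o: int) -> np.ndarray:
        return np.flatnonzero(self.outer == o)

    def inner_train(self, o: int, i: int) -> np.ndarray:
        col = self.inner[:, o]
        return np.flatnonzero((col >= 0) & (col != i))

    def inner_valid(self, o: int, i: int) -> np.ndarray:
        return np.flatnonzero(self.inner[:, o] == i)


def make_cv_plan(items, seed: int, k_outer: int = 8, k_inner: int = 8) -> CVPlan:
    """Randomly assign items to outer folds and, per outer round, inner folds.

    Splits are unstratified (items are shuffled and dealt round-robin), so
    at least ``k_outer * k_inner`` items are required for every inner fold
    to be non-empty.
    """
    items = np.asarray(items)
    n = len(items)
    minimum = k_outer * k_inner
    if n < minimum:
        raise ValueError(f"nested {k_outer}x{k_inner} CV needs at least {minimum} items, got {n}")
    rng = stream(seed, "cv-plan")
    order = rng.permutation(n)
    outer = np.empty(n, dtype=int)
    outer[order] = np.arange(n) % k_outer
    inner = np.full((n, k_outer), -1, dtype=int)
    for o in range(k_outer):
        train_idx = np.flatnonzero(outer != o)
        sub = rng.permutation(len(train_idx))
        inner[train_idx[sub], o] = np.arange(len(train_idx)) % k_inner
    return CVPlan(items=items, outer=outer, inner=inner, k_outer=k_outer, k_inner=k_inner, seed=seed)


def check_no_leakage(plan: CVPlan) -> bool:
    """Verify no model that predicts an item could have trained on it.

    The models predicting item i are the k_inner models of its outer
    round; none of their training or early-stopping validation sets may
    contain i.  Also checks the partition properties.
    """
    n = len(plan.items)
    for o in range(plan.k_outer):
        hold = set(plan.holdout(o))
        cover = set()
        for i in range(plan.k_inner):
            tr = set(plan.inner_train(o, i))
            va = set(plan.inner_valid(o, i))
            if (tr | va) & hold:
                return False
            if tr & va:
                return False
            cover |= tr | va
        if cover != set(range(n)) - hold:
            return False
    if sorted(np.unique(plan.outer)) != list(range(plan.k_outer)):
        return False
    return True


_XGB_DEFAULTS = dict(tree_method="hist", max_bin=64, n_jobs=1, verbosity=0)


class NestedCVClassifier(ClassifierMixin, BaseEstimator):
    """One binary DOE model under nested k x k cross-validation.

    ``fit`` trains ``k_outer * k_inner`` XGBoost models
    (min_child_weight=10, early stopping after 10 rounds without
    validation log-loss improvement, other hyperparameters at library
    defaults apart from histogram settings) and stores inner-fold-averaged
    holdout probabilities for every training item in ``oof_proba_``.
    ``predict_proba`` on new data averages over all trained models.

    Parameters
    ----------
    k_outer, k_inner : fold counts (8 x 8 by default).
    min_child_weight : minimum hessian per leaf, guards against overly
        complex splits.
    early_stopping_rounds : patience for validation log-loss.
    n_estimators : boosting-round cap.
    random_state : seed for fold assignment and the learner.
    cv_plan : optional pre-built :class:`CVPlan`, shared across the
        per-class models so their folds coincide.
    """

    def __init__(self, k_outer: int = 8, k_inner: int = 8, min_child_weight: float = 10.0,
                 early_stopping_rounds: int = 10, n_estimators: int = 100,
                 random_state: int = 0, cv_plan: CVPlan | None = None,
                 xgb_params: dict | None = None):
        self.k_outer = k_outer
        self.k_inner = k_inner
        self.min_child_weight = min_child_weight
        self.early_stopping_rounds = early_stopping_rounds
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.cv_plan = cv_plan
        self.xgb_params = xgb_params

    def _model_config(self) -> dict:
        cfg = dict(_XGB_DEFAULTS)
        cfg.update(
            n_estimators=self.n_estimators,
            min_child_weight=self.min_child_weight,
            early_stopping_rounds=self.early_stopping_rounds,
            eval_metric="logloss",
            objective="binary:logistic",
            random_state=self.random_state,
        )
        if self.xgb_params:
            cfg.update(self.xgb_params)
        return cfg

    def fit(self, X, y):
        X_arr, index = _as_array(X)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1 (one-vs-rest per DOE class)")
        plan = self.cv_plan
        if plan is None:
            plan = make_cv_plan(index, seed=self.random_state, k_outer=self.k_outer, k_inner=self.k_inner)
        if len(plan.items) != len(y):
            raise ValueError("cv_plan does not match the data")

        models: dict[tuple[int, int], xgb.XGBClassifier] = {}
        oof = np.full(len(y), np.nan)
        oof_margin = np.full(len(y), np.nan)
        cfg = self._model_config()
        for o in range(plan.k_outer):
            hold = plan.holdout(o)
            fold_proba = np.zeros((len(hold), plan.k_inner))
            fold_margin = np.zeros((len(hold), plan.k_inner))
            for i in range(plan.k_inner):
                tr = plan.inner_train(o, i)
                va = plan.inner_valid(o, i)
                if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                    raise ValueError(
                        f"class absent in inner fold (outer {o}, inner {i}); "
                        "too few positives for an unstratified split — consider "
                        "stratifying or merging classes")
                clf = xgb.XGBClassifier(**cfg)
                clf.fit(X_arr[tr], y[tr], eval_set=[(X_arr[va], y[va])], verbose=False)
                models[(o, i)] = clf
                fold_proba[:, i] = clf.predict_proba(X_arr[hold])[:, 1]
                booster = clf.get_booster()
                fold_margin[:, i] = booster.predict(xgb.DMatrix(X_arr[hold], missing=np.nan),
                                                    output_margin=True)
            oof[hold] = fold_proba.mean(axis=1)
            oof_margin[hold] = fold_margin.mean(axis=1)

        self.plan_ = plan
        self.models_ = models
        self.oof_proba_ = oof
        self.oof_margin_ = oof_margin
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X_arr.shape[1]
        self.feature_names_ = list(X.columns) if isinstance(X, pd.DataFrame) else None
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "models_")
        X_arr, _ = _as_array(X)
        p = np.mean([m.predict_proba(X_arr)[:, 1] for m in self.models_.values()], axis=0)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def oof_predictions(self, class_name: str = "positive") -> pd.DataFrame:
        """Tidy holdout-prediction table (item, class, probability, outer fold)."""
        check_is_fitted(self, "models_")
        return pd.DataFrame({
            "item": self.plan_.items,
            "doe": class_name,
            "probability": self.oof_proba_,
            "outer_fold": self.plan_.outer,
            "n_inner_models": self.plan_.k_inner,
        })

    def attributions(self, X=None) -> tuple[np.ndarray, np.ndarray]:
        """Additive per-feature contributions for the holdout predictions.

        ``X`` is the design matrix the model was fit on (kept around
        automatically by :meth:`fit_attributed`).  Returns ``(contribs,
        base)`` where ``contribs`` is (n_items, n_features) and ``base``
        the per-item expected margin, averaged over the inner models of
        each item's outer round; per model, base + sum(contribs) equals
        the model's margin output exactly (TreeSHAP additivity), so the
        averaged quantities satisfy base + sum(contribs) == mean
        inner-model margin.
        """
        check_is_fitted(self, "models_")
        if X is not None:
            X_arr = _as_array(X)[0]
        elif getattr(self, "_X_cache_", None) is not None:
            X_arr = self._X_cache_
        else:
            raise RuntimeError("pass X or fit via fit_attributed to compute attributions")
        if X_arr.shape[0] != len(self.plan_.items):
            raise ValueError("X does not match the fitted design matrix")
        plan = self.plan_
        n, p = X_arr.shape
        contrib = np.zeros((n, p))
        base = np.zeros(n)
        for o in range(plan.k_outer):
            hold = plan.holdout(o)
            dm = xgb.DMatrix(X_arr[hold], missing=np.nan)
            acc = np.zeros((len(hold), p + 1))
            for i in range(plan.k_inner):
                acc += self.models_[(o, i)].get_booster().predict(dm, pred_contribs=True)
            acc /= plan.k_inner
            contrib[hold] = acc[:, :-1]
            base[hold] = acc[:, -1]
        return contrib, base

    def fit_attributed(self, X, y):
        """Fit and keep the design matrix so attributions can be computed."""
        self.fit(X, y)
        self._X_cache_ = _as_array(X)[0]
        return self


def write_run_log(est: "NestedCVClassifier", path) -> dict:
    """Write a reproducibility lockfile: frozen model config, seed, fold hashes.

    The fold hash digests the outer/inner assignments, so two runs that
    claim the same seed can be audited for identical splits.
    """
    import hashlib
    import json

    check_is_fitted(est, "models_")
    plan = est.plan_
    payload = {
        "model_config": est._model_config(),
        "seed": int(plan.seed),
        "k_outer": int(plan.k_outer),
        "k_inner": int(plan.k_inner),
        "n_items": int(len(plan.items)),
        "fold_hash": hashlib.sha256(plan.outer.tobytes() + plan.inner.tobytes()).hexdigest(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return payload


def _as_array(X) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.index.to_numpy()
    arr = np.asarray(X, dtype=float)
    return arr, np.arange(arr.shape[0])


def train_nested(X, labels: pd.DataFrame, plan: CVPlan | None = None,
                 seed: int = 0, **params) -> tuple[pd.DataFrame, dict]:
    """Train one-vs-rest nested-CV models for every DOE class.

    ``labels`` is a boolean DataFrame (one column per class) aligned to
    the rows of ``X``.  Folds are shared across classes so the per-class
    holdout predictions are comparable.  Returns the tidy prediction
    table and the fitted per-class estimators.
    """
    X_arr, index = _as_array(X)
    if plan is None:
        plan = make_cv_plan(index, seed=seed,
                            k_outer=params.pop("k_outer", 8), k_inner=params.pop("k_inner", 8))
    preds, fitted = [], {}
    for cls in labels.columns:
        est = NestedCVClassifier(cv_plan=plan, random_state=seed, **params)
        est.fit(X, labels[cls].astype(int).to_numpy())
        preds.append(est.oof_predictions(class_name=str(cls)))
        fitted[str(cls)] = est
    return pd.concat(preds, ignore_index=True), fitted


def novelty_split_train(X, y, novelty, holdout_fraction: float = 1 / 8,
                        k_inner: int = 8, seed: int = 0, **params) -> pd.DataFrame:
    """Generalization check: train on low-novelty genes, predict high-novelty.

    Genes are ranked by the novelty score (ties broken by item id for
    determinism); the top ``holdout_fraction`` is held out, an inner
    k-fold CV is run within the remaining genes (each fold model
    early-stops on its fold), and the averaged predictions on the holdout
    are returned.
    """
    if not (0.0 < holdout_fraction < 1.0):
        raise ValueError(f"holdout_fraction must be in (0, 1), got {holdout_fraction}")
    X_arr, index = _as_array(X)
    y = np.asarray(y).astype(int)
    novelty = np.asarray(novelty, dtype=float)
    order = np.lexsort((index, -novelty))  # descending novelty, ties by item id
    n_hold = int(round(holdout_fraction * len(y)))
    hold = order[:n_hold]
    train = order[n_hold:]

    rng = stream(seed, "novelty-split")
    fold = np.empty(len(train), dtype=int)
    fold[rng.permutation(len(train))] = np.arange(len(train)) % k_inner

    cfg = NestedCVClassifier(random_state=seed, **params)._model_config()
    proba = np.zeros((n_hold, k_inner))
    for i in range(k_inner):
        tr = train[fold != i]
        va = train[fold == i]
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            raise ValueError(f"class absent in inner fold {i}; consider stratifying")
        clf = xgb.XGBClassifier(**cfg)
        clf.fit(X_arr[tr], y[tr], eval_set=[(X_arr[va], y[va])], verbose=False)
        proba[:, i] = clf.predict_proba(X_arr[hold])[:, 1]
    return pd.DataFrame({
        "item": index[hold],
        "probability": proba.mean(axis=1),
        "novelty": novelty[hold],
        "label": y[hold],
    })
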