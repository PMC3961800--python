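"""The Random Forests Relapse Score (RFRS).

A bootstrap ensemble of classification trees votes 'relapse' or
'no relapse' for each sample; the fraction of trees voting relapse is
the RFRS, a continuous score in [0, 1].  For training samples the score
is computed from out-of-bag (OOB) votes only — each sample is scored by
the roughly one third of trees whose bootstrap excluded it — which
stands in for cross-validation.  An odd tree count guarantees a fully
deterministic majority in every vote.
"""

from __future__ import annotations

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .containers import InputError

POSITIVE = "relapse"
NEGATIVE = "no_relapse"

_ARCHIVE_VERSION = 1


class RfrsClassifier(BaseEstimator):
    """Random-forest relapse classifier with out-of-bag vote scores.

    Parameters
    ----------
    n_trees : int, default 100001
        Number of trees; must be odd so every majority vote is decided.
        The large default targets vote-fraction stability; a few
        thousand trees suffice for rank-based metrics.
    random_state : int, default 0

    Attributes
    ----------
    oob_scores_ : pandas.Series
        Per-training-sample RFRS from out-of-bag votes (NaN for any
        sample never out of bag).
    feature_importances_ : pandas.Series
        Gini (mean decrease in impurity) importance per feature.
    feature_names_ : list of str
        Features the forest was trained on, in order.
    """

    def __init__(self, n_trees: int = 100001, random_state: int = 0):
        self.n_trees = n_trees
        self.random_state = random_state

    # -- fitting -------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "RfrsClassifier":
        if self.n_trees % 2 == 0:
            raise InputError(f"n_trees must be odd, got {self.n_trees}")
        X = self._as_frame(X)
        y = np.asarray(y)
        y_bin = self._binarize(y)
        counts = np.bincount(y_bin, minlength=2)
        if counts.min() < 2:
            raise InputError(
                f"need >= 2 samples per class, got {counts[1]} relapse / {counts[0]} no-relapse"
            )
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features="sqrt",
            bootstrap=True,
            min_samples_leaf=1,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X.to_numpy(), y_bin)
        self.feature_names_ = list(X.columns)
        self.feature_importances_ = pd.Series(
            self.forest_.feature_importances_, index=self.feature_names_, name="gini_importance"
        )
        self.oob_scores_ = pd.Series(
            self._oob_vote_fractions(X.to_numpy()), index=X.index, name="rfrs"
        )
        return self

    def _oob_vote_fractions(self, Xv: np.ndarray) -> np.ndarray:
        n = Xv.shape[0]
        votes = np.zeros(n)
        counted = np.zeros(n)
        for tree, sampled in zip(self.forest_.estimators_, self.forest_.estimators_samples_):
            oob = np.ones(n, dtype=bool)
            oob[sampled] = False
            if not oob.any():
                continue
            pred = tree.predict(Xv[oob])
            votes[oob] += pred
            counted[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(counted > 0, votes / np.maximum(counted, 1), np.nan)

    # -- scoring -------------------------------------------------------

    def predict_score(self, X: pd.DataFrame) -> pd.Series:
        """RFRS for new samples: the fraction of all trees voting
        relapse.  Input columns may be a superset of the model's
        features; missing features are an error."""
        self._check_fitted()
        X = self._as_frame(X)
        missing = [f for f in self.feature_names_ if f not in X.columns]
        if missing:
            raise InputError(f"input is missing model features: {missing}")
        Xv = X[self.feature_names_].to_numpy()
        votes = np.zeros(Xv.shape[0])
        for tree in self.forest_.estimators_:
            votes += tree.predict(Xv)
        return pd.Series(votes / self.n_trees, index=X.index, name="rfrs")

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        self._check_fitted()
        joblib.dump({"version": _ARCHIVE_VERSION, "model": self}, path)

    @classmethod
    def load(cls, path) -> "RfrsClassifier":
        payload = joblib.load(path)
        if payload.get("version") != _ARCHIVE_VERSION:
            raise InputError(f"unsupported model archive version: {payload.get('version')}")
        return payload["model"]

    # -- helpers -------------------------------------------------------

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [str(c) for c in X.columns]
        return X

    @staticmethod
    def _binarize(y) -> np.ndarray:
        if y.dtype.kind in "USO":
            known = set(np.unique(y))
            if not known <= {POSITIVE, NEGATIVE}:
                raise InputError(f"labels must be {{{POSITIVE!r}, {NEGATIVE!r}}}, got {sorted(known)}")
            return (y == POSITIVE).astype(int)
        return np.asarray(y).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "forest_"):
            raise InputError("model is not fitted")


def train(X: pd.DataFrame, y, n_trees: int = 100001, seed: int = 0) -> RfrsClassifier:
    """Train an :class:`RfrsClassifier` (functional wrapper)."""
    return RfrsClassifier(n_trees=n_trees, random_state=seed).fit(X, y)


def score(model: RfrsClassifier, X: pd.DataFrame) -> pd.Series:
    """Score new samples with a trained model (functional wrapper)."""
    return model.predict_score(X)


def roc_auc(scores, labels) -> float:
    """ROC AUC as the Mann-Whitney probability that a random event
    sample outranks a random non-event sample, ties counted 1/2."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        labels = (labels == POSITIVE).astype(int)
    if len(np.unique(labels)) < 2:
        raise InputError("ROC AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
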