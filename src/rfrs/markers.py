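"""Array-based ER and HER2 status calling.

ER status is called from a single designated probe set; HER2 status
from the rank sum of four co-amplified HER2-region probe sets.  Cutoffs
separating negative from positive are the maximum score assigned to the
lower-mean component of a two-component Gaussian mixture fitted by EM —
the convention being that the top of the negative mode is itself a
member of the negative class, so positivity is strictly greater-than.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .containers import ExpressionMatrix, InputError


class ConvergenceError(RuntimeError):
    """A numerical fit degenerated (e.g. a mixture component collapsed)."""


def er_score(expr: ExpressionMatrix, er_feature_id: str) -> pd.Series:
    """Per-sample ER score: the linear intensity of the ER probe set."""
    if er_feature_id not in expr.values.columns:
        raise InputError(f"ER feature {er_feature_id!r} not present in expression matrix")
    return expr.values[er_feature_id].rename("er_score")


def her2_rank_sum(expr: ExpressionMatrix, feature_ids) -> pd.Series:
    """Per-sample HER2 score: sum of the sample's ascending ranks on
    each of the four HER2-region probe sets (average ranks on ties)."""
    feature_ids = list(feature_ids)
    if len(feature_ids) != 4:
        raise InputError(f"HER2 rank sum requires exactly 4 features, got {len(feature_ids)}")
    missing = [f for f in feature_ids if f not in expr.values.columns]
    if missing:
        raise InputError(f"HER2 features not present: {missing}")
    if expr.n_samples < 2:
        raise InputError("HER2 rank sum needs at least 2 samples")
    ranks = np.column_stack([rankdata(expr.values[f].to_numpy()) for f in feature_ids])
    return pd.Series(ranks.sum(axis=1), index=expr.values.index, name="her2_score")


class MixtureCutoff(BaseEstimator):
    """Univariate Gaussian-mixture cutoff between the lowest-mean
    component and the rest.

    Fits a ``n_components``-component normal mixture by EM (k-means
    initialization, multiple restarts, unequal variances) and sets the
    cutoff(s) at the maximum observed value assigned (by maximum
    responsibility) to each lower component.

    Attributes
    ----------
    cutoff_ : float
        Boundary between component 1 and 2 (the only boundary when
        ``n_components=2``).
    cutoffs_ : ndarray of shape (n_components - 1,)
        All inter-component boundaries, ascending.
    means_, weights_ : component parameters sorted by mean.
    """

    def __init__(self, n_components: int = 2, n_init: int = 50,
                 tol: float = 1e-6, min_weight: float = 0.01, random_state: int = 0):
        self.n_components = n_components
        self.n_init = n_init
        self.tol = tol
        self.min_weight = min_weight
        self.random_state = random_state

    def fit(self, scores) -> "MixtureCutoff":
        x = np.asarray(scores, dtype=float).ravel()
        if len(x) < 20:
            raise InputError(f"mixture cutoff needs >= 20 values, got {len(x)}")
        if x.var() == 0:
            raise InputError("mixture cutoff undefined for constant scores")
        gm = GaussianMixture(
            n_components=self.n_components,
            covariance_type="full",
            init_params="k-means++",
            n_init=self.n_init,
            tol=self.tol,
            random_state=self.random_state,
        ).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        weights = gm.weights_[order]
        if weights.min() < self.min_weight:
            raise ConvergenceError(
                "a mixture component collapsed (weight "
                f"{weights.min():.4f} < {self.min_weight}); the score "
                "distribution may not be multimodal — set a manual cutoff"
            )
        resp = gm.predict_proba(x[:, None])[:, order]
        comp = resp.argmax(axis=1)
        cutoffs = []
        for c in range(self.n_components - 1):
            assigned = x[comp <= c]
            if len(assigned) == 0:
                raise ConvergenceError(f"no values assigned to component {c + 1}")
            cutoffs.append(float(assigned.max()))
        self.cutoffs_ = np.array(cutoffs)
        self.cutoff_ = float(self.cutoffs_[0])
        self.means_ = gm.means_.ravel()[order]
        self.weights_ = weights
        self.sds_ = np.sqrt(gm.covariances_.reshape(-1)[order])
        self.assignments_ = comp
        return self


def mixture_cutoff(scores, n_components: int = 2, seed: int = 0) -> float:
    """Functional wrapper around :class:`MixtureCutoff`; returns the
    boundary between the first (lower-mean) and second components."""
    return MixtureCutoff(n_components=n_components, random_state=seed).fit(scores).cutoff_


def call_status(
    expr: ExpressionMatrix,
    er_feature_id: str,
    her2_feature_ids,
    seed: int = 0,
) -> pd.DataFrame:
    """Compute ER/HER2 scores, fit mixture cutoffs, and call status.

    Returns a DataFrame indexed by sample id with columns er_score,
    er_array, her2_score, her2_array, and attrs er_cutoff/her2_cutoff.
    A call is positive iff the score is strictly greater than the
    cutoff.
    """
    er = er_score(expr, er_feature_id)
    her2 = her2_rank_sum(expr, her2_feature_ids)
    er_cut = mixture_cutoff(er, seed=seed)
    her2_cut = mixture_cutoff(her2, seed=seed)
    out = pd.DataFrame(
        {
            "er_score": er,
            "er_array": np.where(er > er_cut, "+", "-"),
            "her2_score": her2,
            "her2_array": np.where(her2 > her2_cut, "+", "-"),
        }
    )
    out.attrs["er_cutoff"] = er_cut
    out.attrs["her2_cutoff"] = her2_cut
    return out
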