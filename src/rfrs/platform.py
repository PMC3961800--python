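"""Cross-platform application of a signature.

External cohorts (different array platforms) are mapped onto the
signature genes — choosing one probe per gene when several candidates
exist — and rescaled onto the training intensity distribution by
quantile mapping before scoring, so per-sample monotone distortions of
the external platform cannot change the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix, InputError
from .forest import roc_auc


class QuantileRescaler(BaseEstimator, TransformerMixin):
    """Quantile-map each sample's values onto a reference distribution.

    ``fit`` pools and sorts the reference (training) values; ``transform``
    replaces each external sample's values by the reference quantiles at
    the same within-sample rank fractions, preserving the rank order
    within every sample.
    """

    def fit(self, reference) -> "QuantileRescaler":
        ref = np.asarray(reference, dtype=float).ravel()
        ref = ref[np.isfinite(ref)]
        if ref.size < 2:
            raise InputError("reference distribution needs >= 2 values")
        self.reference_sorted_ = np.sort(ref)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "reference_sorted_"):
            raise InputError("rescaler is not fitted")
        frame = isinstance(X, pd.DataFrame)
        arr = X.to_numpy(dtype=float) if frame else np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        m = self.reference_sorted_.size
        ref_q = (np.arange(m) + 0.5) / m
        out = np.empty_like(arr)
        for i, row in enumerate(arr):
            if np.ptp(row) == 0:
                raise InputError(f"sample {i} is constant; quantile rescaling undefined")
            order = np.argsort(row, kind="stable")
            ranks = np.empty_like(order)
            ranks[order] = np.arange(len(row))
            q = (ranks + 0.5) / len(row)
            out[i] = np.interp(q, ref_q, self.reference_sorted_)
        if frame:
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return pd.DataFrame(out)


def rescale_to_reference(external: pd.DataFrame, reference) -> pd.DataFrame:
    """Functional wrapper around :class:`QuantileRescaler`."""
    return QuantileRescaler().fit(reference).transform(external)


@dataclass
class PlatformMap:
    """Chosen external feature per signature gene."""

    table: pd.DataFrame  # gene, chosen_feature, criterion, n_candidates
    missing: list[str]

    def chosen(self) -> dict[str, str]:
        return dict(zip(self.table["gene"], self.table["chosen_feature"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def choose_probe_per_gene(
    candidates: dict[str, list[str]],
    expr: ExpressionMatrix | pd.DataFrame,
    criterion: str = "variance",
    labels=None,
) -> PlatformMap:
    """Pick one external feature per gene from candidate probes.

    Criteria: 'variance' (default; needs no labels), 'mean', or 'auc'
    (univariate ROC AUC against ``labels``).  Genes with no candidates
    are reported missing; scoring should then fail fast listing them.
    """
    if not candidates:
        raise InputError("empty candidate map")
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    rows, missing = [], []
    for gene, feats in candidates.items():
        feats = [f for f in feats if f in values.columns]
        if not feats:
            missing.append(gene)
            continue
        if criterion == "variance":
            scores = {f: float(values[f].var()) for f in feats}
        elif criterion == "mean":
            scores = {f: float(values[f].mean()) for f in feats}
        elif criterion == "auc":
            if labels is None:
                raise InputError("criterion 'auc' requires labels")
            scores = {f: roc_auc(values[f], labels) for f in feats}
        else:
            raise InputError(f"unknown criterion {criterion!r}")
        best = max(sorted(feats), key=lambda f: scores[f])
        rows.append({"gene": gene, "chosen_feature": best,
                     "criterion": criterion, "n_candidates": len(feats)})
    return PlatformMap(pd.DataFrame(rows), missing)
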