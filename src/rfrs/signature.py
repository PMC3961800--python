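"""Compaction of the full-gene model into small signatures.

The top genes by Gini importance are clustered by k-means on their
standardized expression profiles across training samples; each cluster
contributes one primary gene (its most important member) and the rest
of the cluster as ranked alternates, available as substitutes when a
primary fails to migrate to another assay platform.  Excluded genes
(bad probe alignments, hypothetical proteins) are removed after
clustering, so exclusions can empty a cluster and reduce the primary
count below k — the mechanism that turns a k = 20 clustering into a
17-gene signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import InputError


@dataclass
class SignatureCluster:
    primary: str
    importance: float
    alternates: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class Signature:
    """Primary genes with ranked alternates.

    ``clusters`` are ordered by primary importance descending.
    """

    clusters: list[SignatureCluster]
    k_requested: int
    exclusions_applied: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def primaries(self) -> list[str]:
        return [c.primary for c in self.clusters]

    @property
    def alternates(self) -> list[str]:
        return [g for c in self.clusters for g, _ in c.alternates]

    def to_frame(self, n_alternates: int = 2) -> pd.DataFrame:
        """Wide table: primary, importance, alternate1, importance1, ..."""
        rows = []
        for c in self.clusters:
            row = {"primary": c.primary, "importance": c.importance}
            for i in range(n_alternates):
                if i < len(c.alternates):
                    g, imp = c.alternates[i]
                else:
                    g, imp = "N/A", np.nan
                row[f"alternate{i + 1}"] = g
                row[f"importance{i + 1}"] = imp
            rows.append(row)
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            rows.append({"primary": c.primary, "gene": c.primary,
                         "role": "primary", "importance": c.importance})
            for g, imp in c.alternates:
                rows.append({"primary": c.primary, "gene": g,
                             "role": "alternate", "importance": imp})
        return pd.DataFrame(rows)


def deduplicate_features(importance: pd.Series, feature_to_gene: dict[str, str]) -> pd.Series:
    """Collapse a feature-level importance ranking to gene level,
    keeping each gene's highest-importance feature.  Ties broken
    alphabetically by gene symbol for determinism."""
    df = pd.DataFrame({
        "feature": importance.index,
        "gene": [feature_to_gene.get(f, f) for f in importance.index],
        "importance": importance.to_numpy(dtype=float),
    })
    df = df.sort_values(["importance", "gene"], ascending=[False, True], kind="stable")
    best = df.drop_duplicates("gene", keep="first")
    out = pd.Series(best["importance"].to_numpy(), index=best["gene"].to_numpy(),
                    name="gini_importance")
    out.attrs["gene_to_feature"] = dict(zip(best["gene"], best["feature"]))
    return out


def compact(
    gene_importance: pd.Series,
    expr_genes: pd.DataFrame,
    k: int = 20,
    top_n: int = 100,
    exclusions=(),
    seed: int = 0,
    n_init: int = 100,
) -> Signature:
    """Build a signature from the ``top_n`` genes by importance.

    ``expr_genes`` is a samples x genes frame over the training samples
    (columns must cover the top genes).  Genes are clustered as points
    in sample space after per-gene z-scoring; within each cluster the
    excluded genes are removed, the highest-importance survivor becomes
    the primary and the rest become alternates ordered by importance.
    Clusters emptied by exclusions are dropped.
    """
    gene_importance = gene_importance.sort_values(ascending=False, kind="stable")
    # deterministic tie handling: alphabetical within equal importance
    order = sorted(gene_importance.index, key=lambda g: (-gene_importance[g], g))
    if top_n > len(order):
        raise InputError(f"top_n={top_n} exceeds available genes ({len(order)})")
    top = order[:top_n]
    if k > len(top):
        raise InputError(f"k={k} exceeds the candidate pool ({len(top)})")
    missing = [g for g in top if g not in expr_genes.columns]
    if missing:
        raise InputError(f"expression missing for top genes: {missing[:5]}")

    profiles = expr_genes[top].to_numpy(dtype=float).T  # genes x samples
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (profiles - mu) / sd

    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed).fit(z)
    labels = km.labels_

    exclusions = set(exclusions)
    clusters: list[SignatureCluster] = []
    for c in range(k):
        members = [g for g, lab in zip(top, labels) if lab == c and g not in exclusions]
        if not members:
            continue
        members.sort(key=lambda g: (-gene_importance[g], g))
        clusters.append(
            SignatureCluster(
                primary=members[0],
                importance=float(gene_importance[members[0]]),
                alternates=[(g, float(gene_importance[g])) for g in members[1:]],
            )
        )
    clusters.sort(key=lambda c: (-c.importance, c.primary))
    return Signature(
        clusters=clusters,
        k_requested=k,
        exclusions_applied=sorted(exclusions & set(top)),
        provenance={"top_n": top_n, "pool": top, "seed": seed,
                    "cluster_labels": dict(zip(top, (int(v) for v in labels)))},
    )


class SignatureCompactor:
    """Estimator-style wrapper around :func:`compact`.

    ``fit(expr_genes, importance)`` stores the resulting signature as
    ``signature_``; ``get_params``/``set_params`` follow the sklearn
    convention so the compactor drops into model-selection loops.
    """

    def __init__(self, k: int = 20, top_n: int = 100, exclusions=(),
                 random_state: int = 0):
        self.k = k
        self.top_n = top_n
        self.exclusions = exclusions
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "top_n": self.top_n,
                "exclusions": self.exclusions, "random_state": self.random_state}

    def set_params(self, **params) -> "SignatureCompactor":
        for key, value in params.items():
            if key not in self.get_params():
                raise InputError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, expr_genes: pd.DataFrame, gene_importance: pd.Series) -> "SignatureCompactor":
        self.signature_ = compact(
            gene_importance, expr_genes, k=self.k, top_n=self.top_n,
            exclusions=self.exclusions, seed=self.random_state,
        )
        return self


def eight_gene_variant(
    gene_importance: pd.Series,
    expr_genes: pd.DataFrame,
    exclusions=(),
    seed: int = 0,
) -> Signature:
    """Eight-gene signature: exclusions are removed from the ranking
    first, then the top 90 survivors are clustered with k = 8."""
    kept = gene_importance.drop(index=[g for g in exclusions if g in gene_importance.index])
    top_n = min(90, len(kept))
    return compact(kept, expr_genes, k=8, top_n=top_n, exclusions=(), seed=seed)
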