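"""Cohort assembly: duplicate removal, eligibility filtering, 10-year
outcome binarization, and study-balanced train/test splitting."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, ClinicalTable, ExpressionMatrix, InputError

logger = logging.getLogger(__name__)

RELAPSE = "relapse"
NO_RELAPSE = "no_relapse"
EXCLUDED_SHORT = "excluded_short_followup"
EXCLUDED_ZERO = "excluded_time_zero"


# ---------------------------------------------------------------------
# duplicate detection
# ---------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def detect_duplicates(
    expr: ExpressionMatrix,
    clinical: ClinicalTable | None = None,
    r_threshold: float = 0.99,
    study_precedence: list[str] | None = None,
) -> list[dict]:
    """Group duplicate samples and pick one representative per group.

    Samples are grouped if they share a patient identifier (clinical
    column ``patient_id``, when present) or if their pairwise Pearson
    correlation over all features exceeds ``r_threshold``.  Correlation
    is computed on log2-transformed values to stabilize it against
    intensity outliers.  Groups are the transitive closure of pairwise
    links.

    Returns a list of dicts with keys ``members`` (sorted sample ids)
    and ``representative``.  The representative is the member from the
    study listed earliest in ``study_precedence`` (default: order of
    first appearance in the clinical table), ties broken by input order.
    """
    ids = expr.sample_ids
    if len(ids) < 2:
        raise InputError("duplicate detection needs at least 2 samples")

    logx = expr.log2().to_numpy()
    sd = logx.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d sample(s) have zero variance across features; their "
            "correlations are undefined and treated as non-duplicate",
            int(degenerate.sum()),
        )
    uf = _UnionFind(ids)

    ok = np.flatnonzero(~degenerate)
    if len(ok) >= 2:
        corr = np.corrcoef(logx[ok])
        ii, jj = np.triu_indices(len(ok), k=1)
        hits = corr[ii, jj] > r_threshold
        for a, b in zip(ii[hits], jj[hits]):
            uf.union(ids[ok[a]], ids[ok[b]])

    if clinical is not None and "patient_id" in clinical.data.columns:
        for _, grp in clinical.data.groupby("patient_id"):
            members = [s for s in grp["sample_id"] if s in uf.parent]
            for other in members[1:]:
                uf.union(members[0], other)

    groups: dict[str, list[str]] = {}
    for s in ids:
        groups.setdefault(uf.find(s), []).append(s)

    order = {s: i for i, s in enumerate(ids)}
    study_of = {}
    if clinical is not None:
        study_of = dict(zip(clinical.data["sample_id"], clinical.data["study_id"]))
    if study_precedence is None and clinical is not None:
        study_precedence = list(dict.fromkeys(clinical.data["study_id"]))
    prec = {s: i for i, s in enumerate(study_precedence or [])}

    out = []
    for members in groups.values():
        if len(members) < 2:
            continue
        rep = min(members, key=lambda s: (prec.get(study_of.get(s), len(prec)), order[s]))
        out.append({"members": sorted(members, key=order.get), "representative": rep})
    out.sort(key=lambda g: order[g["members"][0]])
    return out


def deduplicate(expr, clinical, groups):
    """Drop all non-representative members of each duplicate group."""
    drop = set()
    for g in groups:
        drop.update(m for m in g["members"] if m != g["representative"])
    keep = [s for s in expr.sample_ids if s not in drop]
    return expr.subset(samples=keep), clinical.loc(keep)


# ---------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------

def filter_eligibility(clinical: ClinicalTable, array_status: pd.DataFrame) -> tuple[list[str], pd.DataFrame]:
    """Select the eligible cohort: LN-negative, chemo-naive,
    HER2-negative by array, and ER-positive.

    ER positivity requires both the clinical and array determinations
    when a clinical status is available; when clinical ER is missing the
    array call alone decides.  ``array_status`` must be indexed by
    sample id with columns ``er_array`` / ``her2_array`` in {'+', '-'}.

    Returns the eligible sample ids plus a per-sample exclusion-reason
    table.
    """
    df = clinical.data
    missing_cover = [s for s in df["sample_id"] if s not in array_status.index]
    if missing_cover:
        raise InputError(f"array status missing for samples: {missing_cover[:5]}")

    reasons = []
    eligible = []
    for _, row in df.iterrows():
        s = row["sample_id"]
        arr = array_status.loc[s]
        reason = None
        if row["ln_status"] == MISSING:
            reason = "ln_status_missing"
        elif row["ln_status"] != "negative":
            reason = "ln_positive"
        elif row["chemo"]:
            reason = "chemotherapy"
        elif arr["her2_array"] == "+":
            reason = "her2_array_positive"
        elif row["er_clinical"] == MISSING:
            if arr["er_array"] != "+":
                reason = "er_array_negative"
        elif row["er_clinical"] != "+" or arr["er_array"] != "+":
            reason = "er_discordant_or_negative"
        if reason is None:
            eligible.append(s)
        reasons.append({"sample_id": s, "eligible": reason is None, "reason": reason or ""})
    return eligible, pd.DataFrame(reasons)


# ---------------------------------------------------------------------
# 10-year binarization
# ---------------------------------------------------------------------

def binarize_ten_year(clinical: ClinicalTable, horizon: float = 10.0) -> pd.Series:
    """Classify each sample for the 10-year relapse endpoint.

    relapse: event in (0, horizon]; no_relapse: event-free with at least
    ``horizon`` years of follow-up; excluded_time_zero: immediately
    postoperative event (time = 0); excluded_short_followup: event-free
    but censored before ``horizon`` (kept for survival analysis only).
    Events after the horizon count as no_relapse — the patient was
    relapse-free through the full window.
    """
    df = clinical.data
    if (df["followup_years"] < 0).any():
        raise InputError("negative follow-up times")
    labels = []
    for _, row in df.iterrows():
        t, ev = row["followup_years"], row["relapse_event"]
        if ev and t == 0:
            labels.append(EXCLUDED_ZERO)
        elif ev and t <= horizon:
            labels.append(RELAPSE)
        elif t >= horizon:
            labels.append(NO_RELAPSE)
        else:
            labels.append(EXCLUDED_SHORT)
    return pd.Series(labels, index=df["sample_id"].to_numpy(), name="ten_year_class")


# ---------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------

@dataclass
class CohortSplit:
    train_ids: list[str]
    test_ids: list[str]
    report: pd.DataFrame = field(repr=False, default=None)


def stratified_split(
    strata: pd.DataFrame,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> CohortSplit:
    """Split samples into train/test, balancing study of origin and
    outcome class.

    ``strata`` needs columns sample_id, study_id and class (the 10-year
    label).  Within each (study x class) stratum a random subset goes to
    train; stratum quotas use largest-remainder allocation so the global
    train count equals ``round(train_fraction * n)`` whenever possible.
    Single-member strata go to train.  The split is reproducible under a
    fixed seed and invariant to input row order.
    """
    if not 0 < train_fraction <= 1:
        raise InputError("train_fraction must be in (0, 1]")
    df = strata.sort_values("sample_id").reset_index(drop=True)
    n = len(df)
    target = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)

    groups = []
    for (study, cls), grp in df.groupby(["study_id", "class"], sort=True):
        ids = list(grp["sample_id"])
        quota = train_fraction * len(ids)
        base = 1 if len(ids) == 1 else int(np.floor(quota))
        groups.append({"study": study, "class": cls, "ids": ids,
                       "base": base, "remainder": quota - np.floor(quota)})

    allocated = sum(g["base"] for g in groups)
    extra = target - allocated
    # hand out remaining train slots by largest remainder
    order = sorted(range(len(groups)),
                   key=lambda i: (-groups[i]["remainder"], groups[i]["study"], groups[i]["class"]))
    for i in order:
        if extra <= 0:
            break
        g = groups[i]
        if g["base"] < len(g["ids"]):
            g["base"] += 1
            extra -= 1

    train, test, rows = [], [], []
    for g in groups:
        ids = list(g["ids"])
        perm = rng.permutation(len(ids))
        k = min(g["base"], len(ids))
        tr = [ids[j] for j in sorted(perm[:k])]
        te = [ids[j] for j in sorted(perm[k:])]
        train += tr
        test += te
        rows.append({"study_id": g["study"], "class": g["class"],
                     "n": len(ids), "n_train": len(tr), "n_test": len(te)})
    report = pd.DataFrame(rows)
    return CohortSplit(sorted(train), sorted(test), report)
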