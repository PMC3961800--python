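"""Risk-group calibration for the relapse score.

Three components: (1) risk-group thresholds fitted by a 3-component
Gaussian mixture on the out-of-bag score distribution (the study's
thresholds were 0.333 and 0.606); (2) prevalence-adjusted per-group
relapse rates obtained by repeatedly down-sampling event samples until
the cohort matches a target population prevalence (15%) and averaging
over iterations; (3) a loess calibration curve mapping a score to an
estimated 10-year relapse likelihood with a 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import InputError
from .markers import ConvergenceError, MixtureCutoff

GROUPS = ("low", "intermediate", "high")

_ARCHIVE_VERSION = 1


@dataclass
class RiskThresholds:
    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not 0 < self.t_low < self.t_high < 1:
            raise InputError(
                f"thresholds must satisfy 0 < t_low < t_high < 1, got ({self.t_low}, {self.t_high})"
            )


#: thresholds fitted on the original training cohort
STUDY_THRESHOLDS = RiskThresholds(0.333, 0.606)


def fit_thresholds(oob_scores, seed: int = 0, quantile_fallback: bool = False) -> RiskThresholds:
    """Risk-group thresholds from the score distribution.

    Fits a 3-component Gaussian mixture (one component per risk group);
    each boundary is the maximum score assigned to the lower component.
    With ``quantile_fallback`` a degenerate fit falls back to tertiles
    instead of raising.
    """
    x = np.asarray(oob_scores, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 50:
        raise InputError(f"threshold fitting needs >= 50 scores, got {len(x)}")
    try:
        cut = MixtureCutoff(n_components=3, random_state=seed).fit(x)
        t_low, t_high = cut.cutoffs_
    except ConvergenceError:
        if not quantile_fallback:
            raise
        t_low, t_high = np.quantile(x, [1 / 3, 2 / 3])
    return RiskThresholds(float(t_low), float(t_high))


def assign_groups(scores, thresholds: RiskThresholds) -> pd.Series:
    """Risk group per score: high if score >= t_high, intermediate if
    t_low <= score < t_high, low if score < t_low."""
    s = pd.Series(scores, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise InputError("scores must lie in [0, 1]")
    out = pd.Series("low", index=s.index, name="risk_group")
    out[s >= thresholds.t_low] = "intermediate"
    out[s >= thresholds.t_high] = "high"
    return out


def _largest_remainder_sizes(n: int, proportions) -> np.ndarray:
    p = np.asarray(proportions, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise InputError(f"group proportions must sum to 1, got {p.sum():.4f}")
    quota = p * n
    sizes = np.floor(quota).astype(int)
    rem = quota - sizes
    for i in np.argsort(-rem, kind="stable")[: n - sizes.sum()]:
        sizes[i] += 1
    return sizes


def assign_groups_by_proportion(scores, proportions) -> pd.Series:
    """Assign risk groups so group sizes match training proportions.

    ``proportions`` are (low, intermediate, high) fractions summing
    to 1.  Samples are ranked by score descending; the top high-fraction
    go to the high group, the next block to intermediate, the rest to
    low.  Sizes come from largest-remainder apportionment; ties keep
    stable input order.  Used for external cohorts, where the training
    thresholds are not transferable across platforms.
    """
    s = pd.Series(scores, dtype=float)
    n = len(s)
    n_low, n_int, n_high = _largest_remainder_sizes(n, proportions)
    order = np.argsort(-s.to_numpy(), kind="stable")
    out = np.empty(n, dtype=object)
    out[order[:n_high]] = "high"
    out[order[n_high : n_high + n_int]] = "intermediate"
    out[order[n_high + n_int :]] = "low"
    return pd.Series(out, index=s.index, name="risk_group")


def downsample_to_prevalence(events, target: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Remove event samples one at a time, uniformly at random, until
    the event count no longer exceeds the target fraction of the
    remaining cohort (within one sample, i.e. until
    ``n_events <= ceil(target * n_remaining)``).

    On a 572-sample cohort with 143 events and a 15% target this
    retains 505 samples with 76 events.  Returns the retained positions
    as an index array into ``events``.
    """
    ev = np.asarray(events, dtype=bool)
    if not 0 < target < 1:
        raise InputError(f"target prevalence must be in (0, 1), got {target}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    retained = np.arange(len(ev))
    event_pos = list(np.flatnonzero(ev))
    n_events = len(event_pos)
    removed: set[int] = set()
    while n_events > int(np.ceil(target * (len(ev) - len(removed)))):
        if n_events == 0:
            break
        j = rng.integers(len(event_pos))
        removed.add(event_pos.pop(j))
        n_events -= 1
    if removed:
        retained = np.array([i for i in retained if i not in removed])
    return retained


def estimate_group_rates(
    groups_or_scores,
    events,
    target: float = 0.15,
    n_iterations: int = 1000,
    seed: int = 0,
    thresholds: RiskThresholds | None = None,
) -> pd.DataFrame:
    """Average per-group proportions and relapse rates over repeated
    down-sampling to the target prevalence.

    ``groups_or_scores`` is either a precomputed risk-group Series or a
    score Series (then ``thresholds`` must be given).  Per iteration the
    cohort is down-sampled, groups are formed from the retained
    samples, and each group's event rate and share of the cohort is
    recorded; means are reported across iterations.  Iterations in
    which a group is empty contribute nothing to that group's rate; the
    count of contributing iterations is reported.

    The returned frame is indexed low/intermediate/high with columns
    proportion, relapse_rate, n_iterations_nonempty; ``attrs`` carries
    ``monotone_fraction``, the share of iterations with strictly
    increasing rates across the three groups.
    """
    ev = np.asarray(events, dtype=bool)
    s = pd.Series(groups_or_scores)
    if thresholds is not None:
        groups = assign_groups(s, thresholds).to_numpy()
    else:
        groups = s.astype(str).to_numpy()
    rng = np.random.default_rng(seed)

    props = {g: [] for g in GROUPS}
    rates = {g: [] for g in GROUPS}
    monotone = 0
    for _ in range(n_iterations):
        idx = downsample_to_prevalence(ev, target, rng)
        g_it, e_it = groups[idx], ev[idx]
        it_rates = []
        for g in GROUPS:
            mask = g_it == g
            props[g].append(mask.mean())
            if mask.any():
                r = e_it[mask].mean()
                rates[g].append(r)
                it_rates.append(r)
            else:
                it_rates.append(np.nan)
        if not np.isnan(it_rates).any() and it_rates[0] < it_rates[1] < it_rates[2]:
            monotone += 1
    out = pd.DataFrame(
        {
            "proportion": [float(np.mean(props[g])) for g in GROUPS],
            "relapse_rate": [float(np.mean(rates[g])) if rates[g] else np.nan for g in GROUPS],
            "n_iterations_nonempty": [len(rates[g]) for g in GROUPS],
        },
        index=list(GROUPS),
    )
    out.attrs["monotone_fraction"] = monotone / n_iterations
    out.attrs["target_prevalence"] = target
    return out


@dataclass
class LoessCurve:
    """Loess fit of 10-year relapse likelihood against the score.

    Scores are binned into ``n_bins`` equal intervals on [0, 1]; the
    per-bin empirical relapse fraction is smoothed by lowess over the
    occupied bin midpoints.  The 95% CI is fit +/- 1.96 x SE, where the
    per-bin binomial standard error is smoothed the same way.
    """

    bin_mid: np.ndarray
    bin_n: np.ndarray
    bin_rate: np.ndarray
    fit: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    training_scores: np.ndarray = field(default=None, repr=False)

    def lookup(self, score: float) -> tuple[float, float, float]:
        """(likelihood, ci_low, ci_high) at ``score``; clamped to the
        nearest fitted endpoint outside the fitted support."""
        x = np.clip(score, self.bin_mid[0], self.bin_mid[-1])
        f = float(np.interp(x, self.bin_mid, self.fit))
        lo = float(np.interp(x, self.bin_mid, self.lo))
        hi = float(np.interp(x, self.bin_mid, self.hi))
        return f, lo, hi

    def in_support(self, score: float) -> bool:
        return self.bin_mid[0] <= score <= self.bin_mid[-1]

    def fraction_at_or_below(self, likelihood: float) -> float:
        """Fraction of the training cohort whose predicted likelihood
        is <= ``likelihood``."""
        pred = np.interp(
            np.clip(self.training_scores, self.bin_mid[0], self.bin_mid[-1]),
            self.bin_mid,
            self.fit,
        )
        return float(np.mean(pred <= likelihood))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_mid": self.bin_mid, "n": self.bin_n, "rate": self.bin_rate,
             "fit": self.fit, "lo": self.lo, "hi": self.hi}
        )


def loess_curve(scores, outcomes, n_bins: int = 50, span: float = 0.75) -> LoessCurve:
    """Fit the score -> relapse-likelihood calibration curve."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(s) != len(y):
        raise InputError("scores and outcomes differ in length")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(s, edges[1:-1]), 0, n_bins - 1)
    mids, ns, rates = [], [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue  # empty bins are skipped in the fit
        mids.append((edges[b] + edges[b + 1]) / 2)
        ns.append(int(mask.sum()))
        rates.append(float(y[mask].mean()))
    mids, ns, rates = np.array(mids), np.array(ns), np.array(rates)
    if len(mids) < 3:
        raise InputError("too few occupied score bins for a loess fit")
    fit = lowess(rates, mids, frac=span, return_sorted=False)
    # binomial SE per bin with a continuity floor, smoothed like the fit
    p = np.clip(rates, 1.0 / (2 * ns + 2), 1 - 1.0 / (2 * ns + 2))
    se = np.sqrt(p * (1 - p) / ns)
    se_smooth = np.maximum(lowess(se, mids, frac=span, return_sorted=False), 0.0)
    fit = np.clip(fit, 0.0, 1.0)
    return LoessCurve(
        bin_mid=mids, bin_n=ns, bin_rate=rates, fit=fit,
        lo=np.clip(fit - 1.96 * se_smooth, 0.0, 1.0),
        hi=np.clip(fit + 1.96 * se_smooth, 0.0, 1.0),
        training_scores=s,
    )


@dataclass
class CalibrationBundle:
    thresholds: RiskThresholds
    group_rates: pd.DataFrame
    curve: LoessCurve
    target_prevalence: float = 0.15
    n_iterations: int = 1000

    def save(self, path) -> None:
        joblib.dump({"version": _ARCHIVE_VERSION, "bundle": self}, path)

    @classmethod
    def load(cls, path) -> "CalibrationBundle":
        payload = joblib.load(path)
        if payload.get("version") != _ARCHIVE_VERSION:
            raise InputError(f"unsupported calibration archive version: {payload.get('version')}")
        return payload["bundle"]


class RiskCalibrator:
    """Fit the full calibration bundle from training scores + outcomes.

    ``fit(scores, events)`` derives mixture-model thresholds, runs the
    down-sampling group-rate estimate, and fits the loess likelihood
    curve on one seeded down-sampled draw at the target prevalence
    (mirroring the n = 505 curve-fitting cohort of the study design).
    """

    def __init__(self, target_prevalence: float = 0.15, n_iterations: int = 1000,
                 n_bins: int = 50, span: float = 0.75, random_state: int = 0,
                 quantile_fallback: bool = False):
        self.target_prevalence = target_prevalence
        self.n_iterations = n_iterations
        self.n_bins = n_bins
        self.span = span
        self.random_state = random_state
        self.quantile_fallback = quantile_fallback

    def fit(self, scores, events) -> "RiskCalibrator":
        s_all = pd.Series(scores, dtype=float)
        ev_all = pd.Series(np.asarray(events, dtype=bool), index=s_all.index)
        keep = s_all.notna()
        s, ev = s_all[keep], ev_all[keep]
        self.thresholds_ = fit_thresholds(s, seed=self.random_state,
                                          quantile_fallback=self.quantile_fallback)
        self.group_rates_ = estimate_group_rates(
            s, ev, target=self.target_prevalence, n_iterations=self.n_iterations,
            seed=self.random_state, thresholds=self.thresholds_,
        )
        idx = downsample_to_prevalence(ev.to_numpy(), self.target_prevalence,
                                       np.random.default_rng(self.random_state))
        self.curve_ = loess_curve(s.to_numpy()[idx], ev.to_numpy()[idx],
                                  n_bins=self.n_bins, span=self.span)
        self.bundle_ = CalibrationBundle(
            thresholds=self.thresholds_, group_rates=self.group_rates_,
            curve=self.curve_, target_prevalence=self.target_prevalence,
            n_iterations=self.n_iterations,
        )
        return self
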