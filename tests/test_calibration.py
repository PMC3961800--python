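import numpy as np
import pandas as pd
import pytest

from rfrs import (InputError, RiskThresholds, STUDY_THRESHOLDS, assign_groups,
                  assign_groups_by_proportion, downsample_to_prevalence,
                  estimate_group_rates, fit_thresholds, loess_curve)
from rfrs.calibration import CalibrationBundle, RiskCalibrator


def smallest_removal_count(n, e, target):
    """Oracle: iterate the stopping rule directly."""
    r = 0
    while e - r > int(np.ceil(target * (n - r))):
        r += 1
    return r


class TestFitThresholds:
    def test_recovers_planted_three_component_boundaries(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(0.2, 0.05, 200),
                                 rng.normal(0.45, 0.05, 200),
                                 rng.normal(0.75, 0.05, 200)])
        t = fit_thresholds(np.clip(scores, 0.01, 0.99), seed=0)
        assert 0.28 <= t.t_low <= 0.40
        assert 0.55 <= t.t_high <= 0.68
        # equal-variance planted boundaries sit at 0.325 and 0.60
        assert t.t_low == pytest.approx(0.325, abs=0.07)
        assert t.t_high == pytest.approx(0.60, abs=0.07)

    def test_constant_scores_rejected(self):
        with pytest.raises(InputError):
            fit_thresholds(np.full(100, 0.5))

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(InputError):
            RiskThresholds(0.6, 0.3)


class TestAssignGroups:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.2, "low"), (0.333, "intermediate"), (0.5, "intermediate"),
         (0.606, "high"), (0.7, "high"), (0.0, "low"), (1.0, "high")],
    )
    def test_boundary_conventions(self, score, expected):
        assert assign_groups([score], STUDY_THRESHOLDS).iloc[0] == expected

    def test_trivial_tertile_assignment(self):
        groups = assign_groups([0.0, 0.5, 1.0], RiskThresholds(1 / 3, 2 / 3))
        assert list(groups) == ["low", "intermediate", "high"]

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(InputError):
            assign_groups([1.2], STUDY_THRESHOLDS)


class TestAssignByProportion:
    def test_counts_match_proportions(self):
        rng = np.random.default_rng(1)
        g = assign_groups_by_proportion(rng.random(10), (0.5, 0.3, 0.2))
        assert (g == "low").sum() == 5
        assert (g == "intermediate").sum() == 3
        assert (g == "high").sum() == 2

    def test_largest_remainder_apportionment(self):
        g = assign_groups_by_proportion(np.linspace(0, 1, 7), (0.462, 0.386, 0.152))
        assert [(g == lab).sum() for lab in ("low", "intermediate", "high")] == [3, 3, 1]

    def test_monotone_in_score(self):
        rng = np.random.default_rng(2)
        s = rng.permutation(np.linspace(0.01, 0.99, 30))
        g = assign_groups_by_proportion(s, (0.4, 0.35, 0.25))
        order = {"low": 0, "intermediate": 1, "high": 2}
        ranks = pd.Series([order[x] for x in g], index=s)
        srt = ranks.sort_index()
        assert srt.is_monotonic_increasing


class TestDownsample:
    def test_training_cohort_arithmetic(self):
        """572 samples with 143 events down-sampled to 15% leaves 505
        samples with 76 events (76/505 = 15%)."""
        events = np.array([True] * 143 + [False] * 429)
        idx = downsample_to_prevalence(events, 0.15, seed=0)
        assert len(idx) == 505
        assert events[idx].sum() == 76

    def test_identity_when_already_at_target(self):
        events = np.array([True] * 10 + [False] * 90)
        idx = downsample_to_prevalence(events, 0.15, seed=0)
        assert len(idx) == 100

    @pytest.mark.parametrize("n,e,target", [(10, 5, 0.25), (50, 20, 0.1), (30, 10, 0.2)])
    def test_matches_direct_iteration_of_stopping_rule(self, n, e, target):
        events = np.array([True] * e + [False] * (n - e))
        idx = downsample_to_prevalence(events, target, seed=1)
        r = smallest_removal_count(n, e, target)
        assert len(idx) == n - r
        assert events[idx].sum() == e - r

    def test_stopping_rule_is_tight(self):
        """The retained event count is within one rounding step of the
        target, and one fewer removal would still exceed it."""
        events = np.array([True] * 143 + [False] * 429)
        idx = downsample_to_prevalence(events, 0.15, seed=2)
        n, e = len(idx), int(events[idx].sum())
        assert e <= np.ceil(0.15 * n)
        assert (e + 1) > np.ceil(0.15 * (n + 1))

    def test_bad_target_rejected(self):
        with pytest.raises(InputError):
            downsample_to_prevalence(np.array([True, False]), 0.0)


class TestEstimateGroupRates:
    def test_conservation_identity_single_iteration(self):
        rng = np.random.default_rng(3)
        scores = rng.random(200)
        events = rng.random(200) < 0.4
        out = estimate_group_rates(scores, events, target=0.15, n_iterations=1,
                                   seed=0, thresholds=RiskThresholds(1 / 3, 2 / 3))
        total = (out["proportion"] * out["relapse_rate"]).sum()
        idx = downsample_to_prevalence(events, 0.15, np.random.default_rng(0))
        assert total == pytest.approx(events[idx].mean(), abs=1e-12)

    def test_planted_effect_gives_monotone_rates(self):
        rng = np.random.default_rng(4)
        n = 600
        events = rng.random(n) < 0.25
        scores = np.clip(0.25 + 0.3 * events + rng.normal(0, 0.12, n), 0, 1)
        t = RiskThresholds(*np.quantile(scores, [1 / 3, 2 / 3]))
        out = estimate_group_rates(scores, events, target=0.15, n_iterations=200,
                                   seed=1, thresholds=t)
        assert out.attrs["monotone_fraction"] >= 0.95
        assert out["relapse_rate"].is_monotonic_increasing

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(5)
        out = estimate_group_rates(rng.random(150), rng.random(150) < 0.3,
                                   n_iterations=20, seed=0,
                                   thresholds=RiskThresholds(0.3, 0.6))
        assert out["proportion"].sum() == pytest.approx(1.0, abs=1e-9)


class TestLoessCurve:
    def test_null_association_stays_near_prevalence(self):
        rng = np.random.default_rng(6)
        scores = rng.random(4000)
        outcomes = rng.random(4000) < 0.2
        curve = loess_curve(scores, outcomes)
        sel = (curve.bin_mid >= 0.1) & (curve.bin_mid <= 0.9)
        inside = (curve.lo[sel] <= 0.2) & (0.2 <= curve.hi[sel])
        assert inside.mean() >= 0.9

    def test_lookup_monotone_on_monotone_input(self):
        rng = np.random.default_rng(7)
        scores = np.repeat(np.linspace(0.05, 0.95, 30), 40)
        outcomes = rng.random(len(scores)) < np.repeat(np.linspace(0.02, 0.6, 30), 40)
        curve = loess_curve(scores, outcomes)
        grid = [curve.lookup(x)[0] for x in np.linspace(0.1, 0.9, 15)]
        assert all(b >= a - 1e-9 for a, b in zip(grid, grid[1:]))

    def test_lookup_clamps_outside_support(self):
        rng = np.random.default_rng(8)
        scores = np.clip(rng.normal(0.5, 0.1, 500), 0, 1)
        curve = loess_curve(scores, rng.random(500) < scores)
        assert curve.lookup(0.0)[0] == curve.lookup(curve.bin_mid[0])[0]
        assert not curve.in_support(0.0)

    def test_quantile_query(self):
        rng = np.random.default_rng(9)
        scores = rng.random(2000)
        outcomes = rng.random(2000) < scores * 0.4
        curve = loess_curve(scores, outcomes)
        frac = curve.fraction_at_or_below(0.10)
        assert 0.0 < frac < 1.0
        assert curve.fraction_at_or_below(1.0) == 1.0


def test_calibrator_bundle_roundtrip(tmp_path):
    rng = np.random.default_rng(10)
    n = 400
    events = rng.random(n) < 0.3
    scores = np.clip(0.2 + 0.35 * events + rng.normal(0, 0.15, n), 0.001, 0.999)
    cal = RiskCalibrator(n_iterations=50, random_state=0, quantile_fallback=True).fit(
        pd.Series(scores), events)
    cal.bundle_.save(tmp_path / "cal.joblib")
    loaded = CalibrationBundle.load(tmp_path / "cal.joblib")
    assert loaded.thresholds.t_low == cal.thresholds_.t_low
    assert loaded.curve.lookup(0.5) == cal.curve_.lookup(0.5)
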