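import numpy as np
import pandas as pd
import pytest

from rfrs import (ExpressionMatrix, InputError, binarize_ten_year, deduplicate,
                  detect_duplicates, filter_eligibility, stratified_split)
from rfrs.assembly import EXCLUDED_SHORT, EXCLUDED_ZERO, NO_RELAPSE, RELAPSE

from conftest import make_clinical


def _expr_from(rows, prefix="s"):
    vals = pd.DataFrame(np.asarray(rows, dtype=float),
                        index=[f"{prefix}{i}" for i in range(len(rows))],
                        columns=[f"f{j}" for j in range(len(rows[0]))])
    return ExpressionMatrix(vals)


class TestDetectDuplicates:
    def test_exact_copy_grouped(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(50, 500, size=200)
        other = rng.uniform(50, 500, size=200)
        expr = _expr_from([base, base, other])
        groups = detect_duplicates(expr)
        assert len(groups) == 1
        assert groups[0]["members"] == ["s0", "s1"]

    def test_independent_profiles_not_grouped(self):
        # oracle: direct Pearson formula on two independent normal profiles
        rng = np.random.default_rng(1)
        a, b = np.exp2(rng.standard_normal(1000) + 8), np.exp2(rng.standard_normal(1000) + 8)
        la, lb = np.log2(a), np.log2(b)
        r = np.sum((la - la.mean()) * (lb - lb.mean())) / np.sqrt(
            np.sum((la - la.mean()) ** 2) * np.sum((lb - lb.mean()) ** 2))
        assert r < 0.99
        assert detect_duplicates(_expr_from([a, b])) == []

    def test_shared_patient_id_grouped(self):
        rng = np.random.default_rng(2)
        expr = _expr_from(rng.uniform(50, 500, size=(3, 100)))
        clin = make_clinical([
            (f"s{i}", "study_1", "+", "-", "negative", False, False, False, 10.0)
            for i in range(3)
        ])
        clin.data["patient_id"] = ["p1", "p1", "p2"]
        groups = detect_duplicates(expr, clin)
        assert len(groups) == 1 and groups[0]["members"] == ["s0", "s1"]

    def test_transitive_closure_and_idempotence(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(50, 500, size=500)
        noisy1 = np.exp2(np.log2(base) + rng.normal(0, 0.005, 500))
        noisy2 = np.exp2(np.log2(base) + rng.normal(0, 0.005, 500))
        other = rng.uniform(50, 500, size=500)
        expr = _expr_from([base, noisy1, noisy2, other])
        clin = make_clinical([
            (f"s{i}", f"study_{i % 2 + 1}", "+", "-", "negative", False, False, False, 10.0)
            for i in range(4)
        ])
        groups = detect_duplicates(expr, clin)
        assert len(groups) == 1
        assert groups[0]["members"] == ["s0", "s1", "s2"]
        expr2, clin2 = deduplicate(expr, clin, groups)
        assert expr2.n_samples == 2
        assert detect_duplicates(expr2, clin2) == []

    def test_representative_follows_study_precedence(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(50, 500, size=300)
        expr = _expr_from([base, base])
        clin = make_clinical([
            ("s0", "study_B", "+", "-", "negative", False, False, False, 10.0),
            ("s1", "study_A", "+", "-", "negative", False, False, False, 10.0),
        ])
        groups = detect_duplicates(expr, clin, study_precedence=["study_A", "study_B"])
        assert groups[0]["representative"] == "s1"


class TestEligibility:
    def _status(self, rows):
        return pd.DataFrame(rows, columns=["er_array", "her2_array"]).set_axis(
            [f"s{i}" for i in range(len(rows))], axis=0)

    def test_clinical_and_array_must_agree_on_er(self):
        clin = make_clinical([
            ("s0", "a", "+", "-", "negative", False, False, False, 10.0),  # ER+ clin, ER- array
            ("s1", "a", "missing", "-", "negative", False, False, False, 10.0),  # array decides
            ("s2", "a", "-", "-", "negative", False, False, False, 10.0),  # clin negative
        ])
        status = self._status([("-", "-"), ("+", "-"), ("+", "-")])
        eligible, reasons = filter_eligibility(clin, status)
        assert eligible == ["s1"]
        assert reasons.set_index("sample_id").loc["s0", "reason"] == "er_discordant_or_negative"

    def test_her2_positive_by_array_excluded(self):
        clin = make_clinical([
            (f"s{i}", "a", "+", "-", "negative", False, False, False, 10.0) for i in range(10)
        ])
        status = self._status([("+", "+")] * 2 + [("+", "-")] * 8)
        eligible, _ = filter_eligibility(clin, status)
        assert len(eligible) == 8

    def test_missing_ln_and_chemo_excluded(self):
        clin = make_clinical([
            ("s0", "a", "+", "-", "missing", False, False, False, 10.0),
            ("s1", "a", "+", "-", "negative", True, False, False, 10.0),
            ("s2", "a", "+", "-", "positive", False, False, False, 10.0),
        ])
        status = self._status([("+", "-")] * 3)
        eligible, reasons = filter_eligibility(clin, status)
        assert eligible == []
        assert list(reasons["reason"]) == ["ln_status_missing", "chemotherapy", "ln_positive"]


class TestBinarize:
    @pytest.mark.parametrize(
        "event,years,expected",
        [
            (True, 4.2, RELAPSE),
            (True, 10.0, RELAPSE),
            (True, 0.0, EXCLUDED_ZERO),
            (True, 12.0, NO_RELAPSE),  # relapse-free through the 10-year window
            (False, 8.0, EXCLUDED_SHORT),
            (False, 10.0, NO_RELAPSE),
            (False, 15.0, NO_RELAPSE),
        ],
    )
    def test_ten_year_classes(self, event, years, expected):
        clin = make_clinical([("s0", "a", "+", "-", "negative", False, False, event, years)])
        assert binarize_ten_year(clin).iloc[0] == expected

    def test_partition_is_exhaustive_and_disjoint(self, small_cohort):
        labels = binarize_ten_year(small_cohort.clinical)
        assert set(labels.unique()) <= {RELAPSE, NO_RELAPSE, EXCLUDED_SHORT, EXCLUDED_ZERO}
        assert len(labels) == len(small_cohort.clinical.data)

    def test_negative_time_rejected(self):
        clin = make_clinical([("s0", "a", "+", "-", "negative", False, False, False, 10.0)])
        clin.data.loc[0, "followup_years"] = -1.0
        with pytest.raises(InputError):
            binarize_ten_year(clin)


def _strata(n, n_studies=9, relapse_rate=0.35, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "sample_id": [f"s{i:04d}" for i in range(n)],
        "study_id": [f"study_{rng.integers(n_studies) + 1}" for _ in range(n)],
        "class": np.where(rng.random(n) < relapse_rate, RELAPSE, NO_RELAPSE),
    })


class TestStratifiedSplit:
    def test_two_thirds_of_858_gives_572_286(self):
        split = stratified_split(_strata(858), 2 / 3, seed=0)
        assert len(split.train_ids) == 572
        assert len(split.test_ids) == 286

    def test_fraction_one_puts_all_in_train(self):
        split = stratified_split(_strata(50), 1.0, seed=0)
        assert len(split.test_ids) == 0

    def test_split_is_disjoint_and_exhaustive(self):
        strata = _strata(200)
        split = stratified_split(strata, 2 / 3, seed=1)
        assert not set(split.train_ids) & set(split.test_ids)
        assert sorted(split.train_ids + split.test_ids) == sorted(strata["sample_id"])

    def test_reproducible_and_row_order_invariant(self):
        strata = _strata(300, seed=2)
        a = stratified_split(strata, 2 / 3, seed=9)
        b = stratified_split(strata.sample(frac=1.0, random_state=4), 2 / 3, seed=9)
        assert a.train_ids == b.train_ids

    def test_per_study_balance(self):
        strata = _strata(900, seed=3)
        split = stratified_split(strata, 2 / 3, seed=5)
        per_study = split.report.groupby("study_id")[["n", "n_train"]].sum()
        frac = per_study["n_train"] / per_study["n"]
        # every study within one sample of the global two-thirds
        assert (abs(frac - 2 / 3) <= 1.0 / per_study["n"] + 1e-12).all()

    def test_single_member_strata_go_to_train(self):
        strata = pd.DataFrame({
            "sample_id": ["a", "b", "c"],
            "study_id": ["s1", "s2", "s3"],
            "class": [RELAPSE, RELAPSE, NO_RELAPSE],
        })
        split = stratified_split(strata, 2 / 3, seed=0)
        assert split.test_ids == []
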