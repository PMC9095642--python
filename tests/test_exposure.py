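"""Quarterly exposure-response binning and BCT weighted scoring."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from glycotrial.cohort import Theme, ThemeCatalog
from glycotrial.errors import DataError, DomainError
from glycotrial.exposure import (
    bct_chi_square,
    bct_scores,
    exposure_response_bins,
    quarterly_periods,
)


def _visits(rows):
    return pd.DataFrame(rows, columns=["id", "day", "hba1c", "med_change"])


def _completions(rows):
    return pd.DataFrame(rows, columns=["id", "day", "theme_id"])


class TestQuarterlyPeriods:
    def test_hand_counted_example(self):
        visits = _visits([("a", 0, 63, False), ("a", 91, 60, False), ("a", 182, 61, False)])
        comp = _completions([("a", 10, "T01"), ("a", 20, "T01"), ("a", 100, "T02")])
        out = quarterly_periods(visits, comp)
        assert len(out) == 2
        q1, q2 = out.iloc[0], out.iloc[1]
        assert (q1["themes_completed"], q1["delta_hba1c"]) == (2, -3)
        assert (q2["themes_completed"], q2["delta_hba1c"]) == (1, 1)

    def test_half_open_interval_boundaries(self):
        visits = _visits([("a", 0, 60, False), ("a", 91, 59, False)])
        comp = _completions([("a", 0, "T01"), ("a", 91, "T02")])
        out = quarterly_periods(visits, comp)
        # day 0 excluded (open left end), day 91 included (closed right end)
        assert out["themes_completed"].iloc[0] == 1

    def test_no_completions(self):
        visits = _visits([("a", 0, 63, False), ("a", 91, 60, False)])
        out = quarterly_periods(visits, _completions([]))
        assert (out["themes_completed"] == 0).all()

    def test_missing_hba1c_omits_period(self):
        visits = _visits([("a", 0, 63, False), ("a", 91, np.nan, False),
                          ("a", 182, 61, False)])
        out = quarterly_periods(visits, _completions([]))
        assert len(out) == 0  # both periods touch the missing visit

    def test_duplicate_days_raise(self):
        visits = _visits([("a", 0, 63, False), ("a", 0, 60, False)])
        with pytest.raises(DataError):
            quarterly_periods(visits, _completions([]))

    def test_only_year_one_pairs_used(self):
        visits = _visits([("a", d, 60.0, False) for d in (0, 91, 182, 273, 365, 547, 730)])
        out = quarterly_periods(visits, _completions([]))
        assert len(out) == 4
        assert out["quarter_index"].tolist() == [1, 2, 3, 4]


class TestExposureBins:
    def test_hand_binning(self):
        periods = pd.DataFrame({
            "themes_completed": [0, 0, 3, 7],
            "delta_hba1c": [1.0, 2.0, -1.0, -4.0]})
        out = exposure_response_bins(periods).set_index("bin")
        assert out.loc["0", "n"] == 2 and out.loc["0", "mean_delta"] == pytest.approx(1.5)
        assert out.loc["1-4", "n"] == 1 and out.loc["1-4", "mean_delta"] == pytest.approx(-1.0)
        assert out.loc[">=5", "n"] == 1 and out.loc[">=5", "mean_delta"] == pytest.approx(-4.0)

    def test_bin_boundaries(self):
        periods = pd.DataFrame({"themes_completed": [4, 5], "delta_hba1c": [0.0, 0.0]})
        out = exposure_response_bins(periods).set_index("bin")
        assert out.loc["1-4", "n"] == 1 and out.loc[">=5", "n"] == 1

    def test_conservation_and_empty_bins(self):
        rng = np.random.default_rng(3)
        periods = pd.DataFrame({
            "themes_completed": rng.integers(5, 30, 50),
            "delta_hba1c": rng.normal(0, 1, 50)})
        out = exposure_response_bins(periods)
        assert out["n"].sum() == 50
        empty = out.set_index("bin").loc["0"]
        assert empty["n"] == 0 and np.isnan(empty["mean_delta"])

    def test_sem_definition(self):
        periods = pd.DataFrame({"themes_completed": [0, 0, 0, 0],
                                "delta_hba1c": [1.0, 2.0, 3.0, 4.0]})
        out = exposure_response_bins(periods).set_index("bin")
        expected = np.std([1, 2, 3, 4], ddof=1) / 2
        assert out.loc["0", "sem"] == pytest.approx(expected)


def _one_theme_catalog():
    return ThemeCatalog(themes=[Theme("T01", {"A": 0.5, "B": 0.3, "C": 0.2})])


class TestBctScores:
    def test_hand_multiplication(self):
        # one quarter, theme T01 completed once by each of 4 participants:
        # 3 responders (delta < 0), 1 non-responder
        rows, comp = [], []
        deltas = [-2, -1, -3, 0]
        for i, d in enumerate(deltas):
            pid = f"p{i}"
            rows += [(pid, 0, 60, False), (pid, 91, 60 + d, False)]
            comp.append((pid, 30, "T01"))
        scores = bct_scores(_visits(rows), _completions(comp), _one_theme_catalog())
        s = scores.set_index("bct_id")
        assert s["responder_score"].to_dict() == pytest.approx({"A": 1.5, "B": 0.9, "C": 0.6})
        assert s["nonresponder_score"].to_dict() == pytest.approx({"A": 0.5, "B": 0.3, "C": 0.2})

    def test_no_completions_all_zero(self):
        rows = [("p0", 0, 60, False), ("p0", 91, 58, False)]
        scores = bct_scores(_visits(rows), _completions([]), _one_theme_catalog())
        assert (scores[["responder_score", "nonresponder_score"]] == 0).all().all()

    def test_unknown_theme_raises(self):
        rows = [("p0", 0, 60, False), ("p0", 91, 58, False)]
        with pytest.raises(DataError):
            bct_scores(_visits(rows), _completions([("p0", 30, "T99")]),
                       _one_theme_catalog())

    def test_total_score_equals_total_count_when_weights_normalized(self):
        rows, comp = [], []
        rng = np.random.default_rng(5)
        for i in range(6):
            pid = f"p{i}"
            rows += [(pid, 0, 60, False), (pid, 91, 60 + rng.normal(), False)]
            for _ in range(int(rng.integers(0, 4))):
                comp.append((pid, int(rng.integers(1, 92)), "T01"))
        scores = bct_scores(_visits(rows), _completions(comp), _one_theme_catalog())
        total = scores["responder_score"].sum() + scores["nonresponder_score"].sum()
        assert total == pytest.approx(len(comp), abs=1e-9)

    def test_repeat_counting_configurable(self):
        rows = [("p0", 0, 60, False), ("p0", 91, 58, False)]
        comp = _completions([("p0", 10, "T01"), ("p0", 20, "T01")])
        twice = bct_scores(_visits(rows), comp, _one_theme_catalog(), count_repeats=True)
        once = bct_scores(_visits(rows), comp, _one_theme_catalog(), count_repeats=False)
        assert twice["responder_score"].sum() == pytest.approx(2.0)
        assert once["responder_score"].sum() == pytest.approx(1.0)

    def test_linearity_in_weights(self):
        rows = [("p0", 0, 60, False), ("p0", 91, 58, False),
                ("p1", 0, 60, False), ("p1", 91, 62, False)]
        comp = _completions([("p0", 10, "T01"), ("p1", 20, "T01")])
        base = bct_scores(_visits(rows), comp, _one_theme_catalog())
        doubled_cat = ThemeCatalog(themes=[Theme("T01", {"A": 1.0, "B": 0.6, "C": 0.4})])
        doubled = bct_scores(_visits(rows), comp, doubled_cat)
        for col in ("responder_score", "nonresponder_score"):
            assert doubled[col].to_numpy() == pytest.approx(2 * base[col].to_numpy())


class TestBctChiSquare:
    def test_homogeneous_table_is_zero(self):
        table = pd.DataFrame({"bct_id": list("abc"),
                              "responder_score": [10.0, 20.0, 30.0],
                              "nonresponder_score": [5.0, 10.0, 15.0]})
        stat, df, p = bct_chi_square(table)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 2 and p == pytest.approx(1.0)

    def test_two_by_two_frozen_value(self):
        # expected counts from margins give X^2 = 4.5 (hand computation,
        # confirmed by scipy without continuity correction)
        table = pd.DataFrame({"bct_id": ["a", "b"],
                              "responder_score": [10.0, 10.0],
                              "nonresponder_score": [20.0, 5.0]})
        stat, df, _ = bct_chi_square(table)
        assert stat == pytest.approx(4.5, abs=1e-9)
        assert df == 1

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            k = int(rng.integers(2, 8))
            table = pd.DataFrame({
                "bct_id": [f"b{i}" for i in range(k)],
                "responder_score": rng.integers(1, 50, k).astype(float),
                "nonresponder_score": rng.integers(1, 50, k).astype(float)})
            stat, df, p = bct_chi_square(table)
            obs = table[["responder_score", "nonresponder_score"]].to_numpy().T
            ref_stat, ref_p, ref_df, _ = chi2_contingency(obs, correction=False)
            assert stat == pytest.approx(ref_stat, abs=1e-9)
            assert df == ref_df and p == pytest.approx(ref_p, abs=1e-9)

    def test_zero_total_column_excluded_with_warning(self):
        table = pd.DataFrame({"bct_id": list("abc"),
                              "responder_score": [10.0, 0.0, 8.0],
                              "nonresponder_score": [5.0, 0.0, 9.0]})
        with pytest.warns(UserWarning, match="zero total"):
            stat, df, _ = bct_chi_square(table)
        assert df == 1

    def test_nonint_scores_warn_and_scale(self):
        table = pd.DataFrame({"bct_id": ["a", "b"],
                              "responder_score": [1.5, 2.5],
                              "nonresponder_score": [2.0, 0.5]})
        with pytest.warns(UserWarning, match="non-integer"):
            stat1, _, _ = bct_chi_square(table)
        scaled = table.copy()
        scaled[["responder_score", "nonresponder_score"]] *= 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat2, _, _ = bct_chi_square(scaled)
        assert stat2 == pytest.approx(2 * stat1)
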