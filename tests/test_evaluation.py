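"""Metrics, combination-search bookkeeping, feature importance, severity
ratios and unilateral comparisons."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from pulsescreen import (
    ClassifierConfig,
    ConfusionCounts,
    MeasurementCombination,
    ZScoreScaler,
    combination_search,
    confusion_counts,
    measurement_importance,
    metrics,
    q1_partition,
    severity_ratio_analysis,
    summarise_by_count,
    train,
    unilateral_evaluation,
)
from pulsescreen.features import assemble_features

from conftest import make_twin_pools


class TestMetrics:
    def test_symmetric_case(self):
        m = metrics(ConfusionCounts(tp=90, fp=10, fn=10, tn=90))
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["f1"] == pytest.approx(0.9)
        assert not m["degenerate"]

    def test_no_true_positives_gives_zero_f1(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=10, tn=10))
        assert m["f1"] == 0.0
        assert m["degenerate"]  # zero-denominator precision flagged

    def test_balanced_class_f1_consistency(self):
        """On a balanced test set, a published (sens, spec) pair implies F1
        through the metric identities: sens 0.8547 / spec 0.8502 give
        F1 = 0.852 within 0.01 of the published 0.8521."""
        n = 10_000  # per class
        tp = round(0.8547 * n)
        tn = round(0.8502 * n)
        m = metrics(ConfusionCounts(tp=tp, fp=n - tn, fn=n - tp, tn=tn))
        assert m["f1"] == pytest.approx(0.8521, abs=0.01)

    def test_identities_hold(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = ConfusionCounts(*rng.integers(0, 50, size=4))
            m = metrics(c)
            assert m["recall"] == m["sensitivity"]
            denom = 2 * c.tp + c.fp + c.fn
            if denom:
                assert m["f1"] == pytest.approx(2 * c.tp / denom)
            for key in ("sensitivity", "specificity", "precision", "f1"):
                assert 0.0 <= m[key] <= 1.0

    def test_counts_from_labels(self):
        c = confusion_counts([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (2, 1, 1, 1)
        assert c.total == 5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


@pytest.fixture(scope="module")
def search_records():
    """Combination search over 3 measurements (7 combos) on fabricated
    twins with planted carotid-flow signal."""
    h, d = make_twin_pools(40, np.random.default_rng(8),
                           signal_sites=("Q1_R", "Q1_L"), signal=0.25)
    return combination_search(
        "AAA", ("NB", "LR"), h, d, np.random.default_rng(9),
        measurements=("Q1", "Q2", "P1"), n_folds=5)


class TestCombinationSearch:
    def test_record_completeness(self, search_records):
        """|methods| x combinations x folds rows, no silent gaps."""
        assert len(search_records) == 2 * 7 * 5
        counts = search_records.groupby(["method", "combination"]).size()
        assert (counts == 5).all()

    def test_no_errors_recorded(self, search_records):
        assert (search_records["error"] == "").all()

    def test_summary_by_count(self, search_records):
        s = summarise_by_count(search_records)
        # k = 3 has exactly one combination: mean = max = min
        k3 = s[s["n_measurements"] == 3]
        assert np.allclose(k3["mean_f1"], k3["max_f1"])
        assert (s["max_f1"] >= s["mean_f1"] - 1e-12).all()
        assert (s["mean_f1"] >= s["min_f1"] - 1e-12).all()

    def test_argmax_reproducible_by_brute_force(self, search_records):
        s = summarise_by_count(search_records)
        means = (search_records
                 .groupby(["method", "combination", "n_measurements"],
                          as_index=False)["f1"].mean())
        for _, row in s.iterrows():
            g = means[(means["method"] == row["method"])
                      & (means["n_measurements"] == row["n_measurements"])]
            assert row["best_combination"] == g.loc[g["f1"].idxmax(), "combination"]
            assert row["max_f1"] == pytest.approx(g["f1"].max())

    def test_q1_partition_counts(self, search_records):
        part = q1_partition(search_records)
        combos = search_records["combination"].unique()
        inc = part["include_q1"]["combination"].unique()
        exc = part["exclude_q1"]["combination"].unique()
        assert len(inc) == 4 and len(exc) == 3  # of 7 combos over 3 measurements
        assert set(inc) | set(exc) == set(combos)
        assert not set(inc) & set(exc)

    def test_q1_partition_full_search_is_32_31(self):
        """Of the 63 subsets of six measurements, 32 contain Q1, 31 do not."""
        from pulsescreen.features import all_combinations
        combos = all_combinations()
        inc = [c for c in combos if "Q1" in c.measurements]
        assert len(combos) == 63
        assert (len(inc), len(combos) - len(inc)) == (32, 31)

    def test_planted_q1_signal_detected(self, search_records):
        part = q1_partition(search_records)
        assert part["include_mean_f1"] > part["exclude_mean_f1"]


class TestImportance:
    def combo(self):
        return MeasurementCombination(("Q1", "Q2", "Q3", "P1", "P2", "P3"))

    def test_uniform_importances_give_equal_shares(self):
        fake = SimpleNamespace(model=SimpleNamespace(
            feature_importances_=np.full(132, 1.0 / 132)),
            config=SimpleNamespace(method="GB"))
        shares = measurement_importance(fake, self.combo())
        np.testing.assert_allclose(shares.values, 100.0 / 6, atol=1e-9)

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(0)
        imp = rng.dirichlet(np.ones(132))
        fake = SimpleNamespace(model=SimpleNamespace(feature_importances_=imp),
                               config=SimpleNamespace(method="GB"))
        assert measurement_importance(fake, self.combo()).sum() == pytest.approx(
            100.0, abs=0.1)

    def test_planted_carotid_flow_signal_dominates(self):
        """A GB model trained where only Q1 features carry signal assigns
        Q1 more than 90% of the summed importance."""
        h, d = make_twin_pools(150, np.random.default_rng(1),
                               signal_sites=("Q1_R", "Q1_L"), signal=0.5)
        X, y, _, _ = assemble_features(h + d, self.combo())
        Z = ZScoreScaler().fit(X).transform(X)
        tc = train(ClassifierConfig("GB", (("max_depth", 3),
                                           ("n_estimators", 50))), Z, y)
        shares = measurement_importance(tc, self.combo())
        assert shares["Q1"] > 90.0

    def test_model_without_importances_rejected(self):
        fake = SimpleNamespace(model=SimpleNamespace(),
                               config=SimpleNamespace(method="SVM"))
        with pytest.raises(ValueError, match="importance"):
            measurement_importance(fake, self.combo())


class TestSeverityRatios:
    def test_identical_tables_give_unit_ratios(self, search_records):
        gb_like = search_records[search_records["method"] == "NB"].copy()
        gb_like["method"] = "GB"
        out = severity_ratio_analysis(gb_like, gb_like)
        np.testing.assert_allclose(out["f1_ratio"], 1.0)
        assert len(out) == 7

    def test_unmatched_combinations_rejected(self, search_records):
        a = search_records[search_records["method"] == "NB"].copy()
        a["method"] = "GB"
        b = a[a["combination"] != "Q1"]
        with pytest.raises(ValueError, match="unmatched"):
            severity_ratio_analysis(a, b)


class TestUnilateral:
    def test_structure_and_widths(self):
        h, d = make_twin_pools(30, np.random.default_rng(2),
                               signal_sites=("Q1_R", "Q1_L", "P3_R", "P3_L"),
                               signal=0.4)
        out = unilateral_evaluation(h, d, np.random.default_rng(3),
                                    method="NB", n_folds=3)
        assert len(out) == 6  # {Q1, P3} x {right, left, both}
        w = out.set_index(["measurement", "side"])["feature_width"]
        assert w[("Q1", "right")] == 11
        assert w[("Q1", "both")] == 22
        assert set(out["side"]) == {"right", "left", "both"}
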