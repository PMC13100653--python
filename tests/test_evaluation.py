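"""Splits, AUC, operating points and the descriptive suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from idhrisk import (
    build_rows_cohort,
    descriptive_suite,
    operating_point,
    roc_auc,
    split_sessions,
)
from idhrisk.io import sessions_meta

from _oracles import auc_paircount, fisher_hypergeom


def meta_frame(n_pat=8, n_sess=9):
    recs = [
        {"patient_id": f"P{i}", "session_id": f"P{i}-S{j}", "session_order": j}
        for i in range(n_pat)
        for j in range(1, n_sess + 1)
    ]
    return pd.DataFrame(recs)


class TestSplits:
    def test_patient_mode_is_a_patient_partition(self):
        meta = meta_frame()
        train, test = split_sessions(meta, "patient", 0.7, seed=3)
        pat = meta.set_index("session_id")["patient_id"]
        assert set(pat[train]) & set(pat[test]) == set()
        assert set(train) | set(test) == set(meta["session_id"])

    def test_session_mode_chronological_seven_two(self):
        meta = meta_frame(n_pat=1, n_sess=9)
        train, test = split_sessions(meta, "session", 0.7, seed=0)
        orders = meta.set_index("session_id")["session_order"]
        assert sorted(orders[train]) == list(range(1, 8))
        assert sorted(orders[test]) == [8, 9]

    def test_session_mode_test_orders_exceed_train_orders(self):
        meta = meta_frame()
        train, test = split_sessions(meta, "session", 0.7, seed=0)
        df = meta.set_index("session_id")
        for pid in df["patient_id"].unique():
            tr = df.loc[[s for s in train if df.loc[s, "patient_id"] == pid]]
            te = df.loc[[s for s in test if df.loc[s, "patient_id"] == pid]]
            if len(te):
                assert te["session_order"].min() > tr["session_order"].max()

    def test_single_session_patient_goes_to_train(self):
        meta = pd.concat(
            [meta_frame(n_pat=2), meta_frame(n_pat=1, n_sess=1).assign(patient_id="PX")]
        )
        meta.loc[meta["patient_id"] == "PX", "session_id"] = "PX-S1"
        train, _ = split_sessions(meta, "session", 0.7, seed=0)
        assert "PX-S1" in train

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_sessions(meta_frame(), "session", 1.0, seed=0)


class TestAuc:
    def test_reference_values(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_undefined(self):
        assert np.isnan(roc_auc([0.1, 0.2], [1, 1]))

    @given(
        data=st.lists(
            st.tuples(st.floats(0, 1), st.integers(0, 1)), min_size=4, max_size=20
        )
    )
    def test_matches_pair_counting_oracle(self, data):
        scores = [s for s, _ in data]
        labels = [l for _, l in data]
        if len(set(labels)) < 2:
            return
        assert roc_auc(scores, labels) == pytest.approx(
            auc_paircount(scores, labels), abs=1e-12
        )

    @given(
        data=st.lists(
            st.tuples(st.floats(0.01, 0.99), st.integers(0, 1)),
            min_size=4, max_size=20,
        )
    )
    def test_invariant_under_monotone_transform(self, data):
        scores = np.array([s for s, _ in data])
        labels = [l for _, l in data]
        if len(set(labels)) < 2:
            return
        a = roc_auc(scores, labels)
        b = roc_auc(np.log(scores / (1 - scores)) * 3 + 2, labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestOperatingPoint:
    def test_published_confusion_counts(self):
        # TP=37 FN=13 TN=75 FP=25 at the selected cutoff
        scores = np.r_[np.ones(37), np.zeros(13), np.zeros(75), np.ones(25)]
        labels = np.r_[np.ones(50), np.zeros(100)]
        op = operating_point(scores, labels)
        assert op["sensitivity"] == pytest.approx(0.74)
        assert op["specificity"] == pytest.approx(0.75)
        assert op["npv"] == pytest.approx(75 / 88)
        assert op["confusion"] == {"tp": 37, "fp": 25, "fn": 13, "tn": 75}

    def test_degenerate_all_positive_predictions(self):
        scores = np.full(10, 0.9)
        labels = np.r_[np.ones(4), np.zeros(6)]
        op = operating_point(scores, labels)
        assert op["sensitivity"] == 1.0 and op["specificity"] == 0.0

    def test_youden_maximal_over_all_candidates(self):
        rng = np.random.default_rng(8)
        scores = rng.random(50)
        labels = (rng.random(50) < 0.4).astype(int)
        op = operating_point(scores, labels)
        for thr in np.unique(scores):
            pred = scores >= thr
            sens = np.sum(pred & (labels == 1)) / labels.sum()
            spec = np.sum(~pred & (labels == 0)) / (labels == 0).sum()
            assert op["youden_j"] >= sens + spec - 1.0 - 1e-12


class TestFisherOracle:
    @pytest.mark.parametrize(
        "table",
        [[[1, 9], [11, 3]], [[5, 5], [5, 5]], [[0, 10], [0, 8]], [[8, 2], [1, 5]]],
    )
    def test_scipy_matches_hypergeometric_enumeration(self, table):
        assert fisher_exact(table)[1] == pytest.approx(fisher_hypergeom(table), rel=1e-9)

    def test_frozen_enumeration_value(self):
        assert fisher_hypergeom([[1, 9], [11, 3]]) == pytest.approx(0.00275939, abs=5e-7)


class TestDescriptiveSuite:
    def test_on_synthetic_cohort(self, small_continuous_cohort):
        co = small_continuous_cohort
        rows = build_rows_cohort(co.sessions, mode="concurrent")
        first = {s.session_id: s.labels().first_event_time_min for s in co.sessions}
        risk = {
            s.session_id: ("high" if co.truth.set_index("session_id").loc[
                s.session_id, "any_idh"] else "low")
            for s in co.sessions
        }
        out = descriptive_suite(rows, risk, first)
        bins = out["rbv_bins"]
        assert list(bins["bin"]) == [">=95", "90-95", "85-90", "80-85", "<80"]
        assert bins["n"].sum() == len(rows)
        ps = bins["fisher_p"].dropna()
        assert ((ps >= 0) & (ps <= 1)).all()
        # flagged vitals sit at lower RBV by construction of the hazard
        w = out["wilcoxon"]
        assert w["median_flagged"] < w["median_unflagged"]
        cum = out["cumulative_by_group"]
        assert (cum["cum_inc_high"].diff().dropna() >= 0).all()
        assert ((cum["fisher_p"] >= 0) & (cum["fisher_p"] <= 1)).all()

    def test_identical_flagged_unflagged_rbv_gives_p_one(self):
        rows = pd.DataFrame(
            {
                "rbv_pct": [90.0, 85.0, 90.0, 85.0],
                "label": [1, 1, 0, 0],
                "t_min": [30, 60, 90, 120],
            }
        )
        out = descriptive_suite(rows)
        assert out["wilcoxon"]["p"] == 1.0

    def test_zero_event_bins_give_p_one(self):
        rows = pd.DataFrame(
            {
                "rbv_pct": np.r_[np.full(10, 97.0), np.full(10, 92.0)],
                "label": np.zeros(20, dtype=int),
                "t_min": np.tile(np.arange(10) * 30, 2),
            }
        )
        bins = descriptive_suite(rows)["rbv_bins"]
        assert bins.set_index("bin").loc["90-95", "fisher_p"] == pytest.approx(1.0)


class TestEndToEndEvaluation:
    def test_report_shapes_and_rates(self, small_continuous_cohort):
        from idhrisk import evaluate_predictive

        co = small_continuous_cohort
        rows = build_rows_cohort(co.sessions, mode="horizon")
        meta = sessions_meta(co.sessions)
        rep = evaluate_predictive(rows, meta, "label ~ delta_rbv", "session", seed=0)
        d = rep.to_dict()
        assert 0.0 <= d["auc_test"] <= 1.0
        conf = d["operating_point"]["confusion"]
        assert sum(conf.values()) == d["n"]["test_rows"]
        assert set(rep.formula.split()) >= {"label", "~", "delta_rbv"}
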