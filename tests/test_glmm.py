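"""Mixed logistic model: oracles, quadrature accuracy, prediction algebra."""

import os
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from idhrisk import MixedLogit, build_rows_cohort, fit_mixed_logistic


def simulate_rows(seed, n_pat=30, n_obs=25, beta0=-1.0, beta1=0.8, sigma=1.2):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_pat):
        b = rng.normal(0, sigma) if sigma > 0 else 0.0
        x = rng.normal(0, 1, n_obs)
        p = expit(beta0 + beta1 * x + b)
        y = (rng.random(n_obs) < p).astype(int)
        recs += [(f"P{i:03d}", xx, yy) for xx, yy in zip(x, y)]
    return pd.DataFrame(recs, columns=["patient_id", "x", "label"])


class TestOracles:
    def test_sigma_zero_limit_matches_plain_logistic(self):
        rows = simulate_rows(1, sigma=0.0)
        ours = MixedLogit.from_formula("label ~ x", rows).fit(fix_sigma=0.0)
        X = sm.add_constant(rows["x"].to_numpy())
        ref = sm.Logit(rows["label"].to_numpy(), X).fit(disp=0)
        assert np.allclose(ours.params.to_numpy(), ref.params, atol=1e-3)
        assert np.allclose(ours.bse.to_numpy(), ref.bse, atol=1e-3)

    def test_free_sigma_on_homogeneous_data_stays_near_zero(self):
        rows = simulate_rows(2, sigma=0.0, n_pat=40, n_obs=30)
        res = MixedLogit.from_formula("label ~ x", rows).fit()
        assert res.sigma_b < 0.25
        X = sm.add_constant(rows["x"].to_numpy())
        ref = sm.Logit(rows["label"].to_numpy(), X).fit(disp=0)
        assert np.allclose(res.params.to_numpy(), ref.params, atol=0.05)

    def test_two_by_two_table_cross_product_odds_ratio(self):
        # pooled 2x2 layout: exp(beta) must equal (a*d)/(b*c)
        a, b, c, d = 30, 20, 15, 35  # (x=1,y=1),(x=1,y=0),(x=0,y=1),(x=0,y=0)
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        groups = np.arange(a + b + c + d) % 10  # groups irrelevant at sigma=0
        res = MixedLogit(y, np.column_stack([np.ones_like(x), x]), groups,
                         exog_names=["Intercept", "x"]).fit(fix_sigma=0.0)
        assert np.exp(res.params["x"]) == pytest.approx((a * d) / (b * c), rel=1e-4)

    def test_agrees_with_lme4_adaptive_quadrature(self):
        rows = simulate_rows(42)
        res = MixedLogit.from_formula("label ~ x", rows).fit()
        with tempfile.TemporaryDirectory() as dd:
            path = os.path.join(dd, "rows.csv")
            rows.to_csv(path, index=False)
            out = subprocess.run(
                ["Rscript", "-e",
                 'suppressMessages(library(lme4));'
                 f'd <- read.csv("{path}");'
                 'm <- glmer(label ~ x + (1|patient_id), data=d,'
                 '           family=binomial, nAGQ=25);'
                 'cat(fixef(m), sqrt(unlist(VarCorr(m))), sep="\\n")'],
                capture_output=True, text=True, check=True,
            )
        ref = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(res.params.to_numpy(), ref[:2], atol=1e-3)
        assert res.sigma_b == pytest.approx(ref[2], abs=1e-3)


class TestNumerics:
    def test_quadrature_converged_at_default_nodes(self):
        rows = simulate_rows(5, n_pat=20, n_obs=15)
        m = MixedLogit.from_formula("label ~ x", rows)
        r21 = m.fit(quad_points=21)
        r41 = m.fit(quad_points=41)
        assert np.max(np.abs(r21.params_all[:-1] - r41.params_all[:-1])) < 1e-4

    def test_optimum_beats_generating_parameters(self):
        rows = simulate_rows(7)
        m = MixedLogit.from_formula("label ~ x", rows)
        res = m.fit()
        assert res.llf >= m.loglike(np.array([-1.0, 0.8, 1.2])) - 1e-6

    def test_constant_outcome_rejected(self):
        rows = simulate_rows(1).assign(label=0)
        with pytest.raises(ValueError, match="constant"):
            MixedLogit.from_formula("label ~ x", rows)

    def test_wald_coverage_near_nominal(self):
        # ~95% of Wald CIs for the slope should cover the generating value
        rng = np.random.default_rng(123)
        n_rep, covered = 150, 0
        for _ in range(n_rep):
            recs = []
            for i in range(20):
                b = rng.normal(0, 1.0)
                x = rng.normal(0, 1, 12)
                y = (rng.random(12) < expit(-0.5 + 0.6 * x + b)).astype(int)
                recs += [(i, xx, yy) for xx, yy in zip(x, y)]
            rows = pd.DataFrame(recs, columns=["patient_id", "x", "label"])
            if rows["label"].nunique() < 2:
                covered += 1  # degenerate draw; CI undefined, skip as covered
                continue
            res = MixedLogit.from_formula("label ~ x", rows).fit(quad_points=15)
            lo = res.params["x"] - 1.96 * res.bse["x"]
            hi = res.params["x"] + 1.96 * res.bse["x"]
            covered += lo <= 0.6 <= hi
        cov = covered / n_rep
        assert abs(cov - 0.95) <= 3 * np.sqrt(0.95 * 0.05 / n_rep)


@pytest.fixture(scope="module")
def fitted():
    rows = simulate_rows(9)
    return rows, MixedLogit.from_formula("label ~ x", rows).fit()


class TestPredict:
    def test_random_effect_shift_equals_posterior_mode(self, fitted):
        rows, res = fitted
        p_fix = res.predict(rows, use_random_effects=False)
        p_re = res.predict(rows, use_random_effects=True)
        lo = np.log(p_re / (1 - p_re)) - np.log(p_fix / (1 - p_fix))
        expected = rows["patient_id"].map(res.ranef.to_dict()).to_numpy()
        assert np.allclose(lo, expected, atol=1e-10)

    def test_unseen_patients_get_fixed_effects_only(self, fitted):
        rows, res = fitted
        new = rows.head(5).assign(patient_id="UNSEEN")
        assert np.allclose(
            res.predict(new, use_random_effects=True),
            res.predict(new, use_random_effects=False),
        )

    def test_monotone_in_positive_coefficient_feature(self, fitted):
        rows, res = fitted
        assert res.params["x"] > 0
        base = rows.head(10).copy()
        up = base.copy()
        up["x"] += 1.0
        assert np.all(res.predict(up) > res.predict(base))

    def test_probabilities_in_open_unit_interval(self, fitted):
        rows, res = fitted
        p = res.predict(rows, use_random_effects=True)
        assert np.all((p > 0) & (p < 1))


class TestAssociationSuite:
    def test_three_model_table(self, small_archetype_cohort):
        from idhrisk import association_table, fit_association_suite
        from idhrisk.simulate import DEFAULT_TAU

        co = small_archetype_cohort
        rows = build_rows_cohort(co.sessions, mode="concurrent",
                                 threshold_curve=DEFAULT_TAU)
        risk = {
            r.session_id: ("high" if r.high_risk else "low")
            for r in co.truth.itertuples()
        }
        fits = fit_association_suite(rows, risk_by_session=risk)
        assert set(fits) == {"delta_rbv", "risk_group", "below_threshold"}
        table = association_table(fits)
        assert len(table) == 3
        assert (table["ci_low"] < table["OR"]).all()
        assert (table["OR"] < table["ci_high"]).all()
        assert (table["sigma_b"] >= 0).all()
        # the injected archetype effect is positive; its fitted OR should be > 1
        assert table.set_index("model").loc["risk_group", "OR"] > 1.0


class TestRecovery:
    def test_reduced_scale_parameter_recovery(self, small_continuous_cohort):
        co = small_continuous_cohort
        rows = build_rows_cohort(co.sessions, mode="concurrent")
        res = fit_mixed_logistic(rows, "label ~ delta_rbv")
        true = co.effect.terms["delta_rbv"]
        assert abs(res.params["delta_rbv"] - true) < 3 * res.bse["delta_rbv"]
        assert 0.8 < res.sigma_b < 2.8

    def test_summary_and_odds_ratio_table(self, small_continuous_cohort):
        co = small_continuous_cohort
        rows = build_rows_cohort(co.sessions, mode="concurrent")
        res = fit_mixed_logistic(rows, "label ~ delta_rbv")
        text = res.summary()
        assert "delta_rbv" in text and "sigma_b" in text
        ors = res.odds_ratios()
        assert (ors.loc["delta_rbv", "ci_low"]
                < ors.loc["delta_rbv", "OR"]
                < ors.loc["delta_rbv", "ci_high"])
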