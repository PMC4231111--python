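import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cojopred import evaluate as ev


class TestLogistic:
    def test_intercept_only_closed_form(self, rng):
        y = np.array([1] * 30 + [0] * 70, dtype=float)
        fit = ev.fit_logistic(y)
        ybar = y.mean()
        assert fit.fitted == pytest.approx(ybar)
        expect_ll = 100 * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
        assert fit.llf == pytest.approx(expect_ll)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 500
        x = rng.standard_normal((n, 2))
        eta = -1.0 + 0.8 * x[:, 0] - 0.5 * x[:, 1]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = ev.fit_logistic(y, x)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params, rtol=1e-6)
        np.testing.assert_allclose(fit.llf, ref.llf, rtol=1e-8)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_positive_effect_recovered_in_simulation(self, rng):
        hits = 0
        for _ in range(20):
            n = 2000
            g = rng.standard_normal(n)
            eta = -2.2 + 0.4 * g
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = ev.fit_logistic(y, g[:, None])
            hits += fit.params[1] > 0
        assert hits >= 19

    def test_null_covariate_wald_calibrated(self, rng):
        inside = 0
        reps = 200
        for _ in range(reps):
            n = 400
            y = (rng.uniform(size=n) < 0.2).astype(float)
            if y.min() == y.max():
                inside += 1
                continue
            g = rng.standard_normal(n)
            fit = ev.fit_logistic(y, g[:, None])
            inside += abs(fit.zvalues[1]) < 1.96
        assert inside / reps >= 0.93

    def test_perfect_separation_raises(self):
        y = np.array([0.0] * 20 + [1.0] * 20)
        x = np.concatenate([np.zeros(20), np.ones(20)])[:, None]
        with pytest.raises(ev.SeparationError, match="penal"):
            ev.fit_logistic(y, x)

    def test_constant_covariate_rejected(self):
        y = np.array([0.0, 1.0] * 10)
        with pytest.raises(ev.EvaluationError):
            ev.fit_logistic(y, np.ones((20, 1)))


class TestAuc:
    def test_perfect_separation_is_one(self):
        scores = np.array([0.1, 0.2, 0.9, 0.8])
        status = np.array([0, 0, 1, 1])
        assert ev.auc(scores, status) == 1.0

    def test_all_ties_is_half(self):
        assert ev.auc(np.ones(10), np.array([0, 1] * 5)) == 0.5

    def test_matches_exhaustive_pair_count(self, rng):
        scores = rng.standard_normal(100)
        status = np.array([1] * 50 + [0] * 50)
        cases = scores[status == 1]
        controls = scores[status == 0]
        wins = sum(
            (c > d) + 0.5 * (c == d) for c, d in itertools.product(cases, controls)
        )
        assert ev.auc(scores, status) == pytest.approx(wins / (50 * 50), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.standard_normal(300)
        status = (rng.uniform(size=300) < 0.3).astype(int)
        assert ev.auc(scores, status) == pytest.approx(roc_auc_score(status, scores))

    def test_one_class_is_error(self):
        with pytest.raises(ev.EvaluationError):
            ev.auc(np.arange(5.0), np.ones(5, dtype=int))

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 1000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(60)
        status = np.array([0, 1] * 30)
        a = ev.auc(scores, status)
        b = ev.auc(np.exp(2 * scores) + 3, status)
        assert a == pytest.approx(b, abs=1e-12)


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        s = rng.standard_normal(50)
        status = np.array([0, 1] * 25)
        delta, z, p = ev.delong_compare(s, s, status)
        assert delta == 0.0
        assert p == 1.0

    def test_antisymmetric(self, rng):
        a = rng.standard_normal(80)
        b = rng.standard_normal(80)
        status = (rng.uniform(size=80) < 0.4).astype(int)
        d1, z1, p1 = ev.delong_compare(a, b, status)
        d2, z2, p2 = ev.delong_compare(b, a, status)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)

    def test_structural_components_small_fixture(self):
        """Placement values match hand enumeration on 5 cases / 5 controls."""
        scores = np.array([3.0, 1.0, 4.0, 2.5, 5.0, 0.5, 1.5, 2.0, 3.5, 0.0])
        status = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        cases, controls = scores[:5], scores[5:]
        a, v10, v01 = ev._placements(scores, status)
        v10_hand = np.array(
            [np.mean([(c > d) + 0.5 * (c == d) for d in controls]) for c in cases]
        )
        v01_hand = np.array(
            [np.mean([(c > d) + 0.5 * (c == d) for c in cases]) for d in controls]
        )
        np.testing.assert_allclose(v10, v10_hand)
        np.testing.assert_allclose(v01, v01_hand)
        assert a == pytest.approx(v10_hand.mean())

    def test_agrees_with_r_proc_style_variance(self, rng):
        # hand-computed DeLong variance on a fixed small example
        cases_a = np.array([2.1, 0.8, 1.5])
        ctrl_a = np.array([0.2, 1.0, -0.3, 0.6])
        cases_b = np.array([1.1, 1.9, 0.4])
        ctrl_b = np.array([0.9, 0.1, 0.5, 1.2])
        scores_a = np.concatenate([cases_a, ctrl_a])
        scores_b = np.concatenate([cases_b, ctrl_b])
        status = np.array([1, 1, 1, 0, 0, 0, 0])
        delta, z, p = ev.delong_compare(scores_a, scores_b, status)
        a1, v10a, v01a = ev._placements(scores_a, status)
        a2, v10b, v01b = ev._placements(scores_b, status)
        var = (
            np.cov(np.vstack([v10a, v10b]))[0, 0]
            + np.cov(np.vstack([v10a, v10b]))[1, 1]
            - 2 * np.cov(np.vstack([v10a, v10b]))[0, 1]
        ) / 3 + (
            np.cov(np.vstack([v01a, v01b]))[0, 0]
            + np.cov(np.vstack([v01a, v01b]))[1, 1]
            - 2 * np.cov(np.vstack([v01a, v01b]))[0, 1]
        ) / 4
        assert z == pytest.approx((a1 - a2) / np.sqrt(var))


class TestPseudoR2Aic:
    def test_nagelkerke_zero_when_no_improvement(self):
        assert ev.nagelkerke(-10.0, -10.0, 50) == 0.0

    def test_nagelkerke_one_at_perfect_fit(self):
        assert ev.nagelkerke(0.0, -20.0, 40) == pytest.approx(1.0)

    def test_nagelkerke_formula_fixture(self):
        # n=10, L0=-6.93, L1=-5.00
        expect = (1 - np.exp(2 * (-6.93 + 5.00) / 10)) / (1 - np.exp(2 * -6.93 / 10))
        assert ev.nagelkerke(-5.0, -6.93, 10) == pytest.approx(expect, rel=1e-12)

    def test_nagelkerke_rejects_non_nested(self):
        with pytest.raises(ev.EvaluationError):
            ev.nagelkerke(-7.0, -5.0, 10)

    def test_aic_arithmetic(self):
        assert ev.aic(-720.0, 3) == 1446.0
        assert ev.aic(0.0, 0) == 0.0

    def test_consistent_ranking_of_nested_models(self, rng):
        # higher LL => higher R2 and lower AIC at fixed k
        lls = sorted(rng.uniform(-100, -50, 5))
        r2 = [ev.nagelkerke(ll, -100.0, 200) for ll in lls]
        aics = [ev.aic(ll, 3) for ll in lls]
        assert r2 == sorted(r2)
        assert aics == sorted(aics, reverse=True)

    def test_useless_parameter_raises_aic_by_about_two(self, rng):
        # E[2*(LL gain)] for one junk covariate is ~1 (chi2_1), so AIC rises ~1 on average
        import statsmodels.api as sm

        diffs = []
        for _ in range(100):
            n = 300
            y = (rng.uniform(size=n) < 0.3).astype(float)
            x = rng.standard_normal(n)
            f0 = ev.fit_logistic(y)
            f1 = ev.fit_logistic(y, x[:, None])
            diffs.append(f1.aic - f0.aic)
        assert 0 < np.mean(diffs) <= 2.0


class TestLiabilityVariance:
    def test_no_effect_is_zero(self):
        assert ev.liability_variance_snp(1.0, 0.3, 0.10) == 0.0

    def test_monotone_in_odds_ratio(self):
        vals = [ev.liability_variance_snp(o, 0.3, 0.10) for o in [1.1, 1.3, 1.6, 2.0, 3.0]]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_vanishes_at_frequency_extremes(self):
        assert ev.liability_variance_snp(1.4, 1e-6, 0.10) < 1e-4
        assert ev.liability_variance_snp(1.4, 1 - 1e-6, 0.10) < 1e-4

    def test_matches_liability_monte_carlo(self, rng):
        """OR=1.4, p=0.3, K=0.10 against a genotype->liability->status
        simulation: regress liability on genotype at n=10^6."""
        or_, p, K = 1.4, 0.3, 0.10
        v = ev.liability_variance_snp(or_, p, K)
        # construct the implied liability shift per genotype and simulate
        from scipy import optimize, stats as sps

        fg = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        org = or_ ** np.arange(3)
        log_o0 = optimize.brentq(
            lambda lo: fg @ ((np.exp(lo) * org) / (1 + np.exp(lo) * org)) - K,
            np.log(1e-12),
            np.log(1e12),
        )
        pen = np.exp(log_o0) * org / (1 + np.exp(log_o0) * org)
        T = sps.norm.ppf(1 - K)
        mu = T - sps.norm.ppf(1 - pen)
        n = 1_000_000
        g = rng.binomial(2, p, n)
        liab = mu[g] + rng.standard_normal(n)
        # R^2 of liability on genotype, normalized by total liability variance
        r2 = np.corrcoef(g, liab)[0, 1] ** 2
        assert v == pytest.approx(r2, rel=0.10)
        # and the simulated prevalence is consistent with K
        assert abs((liab > T).mean() - K) < 0.01

    def test_set_is_additive_and_capped(self):
        single = ev.liability_variance_snp(1.4, 0.3, 0.10)
        pair = ev.liability_variance_set([(1.4, 0.3), (1.4, 0.3)], 0.10)
        assert pair == pytest.approx(2 * single)
        capped = ev.liability_variance_set([(50.0, 0.5)] * 50, 0.10)
        assert capped == 1.0

    def test_empty_set_is_zero(self):
        assert ev.liability_variance_set([], 0.10) == 0.0


class TestPredictionReport:
    def test_baseline_plus_grs_structure(self, rng):
        n = 600
        pheno = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "status": (rng.uniform(size=n) < 0.2).astype(int),
                "age": rng.uniform(45, 84, n),
                "sex": rng.integers(0, 2, n),
            }
        )
        g = rng.standard_normal(n)
        rep = ev.prediction_report(pheno, {"grs": g}, {"grs": [(1.3, 0.4)]})
        assert rep["models"]["label"].tolist() == ["baseline", "grs"]
        assert len(rep["pairs"]) == 1
        assert rep["models"]["auc"].between(0, 1).all()
        assert rep["models"]["nagelkerke_r2"].between(0, 1).all()
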