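import numpy as np
import pandas as pd
import pytest

from cojopred import datasets
from cojopred import simulate as sim
from cojopred.cojo import (
    CojoError,
    CollinearityError,
    JointGwas,
    estimate_ypy,
    thresholds_sweep,
)
from cojopred.ldpanel import LDView, ld_corr


def stats_frame(b, se, p, n, freq, snp=None, bp=None):
    k = len(b)
    return pd.DataFrame(
        {
            "snp": snp or [f"s{i}" for i in range(k)],
            "chrom": "1",
            "bp": bp if bp is not None else np.arange(k) * 1000,
            "a1": "G",
            "a2": "A",
            "freq": freq,
            "b": b,
            "se": se,
            "p": p,
            "n": n,
        }
    )


class TestYpy:
    def test_direct_arithmetic(self):
        # v=0.5, n=1000, b=0, s=0.1: ypy = 500*0.01*999 = 4995
        stats = stats_frame([0.0], [0.1], [0.5], [1000.0], [0.5])
        ypy, per = estimate_ypy(stats)
        assert ypy == pytest.approx(4995.0)
        assert per[0] == pytest.approx(4995.0)

    def test_median_of_identical_snps(self):
        stats = stats_frame([0.1, 0.1], [0.02, 0.02], [0.5, 0.5], [500.0, 500.0], [0.3, 0.3])
        ypy, per = estimate_ypy(stats)
        assert ypy == pytest.approx(per[0])
        assert per[0] == pytest.approx(per[1])

    def test_recovers_phenotype_sum_of_squares(self):
        # independent SNPs, quantitative trait: median reconstruction ~= sum((y-ybar)^2)
        rng = np.random.default_rng(3)
        sc = sim.SimScenario(
            freqs=rng.uniform(0.1, 0.9, 50),
            ld_latent=np.eye(50),
            causal=[(0, 0.1), (10, 0.15)],
            seed=3,
            gamma_age=0.0,
            gamma_sex=0.0,
        )
        panel = sim.simulate_panel(sc, 2000, rng)
        y = sim.simulate_quantitative(sc, panel, rng)
        stats = sim.marginal_linear(panel, y)
        ypy, _ = estimate_ypy(stats)
        truth = float(np.sum((y - y.mean()) ** 2))
        assert abs(ypy - truth) / truth < 0.05


class TestJointFit:
    def test_single_snp_recovers_marginal(self):
        from scipy.stats import norm

        p_wald = 2 * norm.sf(0.086 / 0.014)  # p consistent with b/se
        stats = stats_frame([0.086], [0.014], [p_wald], [117602.0], [0.451])
        res = JointGwas(stats, LDView(["s0"], np.eye(1))).fit()
        assert res.beta_joint[0] == pytest.approx(0.086)
        assert res.se_joint[0] == pytest.approx(0.014, rel=0.05)
        assert np.log10(res.p_joint[0]) == pytest.approx(np.log10(p_wald), abs=0.5)

    @pytest.mark.parametrize("locus", datasets.locus_names())
    def test_two_snp_worked_examples(self, locus):
        """Published two-SNP joint re-estimates are reproduced from the
        printed marginal statistics and pairwise LD alone."""
        sub, ld = datasets.locus_inputs(locus)
        res = JointGwas(sub, ld).fit()
        np.testing.assert_allclose(res.beta_joint, sub["bj"], atol=0.005)
        np.testing.assert_allclose(res.se_joint, sub["bj_se"], atol=0.005)

    def test_orthogonal_limit_returns_marginals_exactly(self):
        b = [0.1, -0.2, 0.05, 0.3]
        stats = stats_frame(b, [0.02] * 4, [1e-5] * 4, [5000.0] * 4, [0.2, 0.3, 0.4, 0.5])
        res = JointGwas(stats, LDView([f"s{i}" for i in range(4)], np.eye(4))).fit()
        np.testing.assert_allclose(res.beta_joint, b, rtol=1e-12)

    def test_two_snp_closed_form(self):
        # equal n: standardized joint beta1 = (b1s - r b2s) / (1 - r^2)
        r = -0.5
        freq = np.array([0.3, 0.6])
        v = 2 * freq * (1 - freq)
        b = np.array([0.12, 0.07])
        n = 40_000.0
        stats = stats_frame(b, [0.01, 0.01], [1e-8, 1e-8], [n, n], freq)
        ld = LDView(["s0", "s1"], np.array([[1, r], [r, 1.0]]))
        res = JointGwas(stats, ld).fit()
        bs = b * np.sqrt(v)  # standardized marginal effects
        expect_std = np.array(
            [(bs[0] - r * bs[1]) / (1 - r**2), (bs[1] - r * bs[0]) / (1 - r**2)]
        )
        np.testing.assert_allclose(res.beta_joint * np.sqrt(v), expect_std, atol=1e-10)

    def test_masked_pair_joint_exceeds_marginal(self):
        # both risk alleles positive, negative LD: joint > marginal for both
        freq = np.array([0.43, 0.75])
        stats = stats_frame([0.07, 0.08], [0.01, 0.012], [1e-10, 1e-10], [5e4, 5e4], freq)
        ld = LDView(["s0", "s1"], np.array([[1, -0.54], [-0.54, 1.0]]))
        res = JointGwas(stats, ld).fit()
        assert res.beta_joint[0] > 0.07
        assert res.beta_joint[1] > 0.08

    def test_collinear_pair_is_hard_error_naming_snps(self):
        stats = stats_frame([0.1, 0.1], [0.01, 0.01], [1e-9, 1e-9], [1e4, 1e4], [0.4, 0.4])
        ld = LDView(["s0", "s1"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(CollinearityError, match="s0"):
            JointGwas(stats, ld).fit()

    def test_empty_set_is_error(self):
        stats = stats_frame([0.1], [0.01], [1e-9], [1e4], [0.4])
        with pytest.raises(CojoError):
            JointGwas(stats, LDView(["s0"], np.eye(1))).fit([])


@pytest.fixture(scope="module")
def quantitative_cohort():
    rng = np.random.default_rng(42)
    m = 20
    sc = sim.SimScenario(
        freqs=rng.uniform(0.15, 0.85, m),
        ld_latent=sim._null_block_latent(m, block=5, rho=0.4),
        causal=[(2, 0.12), (7, -0.10), (13, 0.08)],
        seed=42,
        gamma_age=0.0,
        gamma_sex=0.0,
    )
    panel = sim.simulate_panel(sc, 2000, rng)
    y = sim.simulate_quantitative(sc, panel, rng)
    return panel, y


class TestExactnessOracle:
    def test_equals_multiple_regression_ols(self, quantitative_cohort):
        """Marginal stats + same-sample LD reproduce the individual-level
        multiple-regression coefficients to machine-level accuracy."""
        panel, y = quantitative_cohort
        stats = sim.marginal_linear(panel, y)
        ld = ld_corr(panel, stats["snp"].tolist())
        model = JointGwas(stats, ld, var=panel.dosage_variance())
        res = model.fit()
        X = np.column_stack([np.ones(panel.n_samples), panel.dosage])
        ols_beta = np.linalg.lstsq(X, y, rcond=None)[0][1:]
        np.testing.assert_allclose(res.beta_joint, ols_beta, rtol=1e-6)

    def test_standard_errors_close_to_ols(self, quantitative_cohort):
        panel, y = quantitative_cohort
        stats = sim.marginal_linear(panel, y)
        ld = ld_corr(panel, stats["snp"].tolist())
        res = JointGwas(stats, ld, var=panel.dosage_variance()).fit()
        X = np.column_stack([np.ones(panel.n_samples), panel.dosage])
        n, k = X.shape
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - k)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        ols_se = np.sqrt(np.diag(cov))[1:]
        np.testing.assert_allclose(res.se_joint, ols_se, rtol=0.05)


class TestConditional:
    def test_orthogonal_candidate_keeps_marginal(self):
        stats = stats_frame([0.2, 0.1], [0.02, 0.02], [1e-20, 1e-6], [1e4, 1e4], [0.5, 0.5])
        ld = LDView(["s0", "s1"], np.eye(2))
        model = JointGwas(stats, ld)
        b_c, se_c, p_c = model.conditional(["s0"], "s1")
        assert b_c == pytest.approx(0.1, rel=1e-9)
        assert np.log10(p_c) == pytest.approx(np.log10(1e-6), abs=1.0)

    def test_masked_candidate_conditional_exceeds_marginal(self):
        # analytic attenuation: marginal_std = beta(1 + r) < beta = conditional
        freq = np.array([0.43, 0.75])
        v = 2 * freq * (1 - freq)
        beta_std = 0.15
        r = -0.54
        b_marg_std = beta_std * (1 + r)
        b = b_marg_std / np.sqrt(v)
        stats = stats_frame(b, [0.01, 0.011], [1e-10, 1e-9], [5e4, 5e4], freq)
        ld = LDView(["s0", "s1"], np.array([[1, r], [r, 1.0]]))
        model = JointGwas(stats, ld)
        b_c, _, _ = model.conditional(["s0"], "s1")
        assert abs(b_c) > abs(b[1])

    def test_candidate_in_model_rejected(self):
        stats = stats_frame([0.1], [0.01], [1e-9], [1e4], [0.4])
        model = JointGwas(stats, LDView(["s0"], np.eye(1)))
        with pytest.raises(CojoError):
            model.conditional(["s0"], "s0")


class TestStepwise:
    def _region_model(self, seed=5, causal=((10, 0.25),), n=20_000):
        rng = np.random.default_rng(seed)
        sc = sim.SimScenario(
            freqs=rng.uniform(0.2, 0.8, 30),
            ld_latent=sim._null_block_latent(30),
            causal=list(causal),
            seed=seed,
            n_gwas=n,
        )
        out = sim.simulate(sc)
        ld = ld_corr(out.ref_panel, out.sumstats["snp"].tolist())
        return JointGwas(out.sumstats, ld), out

    def test_single_causal_region_selects_it_alone(self):
        model, out = self._region_model()
        res, trace = model.select(5e-8)
        assert res is not None
        assert res.snp_ids == ["snp0010"]

    def test_empty_model_when_nothing_significant(self):
        model, out = self._region_model(seed=6, causal=())
        res, trace = model.select(5e-8)
        assert res is None
        assert trace.events[-1].action == "stop"

    def test_trace_is_consistent_with_final_model(self):
        model, _ = self._region_model()
        res, trace = model.select(5e-8)
        assert set(trace.final_model()) == set(res.snp_ids)

    def test_deterministic(self):
        model, _ = self._region_model()
        res1, t1 = model.select(5e-8)
        res2, t2 = model.select(5e-8)
        assert res1.snp_ids == res2.snp_ids
        np.testing.assert_array_equal(res1.beta_joint, res2.beta_joint)

    def test_degenerate_threshold_bounded_by_guards(self):
        model, _ = self._region_model(n=5_000)
        res, trace = model.select(0.999999, max_iter=20)
        assert res is not None
        # growth halted by collinearity guard / candidate exhaustion / max_iter
        assert len(res.snp_ids) <= 30

    def test_masked_pair_both_selected(self, small_masked_sim):
        out = small_masked_sim
        ld = ld_corr(out.ref_panel, out.sumstats["snp"].tolist())
        model = JointGwas(out.sumstats, ld)
        res, trace = model.select(5e-8)
        assert set(out.truth["causal_snps"]) <= set(res.snp_ids)


class TestSweep:
    def test_default_sweep_has_five_thresholds(self):
        from cojopred.cojo import DEFAULT_THRESHOLDS

        assert len(DEFAULT_THRESHOLDS) == 5
        assert DEFAULT_THRESHOLDS[0] == 5e-8
        assert DEFAULT_THRESHOLDS[-1] == 5e-4

    def test_sweep_runs_each_threshold(self, small_masked_sim):
        out = small_masked_sim
        ld = ld_corr(out.ref_panel, out.sumstats["snp"].tolist())
        model = JointGwas(out.sumstats, ld)
        sweep = thresholds_sweep(model, (5e-8, 5e-4))
        assert set(sweep) == {5e-8, 5e-4}
        res8, _ = sweep[5e-8]
        res4, _ = sweep[5e-4]
        assert len(res4.snp_ids) >= len(res8.snp_ids) - 1  # no nesting guarantee
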