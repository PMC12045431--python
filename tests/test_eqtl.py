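import numpy as np
import pytest
from scipy import stats

from retqtl.eqtl import (
    EgenePermutationResult,
    allelic_fold_change,
    assign_qvalues,
    cis_window,
    fit_beta_mle,
    nominal_scan,
    per_gene_threshold,
    permutation_pass,
    storey_qvalues,
)


class TestCisWindow:
    def test_clamped_at_chromosome_start(self):
        assert cis_window(500_000) == (1, 1_500_000)

    def test_symmetric_interior(self):
        assert cis_window(2_000_000) == (1_000_000, 3_000_000)

    def test_bounds_inclusive(self):
        lo, hi = cis_window(2_000_000)
        assert hi == 2_000_000 + 1_000_000  # variant at exactly TSS+1 Mb is in


class TestNominalScan:
    def _data(self, n=100, m=8, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        cov = np.column_stack([rng.normal(size=n), rng.integers(0, 2, n)])
        return g, cov, rng

    def test_exact_recovery_without_noise(self):
        g, cov, rng = self._data()
        y = 0.5 * g[:, 0] + cov @ np.array([0.3, -0.2]) + 1.0
        res = nominal_scan(y, g, cov)
        assert res[0].slope == pytest.approx(0.5, abs=1e-10)
        assert res[0].nominal_p < 1e-200 or res[0].nominal_p == pytest.approx(0.0)

    def test_frisch_waugh_matches_full_multiple_regression(self):
        g, cov, rng = self._data(seed=1)
        y = rng.normal(size=g.shape[0]) + 0.2 * g[:, 2]
        res = nominal_scan(y, g, cov)
        for j in range(g.shape[1]):
            x_full = np.column_stack([np.ones(len(y)), g[:, j], cov])
            beta = np.linalg.lstsq(x_full, y, rcond=None)[0]
            assert res[j].slope == pytest.approx(beta[1], abs=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        n = 150
        cov = rng.normal(size=(n, 3))
        ps = []
        for _ in range(50):
            g = rng.binomial(2, 0.3, size=(n, 100)).astype(float)
            y = rng.normal(size=n)
            ps.extend(a.nominal_p for a in nominal_scan(y, g, cov))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_genotypes_mean_imputed(self):
        g, cov, rng = self._data(seed=3)
        y = 0.4 * g[:, 0] + rng.normal(scale=0.1, size=g.shape[0])
        g_missing = g.copy()
        g_missing[:5, 0] = np.nan
        res = nominal_scan(y, g_missing, cov)
        assert np.isfinite(res[0].slope)
        assert res[0].slope == pytest.approx(0.4, abs=0.1)

    def test_rank_deficient_covariates_rejected(self):
        g, cov, _ = self._data()
        bad = np.column_stack([cov, cov[:, 0]])
        with pytest.raises(ValueError, match="rank"):
            nominal_scan(np.ones(g.shape[0]), g, bad)


class TestPermutationPass:
    def test_single_variant_beta_fit_near_uniform(self):
        rng = np.random.default_rng(0)
        n = 200
        g = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        y = rng.normal(size=n)
        res = permutation_pass(y, g, np.empty((n, 0)), n_permutations=2000, seed=1)
        assert res.beta_a == pytest.approx(1.0, abs=0.08)
        assert res.beta_b == pytest.approx(1.0, abs=0.08)

    def test_planted_eqtl_beats_empirical_bound(self):
        rng = np.random.default_rng(1)
        n = 200
        g = rng.binomial(2, 0.3, size=(n, 30)).astype(float)
        y = 1.0 * g[:, 7] + rng.normal(size=n)
        res = permutation_pass(y, g, np.empty((n, 0)), n_permutations=500, seed=2)
        assert res.top_variant_id == "v7"
        assert res.adjusted_beta_p < res.empirical_p
        assert res.empirical_p == pytest.approx(1 / 501, abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        n = 100
        g = rng.binomial(2, 0.3, size=(n, 20)).astype(float)
        y = rng.normal(size=n)
        r1 = permutation_pass(y, g, np.empty((n, 0)), n_permutations=200, seed=5)
        r2 = permutation_pass(y, g, np.empty((n, 0)), n_permutations=200, seed=5)
        assert (r1.beta_a, r1.beta_b, r1.adjusted_beta_p) == (
            r2.beta_a, r2.beta_b, r2.adjusted_beta_p
        )

    def test_empirical_and_beta_adjusted_agree_on_null(self):
        rng = np.random.default_rng(4)
        n, b = 150, 400
        g = rng.binomial(2, 0.3, size=(n, 25)).astype(float)
        y = rng.normal(size=n)
        res = permutation_pass(y, g, np.empty((n, 0)), n_permutations=b, seed=6)
        assert abs(res.adjusted_beta_p - res.empirical_p) < 2 / np.sqrt(b)

    def test_zero_variance_phenotype_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            permutation_pass(np.ones(50), np.ones((50, 2)), np.empty((50, 0)))


class TestFitBetaMle:
    def test_uniform_draws_recover_one_one(self):
        rng = np.random.default_rng(0)
        a, b = fit_beta_mle(rng.uniform(size=10_000))
        assert 0.95 <= a <= 1.05
        assert 0.95 <= b <= 1.05

    def test_skewed_beta_recovery(self):
        rng = np.random.default_rng(1)
        a, b = fit_beta_mle(rng.beta(0.5, 40.0, size=10_000))
        assert a == pytest.approx(0.5, rel=0.10)
        assert b == pytest.approx(40.0, rel=0.10)

    def test_minima_of_k_uniforms_order_statistic(self):
        # min of k uniforms ~ Beta(1, k): closed-form oracle
        rng = np.random.default_rng(2)
        m = rng.uniform(size=(5000, 10)).min(axis=1)
        a, b = fit_beta_mle(m)
        assert a == pytest.approx(1.0, rel=0.10)
        assert b == pytest.approx(10.0, rel=0.10)

    def test_boundary_values_clamped_with_warning(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(size=500)
        vals[0] = 0.0
        with pytest.warns(UserWarning):
            a, b = fit_beta_mle(vals)
        assert a > 0 and b > 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_mle(np.array([0.5] * 5))


class TestStoreyQvalues:
    def test_all_ones_stay_one(self):
        assert np.allclose(storey_qvalues(np.ones(200)), 1.0)

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(0)
        frac = []
        for _ in range(20):
            q = storey_qvalues(rng.uniform(size=500))
            frac.append(np.mean(q <= 0.05))
        assert np.mean(frac) <= 0.01

    def test_mixture_recovers_signals_with_fdr_control(self):
        rng = np.random.default_rng(1)
        recov, fdps = [], []
        for _ in range(10):
            n_sig, n_null = 100, 900
            p = np.concatenate([
                rng.beta(0.05, 20, size=n_sig), rng.uniform(size=n_null)
            ])
            q = storey_qvalues(p)
            called = q <= 0.05
            recov.append(called[:n_sig].mean())
            fdps.append(called[n_sig:].sum() / max(called.sum(), 1))
        assert np.mean(recov) >= 0.80
        assert np.mean(fdps) <= 0.10

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=300)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([]))


def _perm_result(gene, p, a=1.0, b=50.0):
    return EgenePermutationResult(
        gene_id=gene, top_variant_id="v0", p_min_observed=p / 100,
        beta_a=a, beta_b=b, adjusted_beta_p=p, n_permutations=100,
        n_cis_variants=50, empirical_p=p,
    )


class TestPerGeneThreshold:
    def test_all_null_no_thresholds(self):
        rng = np.random.default_rng(0)
        results = [_perm_result(f"g{i}", p) for i, p in enumerate(rng.uniform(0.2, 1, 50))]
        assign_qvalues(results)
        assert per_gene_threshold(results) == {}

    def test_significant_gene_top_variant_within_threshold(self):
        rng = np.random.default_rng(1)
        results = [_perm_result(f"g{i}", p) for i, p in enumerate(rng.uniform(0.3, 1, 99))]
        results.append(_perm_result("hit", 1e-8))
        assign_qvalues(results)
        th = per_gene_threshold(results)
        assert set(th) == {"hit"}
        hit = next(r for r in results if r.gene_id == "hit")
        # p_min of the hit gene is below its own nominal threshold
        assert hit.p_min_observed <= th["hit"]

    def test_relaxing_fdr_never_shrinks_sets(self):
        rng = np.random.default_rng(2)
        ps = np.concatenate([rng.uniform(0, 0.002, 10), rng.uniform(0.2, 1, 90)])
        results = [_perm_result(f"g{i}", p) for i, p in enumerate(ps)]
        assign_qvalues(results)
        th_strict = per_gene_threshold(results, fdr=0.05)
        for r in results:
            r.p_t = np.nan
        th_loose = per_gene_threshold(results, fdr=0.10)
        assert set(th_strict) <= set(th_loose)
        for g in th_strict:
            assert th_loose[g] >= th_strict[g] - 1e-15


class TestAllelicFoldChange:
    def test_equal_group_means_give_zero(self):
        g = np.array([0.0] * 20 + [1.0] * 20 + [2.0] * 20)
        e = np.full(60, 7.0)
        assert allelic_fold_change(e, g) == pytest.approx(0.0, abs=1e-9)

    def test_model_consistent_means_exact(self):
        # m0=10, m1=15, m2=20 follows c·(2−g+g·2^k)/2 exactly with k=1
        g = np.array([0.0] * 30 + [1.0] * 30 + [2.0] * 30)
        e = np.where(g == 0, 10.0, np.where(g == 1, 15.0, 20.0))
        assert allelic_fold_change(e, g) == pytest.approx(1.0, abs=1e-8)

    def test_single_group_undefined(self):
        with pytest.raises(ValueError):
            allelic_fold_change(np.ones(10), np.zeros(10))

    def test_nb_noise_recovery(self):
        rng = np.random.default_rng(0)
        k_true = -1.5
        g = rng.binomial(2, 0.45, 500).astype(float)
        mu = 300.0 * (2 - g + g * 2.0**k_true) / 2
        e = rng.poisson(rng.gamma(1 / 0.08, mu * 0.08)).astype(float)
        assert allelic_fold_change(e, g) == pytest.approx(k_true, abs=0.15)

    def test_sign_matches_slope_direction(self, small_cohort):
        # planted positive effects give positive aFC and vice versa
        rng = np.random.default_rng(1)
        for k_true in (-1.0, 1.0):
            g = rng.binomial(2, 0.4, 300).astype(float)
            mu = 200.0 * (2 - g + g * 2.0**k_true) / 2
            e = rng.poisson(mu).astype(float)
            assert np.sign(allelic_fold_change(e, g)) == np.sign(k_true)

    def test_cap_applied(self):
        g = np.array([0.0] * 10 + [2.0] * 10)
        e = np.where(g == 0, 1.0, 1e6)
        assert allelic_fold_change(e, g) == pytest.approx(6.64, abs=1e-6)
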