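import numpy as np
import pytest
from scipy import stats

from murat.association import (
    EffectCovarianceSpec,
    adjusted_min_p,
    exchangeable_sqrt,
    murat_pvalue,
    murat_statistic,
    skat_pvalue,
    skat_pvalue_from_fit,
    variant_weights,
)
from murat.null_model import fit_null
from murat.qform import qform_pvalue


UNWEIGHTED = EffectCovarianceSpec(weight_beta_params=(1.0, 1.0))


class TestVariantWeights:
    def test_uniform_params_give_one(self, rng):
        mafs = rng.uniform(0.001, 0.5, 10)
        np.testing.assert_allclose(variant_weights(mafs, (1, 1)), 1.0)

    def test_rare_upweighted(self):
        w = variant_weights([0.01, 0.05], (1, 25))
        assert w[0] > w[1]

    def test_boundary_value(self):
        w = variant_weights([0.5], (1, 25))
        assert w[0] == pytest.approx(25 * 0.5**24)
        assert w[0] > 0

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            variant_weights([0.0])


class TestExchangeableSqrt:
    @pytest.mark.parametrize("K,rho", [(2, 0.0), (2, 0.5), (3, 0.9), (4, 0.99)])
    def test_squares_to_R(self, K, rho):
        Rh = exchangeable_sqrt(K, rho)
        R = (1 - rho) * np.eye(K) + rho * np.ones((K, K))
        np.testing.assert_allclose(Rh @ Rh, R, atol=1e-12)


class TestScoreStatistic:
    def test_hand_computed_single_variant_score_test(self):
        # 8-sample toy, v=1, K=1, intercept-only, unweighted: the score
        # test p equals the two-sided normal test recomputed from sums
        g = np.array([0.0, 1, 0, 2, 1, 0, 0, 1])
        y = np.array([2.1, 3.4, 1.9, 4.2, 2.8, 2.0, 2.4, 3.1])
        r = y - y.mean()
        s2 = (r @ r) / 7
        g_c = g - g.mean()
        z = (g_c @ r) / np.sqrt(s2 * (g_c @ g_c))
        p_hand = 2 * stats.norm.sf(abs(z))

        fit = fit_null(y)
        maf = g.sum() / (2 * len(g))
        Q, mix = murat_statistic(fit, g[:, None], [maf], UNWEIGHTED, rho=0.0)
        assert Q == pytest.approx((g_c @ r) ** 2 / s2**2, rel=1e-10)
        np.testing.assert_allclose(mix.lambdas, [(g_c @ g_c) / s2], rtol=1e-10)
        assert qform_pvalue(mix, Q) == pytest.approx(p_hand, rel=1e-8)

    def test_k1_reduces_to_skat(self, rng):
        for trial in range(5):
            n, v = 300, int(rng.choice([1, 5, 20]))
            mafs = rng.uniform(0.01, 0.3, v)
            G = rng.binomial(2, mafs, (n, v)).astype(float)
            keep = G.sum(0) > 0
            G, mafs = G[:, keep], mafs[keep]
            X = rng.standard_normal((n, 2))
            y = 1 + X @ [0.5, -0.3] + rng.standard_normal(n)
            fit = fit_null(y, X)
            res = murat_pvalue(fit, G, mafs, resamples=150, seed=trial)
            p_skat = skat_pvalue(y, X, G, mafs)
            assert res.final_p == pytest.approx(p_skat, rel=1e-8)

    def test_rho_zero_decomposes_over_phenotypes(self, rng):
        # with diagonal sigma_eps, Q(0) is the sum of per-phenotype SKAT
        # statistics, each divided by its error variance
        n, v = 200, 6
        mafs = rng.uniform(0.02, 0.3, v)
        G = rng.binomial(2, mafs, (n, v)).astype(float)
        Y = rng.standard_normal((n, 2))
        fit = fit_null(Y)
        fit.sigma_eps = np.diag(np.diag(fit.sigma_eps))  # force diagonal
        Q, _ = murat_statistic(fit, G, mafs, UNWEIGHTED, rho=0.0)
        total = 0.0
        w = variant_weights(mafs, (1, 1))
        D = fit.residualize(G) * w
        for k in range(2):
            s2 = fit.sigma_eps[k, k]
            score = D.T @ fit.resid[:, k]
            total += (score @ score) / s2**2
        assert Q == pytest.approx(total, rel=1e-10)

    def test_trace_identity(self, null_dataset):
        gm, block, G, mafs = null_dataset
        fit = fit_null(block.Y, block.X)
        spec = EffectCovarianceSpec()
        w = variant_weights(mafs, spec.weight_beta_params)
        D = fit.residualize(G) * w
        sigma_inv = np.linalg.inv(fit.sigma_eps)
        for rho in (0.0, 0.4, 0.99):
            _, mix = murat_statistic(fit, G, mafs, spec, rho)
            R = (1 - rho) * np.eye(2) + rho * np.ones((2, 2))
            expected = np.trace(R @ sigma_inv) * np.trace(D.T @ D)
            assert mix.trace == pytest.approx(expected, rel=1e-6)


class TestMuratPvalue:
    def test_final_p_dominates_min_p(self, null_dataset, rng):
        gm, block, G, mafs = null_dataset
        fit = fit_null(block.Y, block.X)
        for seed in range(3):
            res = murat_pvalue(fit, G, mafs, resamples=200, seed=seed)
            assert res.final_p >= res.min_p
            assert all(0 < p <= 1 for _, _, p in res.per_rho)
            assert res.n_variants == G.shape[1]

    def test_single_grid_point_no_adjustment(self, null_dataset):
        gm, block, G, mafs = null_dataset
        fit = fit_null(block.Y, block.X)
        spec = EffectCovarianceSpec(rho_grid=(0.3,))
        res = murat_pvalue(fit, G, mafs, spec=spec)
        assert res.final_p == res.min_p == res.per_rho[0][2]

    def test_deterministic_under_seed(self, null_dataset):
        gm, block, G, mafs = null_dataset
        fit = fit_null(block.Y, block.X)
        a = murat_pvalue(fit, G, mafs, resamples=200, seed=9)
        b = murat_pvalue(fit, G, mafs, resamples=200, seed=9)
        assert a.final_p == b.final_p and a.per_rho == b.per_rho

    def test_few_resamples_warns(self, null_dataset):
        gm, block, G, mafs = null_dataset
        fit = fit_null(block.Y, block.X)
        with pytest.warns(UserWarning):
            murat_pvalue(fit, G, mafs, resamples=50, seed=0)

    def test_monomorphic_region_rejected(self, null_dataset):
        gm, block, G, mafs = null_dataset
        fit = fit_null(block.Y, block.X)
        with pytest.raises(ValueError, match="monomorphic"):
            murat_pvalue(fit, np.zeros((block.n_samples, 2)), [0.1, 0.1])


class TestSkat:
    def test_null_distribution_calibrated(self):
        # 400 seeded null replicates: empirical size near alpha
        rng = np.random.default_rng(8)
        n, v, reps = 250, 8, 400
        hits = 0
        for _ in range(reps):
            mafs = rng.uniform(0.01, 0.2, v)
            G = rng.binomial(2, mafs, (n, v)).astype(float)
            keep = G.sum(0) > 0
            y = rng.standard_normal(n)
            p = skat_pvalue(y, None, G[:, keep], mafs[keep])
            hits += p <= 0.05
        assert 0.025 <= hits / reps <= 0.08

    def test_all_zero_region_errors(self, rng):
        y = rng.standard_normal(50)
        with pytest.raises(ValueError):
            skat_pvalue(y, None, np.zeros((50, 3)), [0.1, 0.1, 0.1])


class TestAdjustedMinP:
    @pytest.mark.parametrize(
        "ps,expected",
        [
            ((0.03, 0.2), 0.06),
            ((0.9, 0.8), 1.0),
            ((3.05e-3, 1.39e-1), 6.10e-3),  # doubling the smaller p
        ],
    )
    def test_examples(self, ps, expected):
        assert adjusted_min_p(ps) == pytest.approx(expected, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adjusted_min_p([])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjusted_min_p([0.0, 0.5])


class TestSpecValidation:
    def test_bad_grids(self):
        with pytest.raises(ValueError):
            EffectCovarianceSpec(rho_grid=(0.5, 0.2))
        with pytest.raises(ValueError):
            EffectCovarianceSpec(rho_grid=(0.2, 1.0))
        with pytest.raises(ValueError):
            EffectCovarianceSpec(rho_grid=())

    def test_bad_weights(self):
        with pytest.raises(ValueError):
            EffectCovarianceSpec(weight_beta_params=(0.0, 25.0))
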