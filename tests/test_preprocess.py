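import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from murat import preprocess
from murat.containers import PhenotypeBlock


def _block(Y, X=None, names=None):
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    n = Y.shape[0]
    X = np.empty((n, 0)) if X is None else np.asarray(X, dtype=float)
    return PhenotypeBlock(
        samples=[f"s{i}" for i in range(n)],
        Y=Y,
        X=X,
        phenotype_names=names or [f"y{k}" for k in range(Y.shape[1])],
        covariate_names=[f"x{j}" for j in range(X.shape[1])],
    )


class TestLogTransform:
    @pytest.mark.parametrize(
        "value,expected", [(math.e, 1.0), (1.0, 0.0), (100.0, math.log(100.0))]
    )
    def test_values(self, value, expected):
        block = _block([[value]], names=["y0"])
        out = preprocess.log_transform_phenotypes(block, ["y0"])
        assert out.Y[0, 0] == pytest.approx(expected, abs=1e-15)

    def test_constant_column_stays_constant(self):
        block = _block([[100.0], [100.0], [100.0]])
        out = preprocess.log_transform_phenotypes(block, ["y0"])
        assert np.var(out.Y[:, 0]) == 0.0

    def test_untouched_columns(self):
        block = _block(np.array([[2.0, 7.0], [3.0, 8.0]]), names=["a", "b"])
        out = preprocess.log_transform_phenotypes(block, ["a"])
        np.testing.assert_array_equal(out.Y[:, 1], block.Y[:, 1])

    def test_nonpositive_raises_with_sample_name(self):
        block = _block([[1.0], [-2.0]])
        with pytest.raises(ValueError, match="s1"):
            preprocess.log_transform_phenotypes(block, ["y0"])

    def test_exp_recovers_input(self, rng):
        vals = rng.uniform(50, 200, (30, 1))
        block = _block(vals)
        out = preprocess.log_transform_phenotypes(block, ["y0"])
        np.testing.assert_allclose(np.exp(out.Y), vals, rtol=1e-12)


class TestDropIncomplete:
    def test_missing_phenotype_dropped(self):
        Y = np.array([[1.0, 2], [3, np.nan], [5, 6], [7, 8], [9, 10]])
        out = preprocess.drop_incomplete_samples(_block(Y))
        assert out.n_samples == 4

    def test_identity_when_complete(self):
        block = _block(np.arange(6.0).reshape(3, 2))
        out = preprocess.drop_incomplete_samples(block)
        assert out.samples == block.samples

    def test_missing_covariate_also_dropped(self):
        block = _block(np.ones((3, 1)), X=np.array([[1.0], [np.nan], [3.0]]))
        out = preprocess.drop_incomplete_samples(block)
        assert out.n_samples == 2

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            preprocess.drop_incomplete_samples(_block([[np.nan], [np.nan]]))


class TestCorrelation:
    def test_identical_and_negated(self):
        y = np.array([1.0, 2, 4, 3, 5])
        block = _block(np.column_stack([y, y]), names=["a", "b"])
        assert preprocess.phenotype_correlation(block, "a", "b") == pytest.approx(1.0)
        block = _block(np.column_stack([y, -y]), names=["a", "b"])
        assert preprocess.phenotype_correlation(block, "a", "b") == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        block = _block(np.column_stack([np.ones(5), np.arange(5.0)]), names=["a", "b"])
        with pytest.raises(ValueError, match="zero variance"):
            preprocess.phenotype_correlation(block, "a", "b")

    def test_target_correlation_recovered_at_study_size(self):
        # Fisher z: at n=1851 the sampling sd of r at rho=0.542 is ~0.016,
        # so +-0.04 is a ~2.5 sigma band
        rng = np.random.default_rng(542)
        n, rho = 1851, 0.542
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        Y = rng.standard_normal((n, 2)) @ L.T
        block = _block(Y, names=["logSBP", "logDBP"])
        r = preprocess.phenotype_correlation(block, "logSBP", "logDBP")
        assert abs(r - rho) < 0.04


class TestMaf:
    @pytest.mark.parametrize(
        "dosages,expected",
        [([0, 0, 1, 2], 3 / 8), ([0, 0, 0, 0], 0.0), ([2, 2, 2, 1], 1 / 8)],
    )
    def test_examples(self, dosages, expected):
        assert preprocess.compute_maf(np.array(dosages, dtype=float)) == pytest.approx(
            expected
        )

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            preprocess.compute_maf(np.array([np.nan, np.nan]))


class TestImputation:
    def test_expected_dosage_fill_and_conservation(self):
        d = np.array([0.0, 1.0, np.nan])
        out = preprocess.impute_missing(d, maf=0.25)
        np.testing.assert_array_equal(out, [0.0, 1.0, 0.5])
        assert preprocess.compute_maf(out) == 0.25

    def test_no_missing_identity(self):
        d = np.array([0.0, 1.0, 2.0])
        np.testing.assert_array_equal(preprocess.impute_missing(d), d)

    def test_monomorphic_fill_zero(self):
        d = np.array([0.0, 0.0, np.nan])
        np.testing.assert_array_equal(preprocess.impute_missing(d, maf=0.0), [0, 0, 0])

    def test_inconsistent_maf_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            preprocess.impute_missing(np.array([0.0, 1.0, np.nan]), maf=0.4)

    def test_bit_exact_conservation_randomized(self):
        # minor-alt variants with 0-30% missingness: conservation is exact
        rng = np.random.default_rng(99)
        for _ in range(300):
            n = int(rng.integers(10, 300))
            d = rng.binomial(2, rng.uniform(0.005, 0.45), n).astype(float)
            d[rng.random(n) < rng.uniform(0, 0.3)] = np.nan
            if np.isnan(d).all() or np.nanmean(d) / 2 > 0.5:
                continue
            before = preprocess.compute_maf(d)
            after = preprocess.compute_maf(preprocess.impute_missing(d))
            assert after == before  # bit-level

    def test_alt_frequency_conserved_when_folded(self):
        d = np.array([2.0, 2.0, 1.0, 2.0, np.nan, np.nan, 1.0])
        f_before = preprocess.alt_allele_frequency(d)
        out = preprocess.impute_missing(d)
        assert preprocess.alt_allele_frequency(out) == f_before
        assert preprocess.compute_maf(out) == pytest.approx(
            preprocess.compute_maf(d), abs=1e-15
        )


class TestCarrierFilter:
    @pytest.mark.parametrize(
        "dosages,min_carriers,expected",
        [
            ([0, 1, 1, 1, 1, 0], 4, True),
            ([0, 1, 1, 1, 0, 0], 4, False),
            ([2, 0, 0, 0], 4, False),  # homozygote counts once
        ],
    )
    def test_examples(self, dosages, min_carriers, expected):
        d = np.array(dosages, dtype=float)
        assert preprocess.carrier_filter(d, min_carriers) is expected

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=1, max_size=40),
        st.integers(1, 10),
    )
    def test_monotone_in_threshold(self, dosages, k):
        d = np.array(dosages)
        if preprocess.carrier_filter(d, k + 1):
            assert preprocess.carrier_filter(d, k)


def test_qc_config_validation():
    with pytest.raises(ValueError):
        preprocess.QcConfig(min_carriers=0)
    with pytest.raises(ValueError):
        preprocess.QcConfig(maf_upper=0.6)
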