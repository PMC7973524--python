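import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import hicloops as hl
from hicloops.background import MIN_FIT_SIZE, WeibullFitError
from hicloops.matrix import DiagonalValues, MatrixConfigError

from conftest import brute_force_bh


def _diag(values):
    values = np.asarray(values, dtype=float)
    return DiagonalValues(d=1, values=values, mappable=np.ones(len(values), bool))


class TestFitWeibull:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(11)
        x = 2.0 * rng.weibull(1.5, size=10_000)
        params = hl.fit_weibull(_diag(x), fit_quantile=1.0)
        assert params.shape == pytest.approx(1.5, abs=0.05)
        assert params.scale == pytest.approx(2.0, abs=0.05)
        assert params.n_fit == 10_000

    def test_exponential_is_weibull_shape_one(self):
        rng = np.random.default_rng(12)
        x = rng.exponential(1.0, size=10_000)
        params = hl.fit_weibull(_diag(x), fit_quantile=1.0)
        assert params.shape == pytest.approx(1.0, abs=0.05)
        assert params.scale == pytest.approx(1.0, abs=0.05)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(WeibullFitError):
            hl.fit_weibull(_diag(np.full(200, 3.0)), fit_quantile=1.0)

    def test_too_few_values(self):
        with pytest.raises(WeibullFitError):
            hl.fit_weibull(_diag(np.arange(1, MIN_FIT_SIZE)), fit_quantile=1.0)

    def test_quantile_trimming_reduces_n_fit(self):
        rng = np.random.default_rng(13)
        x = rng.weibull(2.0, size=1000)
        params = hl.fit_weibull(_diag(x), fit_quantile=0.9)
        assert params.n_fit <= 901

    def test_zeros_excluded_by_default(self):
        rng = np.random.default_rng(14)
        x = np.concatenate([rng.weibull(1.5, 500), np.zeros(100)])
        p_excl = hl.fit_weibull(_diag(x), fit_quantile=1.0)
        assert p_excl.n_fit == 500
        p_incl = hl.fit_weibull(_diag(x), fit_quantile=1.0, include_zeros=True)
        assert p_incl.n_fit == 600


class TestSurvivalPvalue:
    def test_at_origin(self):
        params = hl.WeibullParams(d=1, shape=1.5, scale=2.0)
        assert hl.survival_pvalue(0.0, params) == 1.0

    @pytest.mark.parametrize("shape,scale", [(0.7, 0.5), (1.0, 1.0), (2.5, 3.0)])
    def test_at_scale_is_inverse_e(self, shape, scale):
        params = hl.WeibullParams(d=1, shape=shape, scale=scale)
        assert hl.survival_pvalue(scale, params) == pytest.approx(
            math.exp(-1), abs=1e-12
        )

    def test_closed_form(self):
        params = hl.WeibullParams(d=1, shape=2.0, scale=1.0)
        assert hl.survival_pvalue(2.0, params) == pytest.approx(
            math.exp(-4), rel=1e-12
        )

    def test_strictly_decreasing(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            params = hl.WeibullParams(
                d=1, shape=rng.uniform(0.5, 4), scale=rng.uniform(0.1, 5)
            )
            x = np.sort(rng.uniform(0.01, 3 * params.scale, size=50))
            p = hl.survival_pvalue(x, params)
            # strictly decreasing wherever p has not underflowed to zero
            assert np.all(np.diff(p) <= 0)
            pos = p > 1e-300
            assert np.all(np.diff(p[pos]) < 0)

    def test_agrees_with_scipy_survival(self):
        params = hl.WeibullParams(d=1, shape=1.7, scale=2.3)
        x = np.linspace(0.01, 10, 100)
        np.testing.assert_allclose(
            hl.survival_pvalue(x, params),
            stats.weibull_min.sf(x, params.shape, scale=params.scale),
            rtol=1e-10,
        )


class TestBHCorrect:
    def test_worked_example(self):
        np.testing.assert_allclose(
            hl.bh_correct([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_value_identity(self):
        np.testing.assert_allclose(hl.bh_correct([0.2]), [0.2])

    def test_ties_stay_equal(self):
        np.testing.assert_allclose(hl.bh_correct([0.4] * 7), [0.4] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hl.bh_correct([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 1000))
        p = rng.uniform(size=n)
        q = hl.bh_correct(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_step_up_property(self, p):
        """q-values dominate p-values, stay in [0, 1], and match the
        brute-force step-up for arbitrary inputs including ties and
        endpoints."""
        q = hl.bh_correct(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
        assert np.all(q <= 1.0)
        assert np.all(q >= np.asarray(p) - 1e-15)


class TestScaling:
    def _matrix_with_diag_means(self, means):
        # constant diagonals => means are exact
        n = 40
        dense = np.zeros((n, n))
        for d, m in enumerate(means):
            idx = np.arange(n - d)
            dense[idx, idx + d] = m
        return hl.ContactMatrix.from_dense(dense)

    def test_direct_ratio(self):
        cm = self._matrix_with_diag_means([10, 5, 2])
        sc = hl.scaling_coefficients(cm, 0, 3)
        np.testing.assert_allclose(sc.coeffs, [1.0, 0.5, 0.2])

    def test_flat_scaling_all_ones(self):
        cm = self._matrix_with_diag_means([3, 3, 3, 3])
        sc = hl.scaling_coefficients(cm, 0, 4)
        np.testing.assert_allclose(sc.coeffs, 1.0)

    def test_zero_first_diagonal_rejected(self):
        cm = self._matrix_with_diag_means([0, 5, 2])
        with pytest.raises(MatrixConfigError):
            hl.scaling_coefficients(cm, 0, 3)

    def test_outside_range_coefficient_is_one(self):
        cm = self._matrix_with_diag_means([10, 5, 2])
        sc = hl.scaling_coefficients(cm, 0, 3)
        assert sc.coeff(17) == 1.0

    def test_adjust_divides_and_clamps(self):
        import pandas as pd

        calls = pd.DataFrame(
            {"i": [0, 0, 0], "j": [1, 2, 3], "q": [0.1, 0.3, 0.9]}
        )
        sc = hl.ScalingCoefficients(1, 4, np.array([1.0, 0.5, 0.5]))
        out = hl.adjust_by_scale(calls, sc)
        np.testing.assert_allclose(out["q_adj"], [0.1, 0.6, 1.0])


class TestSignificantPixelMask:
    def test_spiked_pixel_is_significant(self):
        cfg = hl.SyntheticConfig(n_bins=200, seed=3)
        cm = hl.generate_background(cfg)
        dense = cm.dense()
        d = 30
        lam = cfg.base_scale * (d + 1) ** -1.0
        dense[60, 60 + d] = 50 * lam
        cm2 = hl.ContactMatrix.from_dense(np.triu(dense))
        res = hl.significant_pixel_mask(cm2, q_threshold=0.1)
        hit = res.calls[(res.calls.i == 60) & (res.calls.j == 90)]
        assert len(hit) == 1
        assert hit.q_adj.iloc[0] <= 0.1

    def test_all_masked_region_is_empty_not_error(self):
        cm = hl.ContactMatrix.from_dense(np.zeros((30, 30)))
        cm.bin_valid[:] = False
        res = hl.significant_pixel_mask(cm)
        assert res.n_tested == 0
        assert len(res.calls) == 0

    def test_unmodeled_diagonals_reported(self):
        # 60 bins: far diagonals are too short for the minimum fit size
        # (upper-quantile trimming shrinks them further)
        cfg = hl.SyntheticConfig(n_bins=60, seed=4)
        cm = hl.generate_background(cfg)
        res = hl.significant_pixel_mask(cm)
        assert res.unmodeled_diagonals  # some diagonals must be too short
        assert all(60 - d < MIN_FIT_SIZE / 0.95 + 2
                   for d in res.unmodeled_diagonals)
        assert all(p.n_fit >= MIN_FIT_SIZE for p in res.models.values())
        assert set(res.models).isdisjoint(res.unmodeled_diagonals)

    def test_raw_pvalues_uniform_under_null(self):
        cfg = hl.SyntheticConfig(n_bins=300, seed=5)
        cm = hl.generate_background(cfg)
        res = hl.significant_pixel_mask(cm, fit_quantile=1.0, return_all=True)
        p = res.all_calls["p"].to_numpy()
        assert len(p) > 5000
        assert stats.kstest(p, "uniform").statistic < 0.02

    def test_bh_scope_matrix_runs(self):
        cfg = hl.SyntheticConfig(n_bins=100, seed=6)
        cm = hl.generate_background(cfg)
        res = hl.significant_pixel_mask(cm, bh_scope="matrix", return_all=True)
        assert (res.all_calls.q >= res.all_calls.p - 1e-12).all()


class TestFitDiagnostics:
    def test_self_consistency(self):
        rng = np.random.default_rng(21)
        x = 1.3 * rng.weibull(1.6, size=5000)
        dv = _diag(x)
        params = hl.fit_weibull(dv, fit_quantile=1.0)
        rec = hl.fit_diagnostics(dv, params)
        assert rec.ks_distance < 0.02
        assert rec.n_fit == 5000

    def test_misspecified_model_fits_worse(self):
        rng = np.random.default_rng(22)
        good = 1.0 * rng.weibull(1.6, size=4000)
        # heavy-tailed mixture: mostly small values plus a lognormal tail
        bad = np.concatenate(
            [rng.weibull(1.6, 3200), rng.lognormal(1.5, 1.0, 800)]
        )
        dv_good, dv_bad = _diag(good), _diag(bad)
        ks_good = hl.fit_diagnostics(
            dv_good, hl.fit_weibull(dv_good, fit_quantile=1.0)
        ).ks_distance
        ks_bad = hl.fit_diagnostics(
            dv_bad, hl.fit_weibull(dv_bad, fit_quantile=1.0)
        ).ks_distance
        assert ks_bad > ks_good

    def test_diagnostics_table_columns(self):
        cfg = hl.SyntheticConfig(n_bins=120, seed=23)
        cm = hl.generate_background(cfg)
        res = hl.significant_pixel_mask(cm)
        table = hl.background.diagnostics_table(cm, res.models)
        assert {"diagonal", "distance_bp", "shape", "scale", "n_fit",
                "ks_distance"} <= set(table.columns)
        assert (table["ks_distance"] < 0.2).all()
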