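"""Phenotype preparation: residualisation, vdW transform, ICC, FDR, ANOVA, alpha."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twinconfound import (
    TwinSimConfig,
    correlation_matrix_fdr,
    cronbach_alpha,
    intraclass_correlation,
    residualize,
    simulate_univariate_twins,
    variance_by_sex_zygosity,
    vdw_transform,
)
from twinconfound.preprocess import DegenerateDataError


class TestResidualize:
    def test_uncorrelated_predictors_are_a_noop(self, rng):
        n = 20000
        v = rng.standard_normal(n)
        age = rng.normal(22, 1, n)
        sex = rng.integers(0, 2, n)
        out = residualize(v, age, sex)
        assert np.corrcoef(out, v)[0, 1] > 0.999

    def test_residuals_orthogonal_to_age(self, rng):
        age = rng.normal(22, 1, 10000)
        # cor(values, age) ~ 0.6 by construction
        v = (age - age.mean()) / age.std() * 0.6 + np.sqrt(1 - 0.36) * rng.standard_normal(10000)
        out = residualize(v, age, rng.integers(0, 2, 10000))
        assert np.corrcoef(out, age)[0, 1] == pytest.approx(0.0, abs=0.02)

    def test_phenotype_equal_to_age_is_degenerate(self, rng):
        age = rng.normal(22, 1, 100)
        with pytest.warns(UserWarning, match="degenerate"):
            out = residualize(2 * age, age, rng.integers(0, 2, 100))
        assert np.allclose(out, 0.0)

    def test_missing_values_propagate(self, rng):
        v = rng.standard_normal(100)
        v[3] = np.nan
        out = residualize(v, rng.normal(22, 1, 100), rng.integers(0, 2, 100))
        assert np.isnan(out[3]) and not np.isnan(np.delete(out, 3)).any()

    def test_all_missing_errors(self):
        with pytest.raises(DegenerateDataError):
            residualize(np.full(10, np.nan), np.arange(10.0), np.zeros(10))


class TestVdwTransform:
    def test_three_values_map_to_quartile_normal_scores(self):
        out = vdw_transform(np.array([1.0, 2.0, 3.0]))
        expected = stats.norm.ppf([0.25, 0.5, 0.75])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out[1] == 0.0

    def test_kills_skewness(self, rng):
        from twinconfound.simulate import skew_warp

        x = skew_warp(rng.standard_normal(5000))
        out = vdw_transform(x)
        assert stats.skew(out) == pytest.approx(0.0, abs=0.1)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=60, unique=True))
    def test_monotone_on_untied_input(self, values):
        v = np.asarray(values)
        out = vdw_transform(v)
        assert stats.spearmanr(v, out).statistic == pytest.approx(1.0)

    def test_constant_input_errors(self):
        with pytest.raises(DegenerateDataError):
            vdw_transform(np.ones(10))


class TestIntraclassCorrelation:
    @staticmethod
    def _table(x1, x2, zyg="MZ"):
        n = len(x1)
        return pd.DataFrame(
            {
                "family_id": np.arange(n),
                "zygosity": [zyg] * n,
                "sex1": 0, "sex2": 0, "age": 22.0,
                "t_1": x1, "t_2": x2,
            }
        )

    def test_identical_cotwins_give_one(self, rng):
        x = rng.standard_normal(100)
        rep = intraclass_correlation(self._table(x, x.copy()), "t", "MZ")
        assert rep.r == pytest.approx(1.0)

    def test_permuted_cotwins_give_zero(self, rng):
        x = rng.standard_normal(5000)
        rep = intraclass_correlation(self._table(x, rng.permutation(x)), "t", "MZ")
        assert rep.r == pytest.approx(0.0, abs=0.03)

    def test_recovers_simulated_mz_correlation(self):
        df = simulate_univariate_twins(
            TwinSimConfig(n_mz=20000, n_dz=1, a2=0.43, c2=0.0, e2=0.57, seed=2)
        )
        rep = intraclass_correlation(df, "trait", "MZ")
        assert rep.r == pytest.approx(0.43, abs=0.02)
        assert rep.n == 20000

    def test_invariant_to_within_pair_ordering(self, rng):
        x1, x2 = rng.standard_normal(50), rng.standard_normal(50)
        a = intraclass_correlation(self._table(x1, x2), "t", "MZ")
        b = intraclass_correlation(self._table(x2, x1), "t", "MZ")
        assert a.r == b.r

    def test_too_few_pairs_errors(self, rng):
        with pytest.raises(DegenerateDataError):
            intraclass_correlation(
                self._table(rng.standard_normal(2), rng.standard_normal(2)), "t", "MZ"
            )


def _bh_bruteforce(p):
    """Direct step-up definition: p_(i) * m / i, cumulative-min from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestCorrelationMatrixFdr:
    def test_adjusted_p_matches_stepup_example(self, rng):
        # engineered so raw p ~= [0.002, 0.01, 0.03, 0.04] -> check via brute force
        from statsmodels.stats.multitest import multipletests

        p = [0.002, 0.01, 0.03, 0.04]
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], [0.008, 0.02, 0.04, 0.04], atol=1e-12
        )
        np.testing.assert_allclose(_bh_bruteforce(p), [0.008, 0.02, 0.04, 0.04], atol=1e-12)

    def test_single_test_unchanged(self, rng):
        x = rng.standard_normal(200)
        left = pd.DataFrame({"a": x})
        right = pd.DataFrame({"b": 0.3 * x + rng.standard_normal(200)})
        rep = correlation_matrix_fdr(left, right)
        assert rep["p_fdr"].iloc[0] == pytest.approx(rep["p_raw"].iloc[0])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=40)
    )
    def test_bh_matches_bruteforce_stepup(self, pvals):
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            multipletests(pvals, method="fdr_bh")[1], _bh_bruteforce(pvals), atol=1e-12
        )

    def test_zero_variance_cell_reported_missing(self, rng):
        left = pd.DataFrame({"a": rng.standard_normal(100), "const": np.ones(100)})
        right = pd.DataFrame({"b": rng.standard_normal(100)})
        rep = correlation_matrix_fdr(left, right)
        assert np.isnan(rep.set_index("left").loc["const", "r"])
        assert np.isfinite(rep.set_index("left").loc["a", "r"])

    def test_full_family_reported_with_cis(self, rng):
        left = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("abc"))
        right = pd.DataFrame(rng.standard_normal((500, 2)), columns=list("xy"))
        rep = correlation_matrix_fdr(left, right)
        assert len(rep) == 6
        assert ((rep["ci_low"] <= rep["r"]) & (rep["r"] <= rep["ci_high"])).all()
        assert (rep["p_fdr"] >= rep["p_raw"] - 1e-15).all()


class TestVarianceBySexZygosity:
    @staticmethod
    def _pairs(y1, y2, sex1, sex2, zyg):
        n = len(y1)
        return pd.DataFrame(
            {
                "family_id": np.arange(n),
                "zygosity": zyg,
                "sex1": sex1, "sex2": sex2, "age": 22.0,
                "t_1": y1, "t_2": y2,
            }
        )

    def test_null_phenotype_has_tiny_joint_share(self, rng):
        hits = 0
        for rep in range(100):
            n = 5000
            zyg = np.where(rng.random(n) < 0.4, "MZ", "DZss")
            s = rng.integers(0, 2, n)
            df = self._pairs(rng.standard_normal(n), rng.standard_normal(n), s, s, zyg)
            eta = variance_by_sex_zygosity(df, "t", seed=rep)
            hits += eta["joint"] < 0.01
        assert hits >= 95

    def test_phenotype_equal_to_sex_is_fully_explained(self, rng):
        n = 500
        s = rng.integers(0, 2, n)
        zyg = np.where(rng.random(n) < 0.5, "MZ", "DZss")
        df = self._pairs(s.astype(float), s.astype(float), s, s, zyg)
        eta = variance_by_sex_zygosity(df, "t", seed=0)
        assert eta["sex"] == pytest.approx(1.0, abs=1e-10)

    def test_engineered_zygosity_share_recovered(self, rng):
        n = 20000
        zyg_code = (rng.random(n) < 0.5).astype(float)
        zyg = np.where(zyg_code == 1, "MZ", "DZss")
        # share = b^2*var(zyg) / (b^2*var(zyg) + 1) = 0.2 with var(zyg)=0.25 -> b = 1
        y = 1.0 * zyg_code + rng.standard_normal(n)
        s = rng.integers(0, 2, n)
        df = self._pairs(y, y, s, s, zyg)
        eta = variance_by_sex_zygosity(df, "t", seed=1)
        assert eta["joint"] == pytest.approx(0.20, abs=0.03)


class TestCronbachAlpha:
    def test_two_items_with_half_correlation(self, rng):
        n = 200000
        z = rng.standard_normal(n)
        w = np.sqrt(0.5)
        items = np.column_stack(
            [w * z + w * rng.standard_normal(n), w * z + w * rng.standard_normal(n)]
        )
        assert cronbach_alpha(items) == pytest.approx(2 / 3, abs=0.01)

    def test_identical_items_give_one(self, rng):
        x = rng.standard_normal(100)
        assert cronbach_alpha(np.column_stack([x] * 4)) == pytest.approx(1.0)

    def test_independent_items_give_zero(self, rng):
        assert cronbach_alpha(rng.standard_normal((10000, 6))) == pytest.approx(
            0.0, abs=0.05
        )

    def test_zero_total_variance_errors(self):
        with pytest.raises(DegenerateDataError):
            cronbach_alpha(np.tile([1.0, -1.0], (10, 1)))
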