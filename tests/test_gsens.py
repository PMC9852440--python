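"""Gsens: scenario scaling, adjusted effects, confounding proportions."""

import numpy as np
import pytest

from twinconfound import (
    GpsSimConfig,
    GsensInput,
    adjusted_effect,
    scale_to_heritability,
    scenario_analysis,
    simulate_gps_cohort,
)
from twinconfound.gsens import ScalingError


def _sample_input(df, n=None, **h2):
    r = np.corrcoef(df[["GPS", "X", "Y"]], rowvar=False)
    return GsensInput(r_gx=r[0, 1], r_gy=r[0, 2], r_xy=r[1, 2],
                      n=n or len(df), **h2)


class TestScaling:
    def test_scaling_to_observed_r2_is_a_noop(self):
        inp = GsensInput(r_gx=0.1, r_gy=0.2, r_xy=0.3)
        out = scale_to_heritability(inp, h2=0.04)
        assert out.r_gx == pytest.approx(0.1, abs=1e-12)
        assert out.r_gy == pytest.approx(0.2, abs=1e-12)

    def test_closed_form_scaling(self):
        out = scale_to_heritability(GsensInput(r_gx=0.1, r_gy=0.2, r_xy=0.3), h2=0.5)
        assert out.r_gy == pytest.approx(np.sqrt(0.5), abs=1e-6)
        assert out.r_gx == pytest.approx(0.1 * np.sqrt(0.5) / 0.2, abs=1e-6)
        assert out.r_xy == 0.3

    def test_zero_exposure_correlation_stays_zero(self):
        out = scale_to_heritability(GsensInput(r_gx=0.0, r_gy=0.2, r_xy=0.3), h2=0.6)
        assert out.r_gx == 0.0

    def test_zero_outcome_correlation_is_undefined(self):
        with pytest.raises(ScalingError, match="undefined"):
            scale_to_heritability(GsensInput(r_gx=0.1, r_gy=0.0, r_xy=0.3), h2=0.5)

    def test_impossible_scaling_is_rejected(self):
        # strong exposure pull + high h2 makes the matrix indefinite
        with pytest.raises(ScalingError, match="positive definite"):
            scale_to_heritability(GsensInput(r_gx=0.25, r_gy=0.1, r_xy=0.0), h2=0.9)


class TestAdjustedEffect:
    def test_no_genetic_path_means_no_attenuation(self):
        res = adjusted_effect(GsensInput(r_gx=0.0, r_gy=0.3, r_xy=0.3))
        assert res.b_adjusted == pytest.approx(0.3, abs=1e-12)
        assert res.attenuation_pct == pytest.approx(0.0, abs=1e-10)

    def test_fully_confounded_configuration(self):
        res = adjusted_effect(GsensInput(r_gx=0.2, r_gy=0.3, r_xy=0.06))
        assert res.b_adjusted == pytest.approx(0.0, abs=1e-12)
        assert res.attenuation_pct == pytest.approx(100.0, abs=1e-10)

    def test_worked_case_matches_least_squares_oracle(self, rng):
        inp = GsensInput(r_gx=0.3536, r_gy=0.7071, r_xy=0.3)
        res = adjusted_effect(inp)
        # oracle: OLS of Y on (X, G) in data whitened to the exact correlations
        n = 4000
        Z = rng.standard_normal((n, 3))
        Z -= Z.mean(axis=0)
        Z = Z @ np.linalg.inv(np.linalg.cholesky(np.cov(Z, rowvar=False)).T)
        D = Z @ np.linalg.cholesky(inp.matrix()).T  # exact sample moments
        G, X, Y = D[:, 0], D[:, 1], D[:, 2]
        beta = np.linalg.lstsq(np.column_stack([X, G]), Y, rcond=None)[0]
        assert res.b_adjusted == pytest.approx(beta[0], abs=1e-6)
        assert res.b_adjusted == pytest.approx(0.0571, abs=5e-5)
        assert res.attenuation_pct == pytest.approx(81.0, abs=0.05)

    def test_agrees_with_two_predictor_normal_equations(self):
        inp = GsensInput(r_gx=0.15, r_gy=0.25, r_xy=0.2)
        res = adjusted_effect(inp)
        R = np.array([[1.0, inp.r_gx], [inp.r_gx, 1.0]])
        b = np.linalg.solve(R, [inp.r_xy, inp.r_gy])
        assert res.b_adjusted == pytest.approx(b[0], abs=1e-10)
        assert res.b_genetic == pytest.approx(b[1], abs=1e-10)

    def test_near_singular_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            adjusted_effect(GsensInput(r_gx=0.9999999, r_gy=0.0, r_xy=0.0))

    def test_bootstrap_ci_brackets_delta_estimate(self):
        inp = GsensInput(r_gx=0.1, r_gy=0.2, r_xy=0.3, n=6000)
        res = adjusted_effect(inp, bootstrap=True, n_boot=300, seed=5)
        lo, hi = res.ci
        assert lo < res.b_adjusted < hi
        # delta SE and bootstrap spread should be the same order
        assert (hi - lo) / 2 == pytest.approx(1.96 * res.se, rel=0.3)

    def test_bootstrap_coverage_for_adjusted_effect(self):
        """Parametric-bootstrap-free check: delta CIs cover the population value."""
        truth = adjusted_effect(GsensInput(r_gx=0.1, r_gy=0.2, r_xy=0.3)).b_adjusted
        rng = np.random.default_rng(17)
        L = np.linalg.cholesky(GsensInput(0.1, 0.2, 0.3).matrix())
        cover = 0
        n_rep, n = 300, 6000
        for _ in range(n_rep):
            D = rng.standard_normal((n, 3)) @ L.T
            R = np.corrcoef(D, rowvar=False)
            res = adjusted_effect(GsensInput(R[0, 1], R[0, 2], R[1, 2], n=n))
            cover += abs(res.b_adjusted - truth) < 1.96 * res.se
        assert 0.93 <= cover / n_rep <= 0.97


class TestScenarioAnalysis:
    def test_pure_confounding_cohort(self):
        # the weak score (R^2 = 0.01) makes the scenario scaling factor noisy,
        # so the cohort is large enough for the +-5-point check to be meaningful
        df = simulate_gps_cohort(
            GpsSimConfig(n=2_000_000, h2_y=0.5, r2_gps=0.01, b_gx=0.3, b_xy=0.0, seed=8)
        )
        inp = _sample_input(df, h2_snp=0.25, h2_twin=0.5)
        obs, snp, twin = scenario_analysis(inp)
        assert abs(obs.attenuation_pct) < 10
        assert twin.attenuation_pct == pytest.approx(100.0, abs=5.0)
        assert obs.attenuation_pct < snp.attenuation_pct < twin.attenuation_pct

    def test_pure_causal_cohort(self):
        df = simulate_gps_cohort(
            GpsSimConfig(n=2_000_000, h2_y=0.5, r2_gps=0.01, b_gx=0.0, b_xy=0.3, seed=9)
        )
        inp = _sample_input(df, h2_snp=0.25, h2_twin=0.5)
        for res in scenario_analysis(inp):
            assert res.attenuation_pct == pytest.approx(0.0, abs=3.0)

    def test_equal_heritabilities_give_identical_scenarios(self):
        inp = GsensInput(r_gx=0.1, r_gy=0.2, r_xy=0.3, h2_snp=0.3, h2_twin=0.3)
        _, snp, twin = scenario_analysis(inp)
        assert snp.b_adjusted == twin.b_adjusted

    def test_snp_above_twin_warns_but_runs(self):
        inp = GsensInput(r_gx=0.1, r_gy=0.2, r_xy=0.3, h2_snp=0.5, h2_twin=0.3)
        with pytest.warns(UserWarning, match="lower bound"):
            results = scenario_analysis(inp)
        assert len(results) == 3

    def test_attenuation_monotone_in_h2(self):
        inp = GsensInput(r_gx=0.1, r_gy=0.2, r_xy=0.3)
        att = [
            adjusted_effect(scale_to_heritability(inp, h2)).attenuation_pct
            for h2 in np.arange(0.05, 1.0, 0.1)
        ]
        assert np.all(np.diff(att) > 0)

    def test_twin_scenario_recovers_causal_effect_under_mixed_truth(self):
        df = simulate_gps_cohort(
            GpsSimConfig(n=100000, h2_y=0.4, r2_gps=0.02, b_gx=0.15, b_xy=0.15, seed=10)
        )
        inp = _sample_input(df, h2_snp=0.2, h2_twin=0.4)
        twin = scenario_analysis(inp)[2]
        assert twin.b_adjusted == pytest.approx(0.15, abs=0.02)
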