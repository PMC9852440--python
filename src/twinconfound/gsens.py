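"""Genetic-confounding sensitivity analysis (Gsens).

Polygenic scores capture only a fraction of a trait's heritability, so
adjusting an exposure-outcome association for an observed score understates
genetic confounding.  This module estimates the exposure effect adjusted for
a genetic variable and then re-estimates it under scenarios in which the
score is inflated to explain the outcome's SNP-based or twin-based
heritability, bounding how much of the association genetic confounding could
account for.

For standardized variables the adjusted effect has the closed form of a
partial regression coefficient,

    b_adjusted = (r_xy - r_gx * r_gy) / (1 - r_gx^2),

computed from the 3x3 correlation matrix of (score, exposure, outcome).
Scenario scaling anchors on the outcome: r_gy is raised to sqrt(h2) and the
score-exposure correlation is scaled by the same factor, preserving the
score's exposure/outcome association ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GsensInput",
    "GsensResult",
    "scale_to_heritability",
    "adjusted_effect",
    "scenario_analysis",
]


class ScalingError(ValueError):
    """Scenario scaling produced an impossible correlation structure."""


@dataclass
class GsensInput:
    """Observed correlations among (polygenic score G, exposure X, outcome Y)."""

    r_gx: float
    r_gy: float
    r_xy: float
    n: int = 6000
    h2_snp: float | None = None
    h2_twin: float | None = None

    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.r_gx, self.r_gy],
                [self.r_gx, 1.0, self.r_xy],
                [self.r_gy, self.r_xy, 1.0],
            ]
        )

    def validate(self) -> None:
        for name in ("r_gx", "r_gy", "r_xy"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {v}")
        if np.linalg.eigvalsh(self.matrix()).min() <= 0:
            raise ScalingError(
                "correlation matrix of (score, exposure, outcome) is not "
                "positive definite"
            )


@dataclass
class GsensResult:
    scenario: str
    b_unadjusted: float
    b_adjusted: float
    confounding_prop: float
    attenuation_pct: float
    se: float = float("nan")
    ci: tuple[float, float] | None = None
    b_genetic: float = float("nan")
    input: GsensInput | None = field(default=None, repr=False)


def scale_to_heritability(inp: GsensInput, h2: float) -> GsensInput:
    """Rescale the score's correlations as if it explained heritability h2.

    Sets r_gy' = sign(r_gy) * sqrt(h2) and scales r_gx by the same factor
    sqrt(h2)/|r_gy|, so the ratio r_gx/r_gy — the score's relative pull on
    exposure versus outcome — is preserved.  The phenotypic correlation r_xy
    is left untouched.  Raises ``ScalingError`` when the scaled matrix stops
    being positive definite (the requested confounding exceeds what the
    observed association structure permits).
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"h2 must lie in (0, 1], got {h2}")
    if inp.r_gy == 0.0:
        raise ScalingError("r_gy = 0: scaling to a target heritability is undefined")
    if inp.r_gy**2 > h2 + 1e-12:
        raise ScalingError(
            f"observed r_gy^2 = {inp.r_gy**2:.4f} already exceeds target h2 = {h2}"
        )
    factor = np.sqrt(h2) / abs(inp.r_gy)
    scaled = replace(inp, r_gx=inp.r_gx * factor, r_gy=inp.r_gy * factor)
    lam = np.linalg.eigvalsh(scaled.matrix()).min()
    if lam <= 0:
        raise ScalingError(
            f"scaling to h2 = {h2} gives r_gx' = {scaled.r_gx:.4f}, "
            f"r_gy' = {scaled.r_gy:.4f}, which is incompatible with "
            f"r_xy = {inp.r_xy:.4f} (matrix not positive definite): genetic "
            "confounding alone cannot exceed the observed association structure"
        )
    return scaled


def _corr_cov(inp: GsensInput) -> np.ndarray:
    """Asymptotic covariance of (r_gx, r_gy, r_xy), Olkin-Siotani form."""
    rgx, rgy, rxy, n = inp.r_gx, inp.r_gy, inp.r_xy, inp.n

    def var(r):
        return (1 - r * r) ** 2

    def cov_shared(r_ij, r_ik, r_jk):
        return r_jk * (1 - r_ij**2 - r_ik**2) - 0.5 * r_ij * r_ik * (
            1 - r_ij**2 - r_ik**2 - r_jk**2
        )

    C = np.array(
        [
            [var(rgx), cov_shared(rgx, rgy, rxy), cov_shared(rgx, rxy, rgy)],
            [cov_shared(rgx, rgy, rxy), var(rgy), cov_shared(rgy, rxy, rgx)],
            [cov_shared(rgx, rxy, rgy), cov_shared(rgy, rxy, rgx), var(rxy)],
        ]
    )
    return C / n


def _b_adjusted(rgx: float, rgy: float, rxy: float) -> float:
    return (rxy - rgx * rgy) / (1.0 - rgx * rgx)


def adjusted_effect(
    inp: GsensInput,
    scenario: str = "observed",
    bootstrap: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> GsensResult:
    """Exposure effect on the outcome, adjusted for the genetic variable.

    ``b_unadjusted`` is the plain standardized association r_xy;
    ``b_adjusted`` partials the (possibly scenario-scaled) genetic variable
    out of it.  The confounding proportion 1 - b_adjusted/b_unadjusted and
    its percentage form are reported alongside a delta-method standard error;
    ``bootstrap=True`` adds a seeded parametric-bootstrap percentile CI from
    ``n_boot`` resampled correlation matrices at sample size n.
    """
    inp.validate()
    denom = 1.0 - inp.r_gx**2
    if denom < 1e-6:
        raise ValueError("1 - r_gx^2 < 1e-6: adjustment is numerically singular")
    b_unadj = inp.r_xy
    b_adj = _b_adjusted(inp.r_gx, inp.r_gy, inp.r_xy)
    b_gen = (inp.r_gy - inp.r_gx * inp.r_xy) / denom
    conf = 1.0 - b_adj / b_unadj if b_unadj != 0 else float("nan")

    # delta method on the closed-form partial coefficient
    g = np.array(
        [
            (-inp.r_gy * denom + 2 * inp.r_gx * (inp.r_xy - inp.r_gx * inp.r_gy))
            / denom**2,
            -inp.r_gx / denom,
            1.0 / denom,
        ]
    )
    se = float(np.sqrt(g @ _corr_cov(inp) @ g))

    ci = None
    if bootstrap:
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(inp.matrix())
        vals = []
        for _ in range(n_boot):
            Z = rng.standard_normal((inp.n, 3)) @ L.T
            R = np.corrcoef(Z, rowvar=False)
            vals.append(_b_adjusted(R[0, 1], R[0, 2], R[1, 2]))
        lo, hi = np.percentile(vals, [2.5, 97.5])
        ci = (float(lo), float(hi))

    return GsensResult(
        scenario=scenario,
        b_unadjusted=b_unadj,
        b_adjusted=b_adj,
        confounding_prop=conf,
        attenuation_pct=100.0 * conf,
        se=se,
        ci=ci,
        b_genetic=b_gen,
        input=inp,
    )


def scenario_analysis(
    inp: GsensInput,
    bootstrap: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[GsensResult]:
    """Run the observed, SNP-heritability and twin-heritability scenarios.

    Requires ``h2_snp`` and ``h2_twin`` on the input; warns (but proceeds)
    when h2_snp > h2_twin, since SNP heritability is normally the lower bound.
    """
    if inp.h2_snp is None or inp.h2_twin is None:
        raise ValueError("scenario_analysis requires h2_snp and h2_twin")
    if inp.h2_snp > inp.h2_twin:
        warnings.warn(
            f"h2_snp = {inp.h2_snp} exceeds h2_twin = {inp.h2_twin}; "
            "proceeding, but SNP heritability is usually the lower bound"
        )
    results = [adjusted_effect(inp, "observed", bootstrap, n_boot, seed)]
    for name, h2 in (("snp_h2", inp.h2_snp), ("twin_h2", inp.h2_twin)):
        scaled = scale_to_heritability(inp, h2)
        results.append(adjusted_effect(scaled, name, bootstrap, n_boot, seed + 1))
    return results


def scenario_table(results: list[GsensResult]):
    """Tidy comparison frame of the scenario results."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "scenario": r.scenario,
                "b_unadjusted": r.b_unadjusted,
                "b_adjusted": r.b_adjusted,
                "se": r.se,
                "confounding_prop": r.confounding_prop,
                "attenuation_pct": r.attenuation_pct,
                "ci_low": r.ci[0] if r.ci else np.nan,
                "ci_high": r.ci[1] if r.ci else np.nan,
            }
            for r in results
        ]
    ).set_index("scenario")
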