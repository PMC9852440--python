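"""Synthetic twin cohorts and polygenic-score cohorts with known ground truth.

The generators emulate the data model of a classical twin design: monozygotic
(MZ) co-twins share all additive genetic influences, dizygotic (DZ) co-twins
share half of them on average, the shared environment C is common to a pair
and the nonshared environment E is independent per twin.  Phenotypes are built
on a latent standard-normal scale as

    P = sqrt(a2) * A + sqrt(c2) * C + sqrt(e2) * E  (+ age/sex fixed effects),

so the ACE truth is exact on the latent scale and every downstream estimator
can be tested for parameter recovery without access-restricted cohort data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TwinSimConfig",
    "GpsSimConfig",
    "simulate_univariate_twins",
    "simulate_bivariate_twins",
    "simulate_gps_cohort",
    "skew_warp",
    "write_pairs_csv",
    "read_pairs_csv",
]

#: Mean and SD of age at assessment emulated by the generator (years).
AGE_MEAN = 22.14
AGE_SD = 0.85

_VAR_TOL = 1e-12


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class TwinSimConfig:
    """Ground-truth parameters for a simulated twin cohort.

    ``a2``/``c2``/``e2`` are per-trait variance proportions (sequences for
    bivariate mode, scalars for univariate); ``rA``/``rC``/``rE`` are the
    cross-trait correlations of the latent factors and are only used when two
    traits are configured.  ``beta_age``/``beta_sex`` add fixed effects on the
    raw scale before any standardisation downstream.
    """

    n_mz: int = 2890
    n_dz: int = 4879
    a2: float | tuple[float, ...] = 0.43
    c2: float | tuple[float, ...] = 0.0
    e2: float | tuple[float, ...] = 0.57
    rA: float = 0.0
    rC: float = 0.0
    rE: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    seed: int = 0
    trait_names: tuple[str, ...] = field(default=("trait",))

    def components(self) -> np.ndarray:
        """Per-trait (a2, c2, e2) as an array of shape (n_traits, 3)."""
        a2 = np.atleast_1d(np.asarray(self.a2, dtype=float))
        c2 = np.atleast_1d(np.asarray(self.c2, dtype=float))
        e2 = np.atleast_1d(np.asarray(self.e2, dtype=float))
        return np.stack([a2, c2, e2], axis=1)

    def validate(self, n_traits: int) -> None:
        comp = self.components()
        if comp.shape[0] != n_traits:
            raise ConfigurationError(
                f"expected {n_traits} trait(s), got components for {comp.shape[0]}"
            )
        if np.any(comp < 0) or np.any(comp > 1):
            raise ConfigurationError("variance components must lie in [0, 1]")
        if np.any(np.abs(comp.sum(axis=1) - 1.0) > _VAR_TOL):
            raise ConfigurationError("a2 + c2 + e2 must equal 1 for each trait")
        for name, r in (("rA", self.rA), ("rC", self.rC), ("rE", self.rE)):
            if abs(r) > 1:
                raise ConfigurationError(f"|{name}| must be <= 1, got {r}")
        if self.n_mz < 1 or self.n_dz < 1:
            raise ConfigurationError("n_mz and n_dz must be >= 1")


@dataclass
class GpsSimConfig:
    """Ground truth for an unrelated-individuals polygenic-score cohort.

    ``h2_y`` is the heritability of the outcome Y, ``r2_gps`` the variance in
    Y the *observed* score explains (so r2_gps <= h2_y), ``b_gx`` the latent
    genetic path into the exposure X and ``b_xy`` the causal exposure effect.
    """

    n: int = 6000
    h2_y: float = 0.4
    r2_gps: float = 0.01
    b_gx: float = 0.3
    b_xy: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.r2_gps <= self.h2_y <= 1.0):
            raise ConfigurationError(
                f"need 0 <= r2_gps <= h2_y <= 1, got r2_gps={self.r2_gps}, h2_y={self.h2_y}"
            )
        if abs(self.b_gx) > 1 or abs(self.b_xy) > 1:
            raise ConfigurationError("path coefficients must lie in [-1, 1]")
        if self.n < 2:
            raise ConfigurationError("n must be >= 2")


def _draw_ages_sexes(rng: np.random.Generator, n_mz: int, n_dz: int):
    age = rng.normal(AGE_MEAN, AGE_SD, size=n_mz + n_dz)
    # MZ co-twins share sex; DZ twin sexes are drawn independently, so about
    # half of DZ pairs come out opposite-sex (labelled DZos).
    sex_mz = rng.integers(0, 2, size=n_mz)
    sex1 = np.concatenate([sex_mz, rng.integers(0, 2, size=n_dz)])
    sex2 = np.concatenate([sex_mz, rng.integers(0, 2, size=n_dz)])
    return age, sex1, sex2


def _zygosity_labels(n_mz: int, sex1, sex2) -> np.ndarray:
    lab = np.where(sex1 == sex2, "DZss", "DZos")
    lab[:n_mz] = "MZ"
    return lab


def simulate_univariate_twins(config: TwinSimConfig) -> pd.DataFrame:
    """Generate one-trait twin pairs with the configured ACE structure.

    Returns a table with one row per pair: ``family_id, zygosity, sex1, sex2,
    age, <trait>_1, <trait>_2``; the true parameters are attached under
    ``df.attrs["truth"]``.
    """
    config.validate(n_traits=1)
    a2, c2, e2 = config.components()[0]
    rng = np.random.default_rng(config.seed)
    n_mz, n_dz = config.n_mz, config.n_dz
    n = n_mz + n_dz

    # Additive genetic factors: MZ co-twins share A entirely; each DZ twin is
    # sqrt(.5)*A_shared + sqrt(.5)*A_unique, giving the expected 0.5 cross-twin
    # genetic correlation.
    a_sh = rng.standard_normal(n)
    a_u1 = rng.standard_normal(n_dz)
    a_u2 = rng.standard_normal(n_dz)
    s = np.sqrt(0.5)
    A1 = np.concatenate([a_sh[:n_mz], s * a_sh[n_mz:] + s * a_u1])
    A2 = np.concatenate([a_sh[:n_mz], s * a_sh[n_mz:] + s * a_u2])

    C = rng.standard_normal(n)  # pair-shared
    E1 = rng.standard_normal(n)
    E2 = rng.standard_normal(n)

    age, sex1, sex2 = _draw_ages_sexes(rng, n_mz, n_dz)
    fixed1 = config.beta_age * age + config.beta_sex * sex1
    fixed2 = config.beta_age * age + config.beta_sex * sex2
    w = np.sqrt([a2, c2, e2])
    p1 = w[0] * A1 + w[1] * C + w[2] * E1 + fixed1
    p2 = w[0] * A2 + w[1] * C + w[2] * E2 + fixed2

    trait = config.trait_names[0]
    df = pd.DataFrame(
        {
            "family_id": np.arange(n),
            "zygosity": _zygosity_labels(n_mz, sex1, sex2),
            "sex1": sex1,
            "sex2": sex2,
            "age": age,
            f"{trait}_1": p1,
            f"{trait}_2": p2,
        }
    )
    df.attrs["truth"] = {"a2": a2, "c2": c2, "e2": e2, "seed": config.seed}
    return df


def _bivariate_factor(rng, n_mz, n_dz, r, cross_twin: str):
    """Draw a (F_x1, F_y1, F_x2, F_y2) factor block with cross-trait corr r.

    ``cross_twin`` sets how the factor is shared across co-twins: "mz_dz" for
    additive genetics (1.0 within MZ, 0.5 within DZ), "shared" for C,
    "independent" for E.
    """
    n = n_mz + n_dz
    within = np.array([[1.0, r], [r, 1.0]])
    if cross_twin == "shared":
        L = np.linalg.cholesky(within + 1e-12 * np.eye(2))
        f = rng.standard_normal((n, 2)) @ L.T
        return f[:, 0], f[:, 1], f[:, 0].copy(), f[:, 1].copy()
    if cross_twin == "independent":
        L = np.linalg.cholesky(within + 1e-12 * np.eye(2))
        f1 = rng.standard_normal((n, 2)) @ L.T
        f2 = rng.standard_normal((n, 2)) @ L.T
        return f1[:, 0], f1[:, 1], f2[:, 0], f2[:, 1]
    # additive genetic: build the full 4x4 covariance per zygosity
    out = np.empty((n, 4))
    for grp, k, sl in (("MZ", 1.0, slice(0, n_mz)), ("DZ", 0.5, slice(n_mz, n))):
        cov = np.block([[within, k * within], [k * within, within]])
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(4))
        m = sl.stop - sl.start
        out[sl] = rng.standard_normal((m, 4)) @ L.T
    return out[:, 0], out[:, 1], out[:, 2], out[:, 3]


def simulate_bivariate_twins(config: TwinSimConfig) -> pd.DataFrame:
    """Generate two-trait twin pairs with cross-trait factor correlations.

    The implied covariances follow the bivariate ACE algebra: within-twin
    cross-trait covariance sqrt(a2x*a2y)*rA + sqrt(c2x*c2y)*rC +
    sqrt(e2x*e2y)*rE; the MZ cross-twin cross-trait covariance drops the rE
    term and the DZ one additionally halves the rA term.
    """
    if len(config.trait_names) != 2:
        raise ConfigurationError("bivariate simulation needs two trait names")
    config.validate(n_traits=2)
    comp = config.components()
    rng = np.random.default_rng(config.seed)
    n_mz, n_dz = config.n_mz, config.n_dz
    n = n_mz + n_dz

    Ax1, Ay1, Ax2, Ay2 = _bivariate_factor(rng, n_mz, n_dz, config.rA, "mz_dz")
    Cx1, Cy1, Cx2, Cy2 = _bivariate_factor(rng, n_mz, n_dz, config.rC, "shared")
    Ex1, Ey1, Ex2, Ey2 = _bivariate_factor(rng, n_mz, n_dz, config.rE, "independent")

    age, sex1, sex2 = _draw_ages_sexes(rng, n_mz, n_dz)
    wx, wy = np.sqrt(comp[0]), np.sqrt(comp[1])
    tx, ty = config.trait_names
    df = pd.DataFrame(
        {
            "family_id": np.arange(n),
            "zygosity": _zygosity_labels(n_mz, sex1, sex2),
            "sex1": sex1,
            "sex2": sex2,
            "age": age,
            f"{tx}_1": wx[0] * Ax1 + wx[1] * Cx1 + wx[2] * Ex1
            + config.beta_age * age + config.beta_sex * sex1,
            f"{ty}_1": wy[0] * Ay1 + wy[1] * Cy1 + wy[2] * Ey1
            + config.beta_age * age + config.beta_sex * sex1,
            f"{tx}_2": wx[0] * Ax2 + wx[1] * Cx2 + wx[2] * Ex2
            + config.beta_age * age + config.beta_sex * sex2,
            f"{ty}_2": wy[0] * Ay2 + wy[1] * Cy2 + wy[2] * Ey2
            + config.beta_age * age + config.beta_sex * sex2,
        }
    )
    df.attrs["truth"] = {
        "a2": tuple(comp[:, 0]),
        "c2": tuple(comp[:, 1]),
        "e2": tuple(comp[:, 2]),
        "rA": config.rA,
        "rC": config.rC,
        "rE": config.rE,
        "seed": config.seed,
    }
    return df


def simulate_gps_cohort(config: GpsSimConfig) -> pd.DataFrame:
    """Generate (G_latent, GPS, X, Y) for unrelated individuals.

    G is standard normal; X = b_gx*G + noise to unit variance;
    Y = b_xy*X + b_gy*G + noise to unit variance, with b_gy chosen so that at
    b_xy = 0 the variance of Y explained by G equals h2_y; the observed score
    is GPS = lambda*G + noise with lambda = sqrt(r2_gps / h2_y), so that
    cor(GPS, Y)^2 ~= r2_gps at b_xy = 0.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    G = rng.standard_normal(n)
    ex = np.sqrt(max(0.0, 1.0 - config.b_gx**2))
    X = config.b_gx * G + ex * rng.standard_normal(n)

    b_gy = np.sqrt(config.h2_y)
    var_y = config.b_xy**2 + b_gy**2 + 2 * config.b_xy * b_gy * config.b_gx
    ey2 = 1.0 - var_y
    if ey2 < 0:
        raise ConfigurationError(
            "implied outcome variance exceeds 1; reduce b_xy or h2_y"
        )
    Y = config.b_xy * X + b_gy * G + np.sqrt(ey2) * rng.standard_normal(n)

    if config.h2_y > 0:
        lam = np.sqrt(config.r2_gps / config.h2_y)
    else:
        lam = 0.0
    GPS = lam * G + np.sqrt(max(0.0, 1.0 - lam**2)) * rng.standard_normal(n)
    df = pd.DataFrame({"G_latent": G, "GPS": GPS, "X": X, "Y": Y})
    df.attrs["truth"] = asdict(config)
    return df


def skew_warp(values: np.ndarray, strength: float = 1.0) -> np.ndarray:
    """Monotone exponential warp introducing positive skew.

    Applied after generation so that the ACE truth stays exact on the latent
    Gaussian scale; used to exercise the rank-based normalisation.
    """
    v = np.asarray(values, dtype=float)
    return np.expm1(strength * v) / strength


def write_pairs_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pair table as CSV with the ground truth in a sidecar JSON."""
    path = Path(path)
    df.to_csv(path, index=False)
    truth = df.attrs.get("truth")
    if truth is not None:
        path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=2))


def read_pairs_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".truth.json")
    if sidecar.exists():
        df.attrs["truth"] = json.loads(sidecar.read_text())
    return df
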