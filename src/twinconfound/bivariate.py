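"""Bivariate Cholesky decomposition of a cross-trait association.

The bivariate ACE (Cholesky) model decomposes the phenotypic correlation
between two standardized traits X and Y into the parts transmitted through
additive-genetic (A), shared-environmental (C) and nonshared-environmental
(E) factors, identified by the MZ/DZ contrast on cross-twin cross-trait
correlations:

    within-twin cross-trait cov  = a11*a21 + c11*c21 + e11*e21
    MZ cross-twin cross-trait    = a11*a21 + c11*c21
    DZ cross-twin cross-trait    = 0.5*a11*a21 + c11*c21

The primary outputs are the proportions prop_a/prop_c/prop_e of the
phenotypic correlation (the rphA/rphC/rphE decomposition) and the component
correlations rA/rC/rE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .univariate import FitError, fit_ace_ml_raw

__all__ = [
    "CholeskyPaths",
    "BivariateDecomposition",
    "cross_twin_cross_trait",
    "fit_bivariate_cholesky",
    "genetic_correlation",
]

#: below this |r_ph| the proportion split is numerically unstable
RPH_GUARD = 0.05


@dataclass
class CholeskyPaths:
    """Lower-triangular path coefficients, one triangle per A/C/E component."""

    a11: float
    a21: float
    a22: float
    c11: float
    c21: float
    c22: float
    e11: float
    e21: float
    e22: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a11, self.a21, self.a22, self.c11, self.c21, self.c22,
             self.e11, self.e21, self.e22]
        )

    def variance_components(self) -> dict[str, tuple[float, float]]:
        """Per-trait (trait X, trait Y) variance shares of A, C, E."""
        return {
            "a2": (self.a11**2, self.a21**2 + self.a22**2),
            "c2": (self.c11**2, self.c21**2 + self.c22**2),
            "e2": (self.e11**2, self.e21**2 + self.e22**2),
        }


@dataclass
class BivariateDecomposition:
    r_ph: float
    cov_a: float
    cov_c: float
    cov_e: float
    prop_a: float
    prop_c: float
    prop_e: float
    rA: float | None
    rC: float | None
    rE: float | None
    loglik: float = float("nan")
    low_precision: bool = False
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def _pair_matrix(pairs: pd.DataFrame, tx: str, ty: str, group: str) -> np.ndarray:
    if group == "DZ":
        sub = pairs[pairs["zygosity"].str.startswith("DZ")]
    else:
        sub = pairs[pairs["zygosity"] == group]
    cols = [f"{tx}_1", f"{ty}_1", f"{tx}_2", f"{ty}_2"]
    M = sub[cols].to_numpy(dtype=float)
    return M[~np.isnan(M).any(axis=1)]


_SWAP = np.array([2, 3, 0, 1])


def _symmetrized_cov(M: np.ndarray) -> np.ndarray:
    """Covariance of (X1, Y1, X2, Y2) averaged over both pair orderings."""
    D = np.vstack([M, M[:, _SWAP]])
    D = D - D.mean(axis=0)
    return D.T @ D / len(D)


def cross_twin_cross_trait(
    pairs: pd.DataFrame, trait_x: str, trait_y: str, min_pairs: int = 20
) -> dict[str, pd.DataFrame]:
    """Double-entered 4x4 correlation matrices for MZ and DZ groups.

    Rows/columns are ordered (X twin1, Y twin1, X twin2, Y twin2); the
    double entry makes the matrix symmetric under swapping twin 1 and 2.
    """
    labels = [f"{trait_x}_t1", f"{trait_y}_t1", f"{trait_x}_t2", f"{trait_y}_t2"]
    out = {}
    for grp in ("MZ", "DZ"):
        M = _pair_matrix(pairs, trait_x, trait_y, grp)
        if len(M) < min_pairs:
            raise FitError(f"need >= {min_pairs} complete {grp} pairs, got {len(M)}")
        S = _symmetrized_cov(M)
        d = np.sqrt(np.diag(S))
        out[grp] = pd.DataFrame(S / np.outer(d, d), index=labels, columns=labels)
    return out


def _implied_sigma(p: np.ndarray, k: float) -> np.ndarray:
    a11, a21, a22, c11, c21, c22, e11, e21, e22 = p
    vx = a11**2 + c11**2 + e11**2
    vy = a21**2 + a22**2 + c21**2 + c22**2 + e21**2 + e22**2
    cw = a11 * a21 + c11 * c21 + e11 * e21
    bxx = k * a11**2 + c11**2
    byy = k * (a21**2 + a22**2) + c21**2 + c22**2
    bxy = k * a11 * a21 + c11 * c21
    W = np.array([[vx, cw], [cw, vy]])
    B = np.array([[bxx, bxy], [bxy, byy]])
    return np.block([[W, B], [B, W]])


def _nll_paths(p: np.ndarray, stats_by_group) -> float:
    total = 0.0
    for k, (n, S) in stats_by_group.items():
        sigma = _implied_sigma(p, k)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e12
        total += 0.5 * n * (logdet + np.trace(np.linalg.solve(sigma, S)))
    return total


def _decompose(p: np.ndarray, loglik: float) -> tuple[CholeskyPaths, BivariateDecomposition]:
    paths = CholeskyPaths(*p)
    cov_a = paths.a11 * paths.a21
    cov_c = paths.c11 * paths.c21
    cov_e = paths.e11 * paths.e21
    r_ph = cov_a + cov_c + cov_e
    low = abs(r_ph) < RPH_GUARD
    if low:
        warnings.warn(
            f"|r_ph| = {abs(r_ph):.3f} < {RPH_GUARD}; proportion estimates are "
            "low-precision (near-zero denominator)"
        )
    denom = r_ph if r_ph != 0 else np.nan
    decomp = BivariateDecomposition(
        r_ph=r_ph,
        cov_a=cov_a,
        cov_c=cov_c,
        cov_e=cov_e,
        prop_a=cov_a / denom,
        prop_c=cov_c / denom,
        prop_e=cov_e / denom,
        rA=genetic_correlation(paths, "a"),
        rC=genetic_correlation(paths, "c"),
        rE=genetic_correlation(paths, "e"),
        loglik=loglik,
        low_precision=low,
    )
    return paths, decomp


def _fit_paths(stats_by_group, seed: int, n_restarts: int = 5) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(seed)

    def unit_var_x(p):
        return p[0] ** 2 + p[3] ** 2 + p[6] ** 2 - 1.0

    def unit_var_y(p):
        return p[1] ** 2 + p[2] ** 2 + p[4] ** 2 + p[5] ** 2 + p[7] ** 2 + p[8] ** 2 - 1.0

    cons = [
        {"type": "eq", "fun": unit_var_x},
        {"type": "eq", "fun": unit_var_y},
    ]
    # a11, a22, c11, c22, e11, e22 >= 0 fixes the reflection indeterminacy
    bounds = [(0, 1), (-1, 1), (0, 1), (0, 1), (-1, 1), (0, 1), (1e-4, 1), (-1, 1), (1e-4, 1)]

    def random_start():
        vx = rng.dirichlet([2.0, 1.0, 2.0])
        vy = rng.dirichlet([2.0, 1.0, 2.0])
        return np.array(
            [np.sqrt(vx[0]), 0.1, np.sqrt(max(vy[0] - 0.01, 1e-4)),
             np.sqrt(vx[1]), 0.0, np.sqrt(vy[1]),
             np.sqrt(vx[2]), 0.1, np.sqrt(max(vy[2] - 0.01, 1e-4))]
        )

    starts = [
        np.array([0.6, 0.2, 0.55, 0.1, 0.0, 0.1, 0.75, 0.1, 0.75]),
        np.array([0.3, 0.0, 0.3, 0.3, 0.0, 0.3, 0.85, 0.0, 0.85]),
    ]
    starts += [random_start() for _ in range(n_restarts)]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            _nll_paths,
            x0,
            args=(stats_by_group,),
            method="SLSQP",
            bounds=bounds,
            constraints=cons,
            options={"ftol": 1e-12, "maxiter": 1000},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("bivariate Cholesky optimizer failed to converge")
    return best.x, float(best.fun)


def fit_bivariate_cholesky(
    pairs: pd.DataFrame,
    trait_x: str,
    trait_y: str,
    seed: int = 0,
    ci: bool = False,
    n_boot: int = 200,
    min_pairs: int = 20,
    n_restarts: int = 5,
) -> tuple[CholeskyPaths, BivariateDecomposition]:
    """ML fit of the bivariate Cholesky ACE model to a two-trait pair table.

    Maximizes the 4-variate normal likelihood per zygosity group with both
    trait variances constrained to 1.  With ``ci=True``, confidence intervals
    on the proportions are obtained by a seeded nonparametric pair-resampling
    bootstrap (percentile method, ``n_boot`` replicates).
    """
    data = {
        1.0: _pair_matrix(pairs, trait_x, trait_y, "MZ"),
        0.5: _pair_matrix(pairs, trait_x, trait_y, "DZ"),
    }
    for k, M in data.items():
        if len(M) < min_pairs:
            grp = "MZ" if k == 1.0 else "DZ"
            raise FitError(f"need >= {min_pairs} complete {grp} pairs, got {len(M)}")
    stats_by_group = {k: (len(M), _symmetrized_cov(M)) for k, M in data.items()}

    # A (near-)duplicate trait makes the 4-variate likelihood singular; the
    # model then degenerates to the univariate ACE split of the shared trait.
    pooled = sum(n * S for n, S in stats_by_group.values())
    r_wt = pooled[0, 1] / np.sqrt(pooled[0, 0] * pooled[1, 1])
    if abs(r_wt) > 0.999:
        warnings.warn(
            "traits are (near-)duplicates; returning the univariate ACE split"
        )
        u = fit_ace_ml_raw(pairs.rename(
            columns={f"{trait_x}_1": "shared_1", f"{trait_x}_2": "shared_2"}
        ), "shared", seed=seed)
        sgn = np.sign(r_wt)
        p = np.array(
            [np.sqrt(u.a2), sgn * np.sqrt(u.a2), 0.0,
             np.sqrt(u.c2), sgn * np.sqrt(u.c2), 0.0,
             np.sqrt(u.e2), sgn * np.sqrt(u.e2), 0.0]
        )
        return _decompose(p, loglik=float("nan"))
    p, fmin = _fit_paths(stats_by_group, seed, n_restarts=n_restarts)
    paths, decomp = _decompose(p, loglik=-fmin)

    if ci:
        rng = np.random.default_rng(seed + 1)
        props = []
        for _ in range(n_boot):
            boot_stats = {}
            for k, M in data.items():
                idx = rng.integers(0, len(M), size=len(M))
                boot_stats[k] = (len(M), _symmetrized_cov(M[idx]))
            try:
                pb, fb = _fit_paths(boot_stats, seed=int(rng.integers(2**31)), n_restarts=1)
            except FitError:
                continue
            _, db = _decompose(pb, -fb)
            props.append((db.prop_a, db.prop_c, db.prop_e))
        if props:
            arr = np.asarray(props)
            for i, name in enumerate(("prop_a", "prop_c", "prop_e")):
                lo, hi = np.percentile(arr[:, i], [2.5, 97.5])
                decomp.ci[name] = (float(lo), float(hi))
    return paths, decomp


def genetic_correlation(paths: CholeskyPaths, component: str = "a") -> float | None:
    """Component correlation rA (or rC/rE) implied by the Cholesky paths.

    rA = a11*a21 / (|a11| * sqrt(a21^2 + a22^2)); returns None with a warning
    when either trait carries no variance of that component.
    """
    p11, p21, p22 = {
        "a": (paths.a11, paths.a21, paths.a22),
        "c": (paths.c11, paths.c21, paths.c22),
        "e": (paths.e11, paths.e21, paths.e22),
    }[component]
    sd_x = abs(p11)
    sd_y = np.hypot(p21, p22)
    if sd_x < 1e-6 or sd_y < 1e-6:
        warnings.warn(
            f"component {component!r} has (near-)zero variance in one trait; "
            "its correlation is undefined"
        )
        return None
    return float(p11 * p21 / (sd_x * sd_y))
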