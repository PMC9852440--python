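"""Univariate ACE variance decomposition from twin data.

Estimates the additive-genetic (A), shared-environmental (C) and nonshared-
environmental (E) variance proportions of a standardized trait from the MZ/DZ
twin contrast, three ways:

* ``falconer_estimates`` — the rough arithmetic: A = 2(rMZ - rDZ),
  C = rMZ - A, E = 1 - A - C, with no constraints;
* ``fit_ace_ml_summary`` — maximum likelihood on the two intraclass
  correlations via the Fisher-z approximation, with a2, c2 >= 0 and
  a2 + c2 <= 1 enforced (the summary-level analogue of an SEM fit);
* ``fit_ace_ml_raw`` — full bivariate-normal maximum likelihood on the pair
  table, with the same constraints.

Both ML fits report boundary flags and support likelihood-profile confidence
intervals (``profile_ci``) and nested-submodel comparison
(``compare_submodels``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CorrelationSummary",
    "ACEEstimate",
    "falconer_estimates",
    "fit_ace_ml_summary",
    "fit_ace_ml_raw",
    "profile_ci",
    "compare_submodels",
]

_RHO_CAP = 1.0 - 1e-10


class FitError(RuntimeError):
    """Optimizer failed to converge or the data do not identify the model."""


@dataclass
class CorrelationSummary:
    """MZ/DZ intraclass correlations with group sizes (in pairs)."""

    r_mz: float
    r_dz: float
    n_mz: int
    n_dz: int

    def validate(self) -> None:
        if not (np.isfinite(self.r_mz) and np.isfinite(self.r_dz)):
            raise ValueError("correlations must be finite")
        if self.n_mz < 4 or self.n_dz < 4:
            raise ValueError("need at least 4 pairs per zygosity group")


@dataclass
class ACEEstimate:
    """Standardized variance components with flags, loglik and optional CIs."""

    a2: float
    c2: float
    e2: float
    method: str
    loglik: float = float("nan")
    boundary: dict[str, bool] = field(default_factory=dict)
    out_of_range: dict[str, bool] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    # negative log-likelihood as a function of (a2, c2); used for profiling
    nll: Callable[[float, float], float] | None = field(
        default=None, repr=False, compare=False
    )

    def as_dict(self) -> dict:
        d = {
            "a2": self.a2,
            "c2": self.c2,
            "e2": self.e2,
            "method": self.method,
            "loglik": self.loglik,
            "boundary": self.boundary,
            "out_of_range": self.out_of_range,
        }
        if self.ci:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def falconer_estimates(r_mz: float, r_dz: float) -> ACEEstimate:
    """Rough ACE estimates from doubling the MZ-DZ correlation difference.

    No constraints are applied; components falling outside [0, 1] are flagged
    in ``out_of_range`` rather than clipped.
    """
    if not (-1 <= r_mz <= 1 and -1 <= r_dz <= 1):
        raise ValueError("correlations must lie in [-1, 1]")
    a2 = 2.0 * (r_mz - r_dz)
    c2 = r_mz - a2
    e2 = 1.0 - a2 - c2
    flags = {k: not (0.0 <= v <= 1.0) for k, v in {"a2": a2, "c2": c2, "e2": e2}.items()}
    return ACEEstimate(a2=a2, c2=c2, e2=e2, method="falconer", out_of_range=flags)


def _expected_rho(a2: float, c2: float) -> tuple[float, float]:
    return a2 + c2, 0.5 * a2 + c2


def _maximize(nll, seed: int = 0, n_restarts: int = 5) -> tuple[float, float, float]:
    """Minimize nll(a2, c2) over the constrained simplex with restarts."""
    rng = np.random.default_rng(seed)
    cons = [{"type": "ineq", "fun": lambda p: 1.0 - p[0] - p[1]}]
    bounds = [(0.0, 1.0), (0.0, 1.0)]
    starts = [(0.3, 0.1), (0.5, 0.0), (0.05, 0.3)]
    while len(starts) < 3 + n_restarts:
        p = rng.dirichlet([1.0, 1.0, 1.0])
        starts.append((p[0], p[1]))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            lambda p: nll(p[0], p[1]),
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=cons,
            options={"ftol": 1e-12, "maxiter": 500},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("ACE optimizer failed to converge from all starts")
    return float(best.x[0]), float(best.x[1]), float(best.fun)


def _boundary_flags(a2: float, c2: float, tol: float = 1e-6) -> dict[str, bool]:
    return {
        "a2": a2 < tol,
        "c2": c2 < tol,
        "e2": (1.0 - a2 - c2) < tol,
    }


def fit_ace_ml_summary(summary: CorrelationSummary, seed: int = 0) -> ACEEstimate:
    """Constrained ML fit of the ACE model to MZ/DZ intraclass correlations.

    The likelihood treats each Fisher-z transformed group correlation as
    Normal(z(rho_g), 1/(n_g - 3)) with rho_MZ = a2 + c2 and
    rho_DZ = a2/2 + c2.  This reproduces a raw-data SEM fit asymptotically
    while needing only the printed summary statistics.
    """
    summary.validate()
    z_mz, z_dz = np.arctanh(summary.r_mz), np.arctanh(summary.r_dz)
    w_mz, w_dz = summary.n_mz - 3, summary.n_dz - 3

    def nll(a2: float, c2: float) -> float:
        rho_mz, rho_dz = _expected_rho(a2, c2)
        rho_mz = min(max(rho_mz, -_RHO_CAP), _RHO_CAP)
        rho_dz = min(max(rho_dz, -_RHO_CAP), _RHO_CAP)
        return 0.5 * (
            w_mz * (z_mz - np.arctanh(rho_mz)) ** 2
            + w_dz * (z_dz - np.arctanh(rho_dz)) ** 2
        )

    a2, c2, fmin = _maximize(nll, seed=seed)
    return ACEEstimate(
        a2=a2,
        c2=c2,
        e2=1.0 - a2 - c2,
        method="ml_summary",
        loglik=-fmin,
        boundary=_boundary_flags(a2, c2),
        nll=nll,
    )


def _group_stats(pairs: pd.DataFrame, trait: str):
    """Complete-pair sufficient statistics (n, sum sq, sum cross) per group."""
    out = {}
    for grp in ("MZ", "DZ"):
        if grp == "DZ":
            sub = pairs[pairs["zygosity"].str.startswith("DZ")]
        else:
            sub = pairs[pairs["zygosity"] == "MZ"]
        x1 = sub[f"{trait}_1"].to_numpy(dtype=float)
        x2 = sub[f"{trait}_2"].to_numpy(dtype=float)
        ok = ~(np.isnan(x1) | np.isnan(x2))
        x1, x2 = x1[ok], x2[ok]
        out[grp] = (len(x1), float(np.sum(x1**2 + x2**2)), float(np.sum(x1 * x2)))
    return out


def fit_ace_ml_raw(
    pairs: pd.DataFrame, trait: str, seed: int = 0, min_pairs: int = 20
) -> ACEEstimate:
    """Full-information ML fit of the ACE model to a standardized pair table.

    Each complete pair contributes a bivariate-normal likelihood term with
    unit variances and co-twin correlation rho_MZ = a2 + c2 or
    rho_DZ = a2/2 + c2.  The likelihood is symmetric in the within-pair
    ordering, so estimates are invariant to swapping twin 1 and twin 2.
    """
    gs = _group_stats(pairs, trait)
    for grp, (n, *_rest) in gs.items():
        if n < min_pairs:
            raise FitError(
                f"need >= {min_pairs} complete {grp} pairs for identification, got {n}"
            )

    def nll(a2: float, c2: float) -> float:
        rho_mz, rho_dz = _expected_rho(a2, c2)
        total = 0.0
        for grp, rho in (("MZ", rho_mz), ("DZ", rho_dz)):
            rho = min(max(rho, -_RHO_CAP), _RHO_CAP)
            n, ssq, sp = gs[grp]
            one_m = 1.0 - rho * rho
            total += (
                n * np.log(2 * np.pi)
                + 0.5 * n * np.log(one_m)
                + 0.5 * (ssq - 2.0 * rho * sp) / one_m
            )
        return total

    a2, c2, fmin = _maximize(nll, seed=seed)
    return ACEEstimate(
        a2=a2,
        c2=c2,
        e2=1.0 - a2 - c2,
        method="ml_raw",
        loglik=-fmin,
        boundary=_boundary_flags(a2, c2),
        nll=nll,
    )


def _profile_component(fit: ACEEstimate, comp: str, crit: float):
    """One-component likelihood profile; returns the (lo, hi) interval."""
    nll = fit.nll
    nll_min = -fit.loglik
    est = getattr(fit, comp)

    def prof(v: float) -> float:
        # minimize over the remaining free direction at fixed component value
        if comp == "a2":
            lo, hi = 0.0, 1.0 - v
            f = lambda c2: nll(v, c2)
        elif comp == "c2":
            lo, hi = 0.0, 1.0 - v
            f = lambda a2: nll(a2, v)
        else:  # e2 fixed -> a2 + c2 = 1 - v, slide along the line
            lo, hi = 0.0, 1.0 - v
            f = lambda a2: nll(a2, (1.0 - v) - a2)
        if hi <= lo:
            return f(lo)
        res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        return float(res.fun)

    def g(v: float) -> float:
        return 2.0 * (prof(v) - nll_min) - crit

    def bound(side: str) -> float:
        if side == "lower":
            a, b = 0.0, est
        else:
            a, b = est, 1.0
        if b - a < 1e-9:
            return est
        edge = a if side == "lower" else b
        if g(edge) <= 0:  # profile never crosses the cutoff before the box edge
            return edge
        return float(optimize.brentq(lambda v: g(v), a, b, xtol=1e-6))

    return (bound("lower"), bound("upper"))


def profile_ci(fit: ACEEstimate, level: float = 0.95) -> ACEEstimate:
    """Likelihood-ratio profile intervals for a2, c2, e2, truncated to [0,1].

    The bound solves 2*(loglik_max - loglik_profile) = chi2_1 quantile
    (3.84 at the 95% level); components estimated on a boundary get the
    boundary as the corresponding limit.
    """
    if fit.nll is None or not np.isfinite(fit.loglik):
        raise ValueError("profile_ci requires a converged ML fit")
    crit = stats.chi2.ppf(level, df=1)
    for comp in ("a2", "c2", "e2"):
        fit.ci[comp] = _profile_component(fit, comp, crit)
    return fit


_SUBMODELS = {
    "ACE": (None, None, 2),
    "AE": (None, 0.0, 1),
    "CE": (0.0, None, 1),
    "E": (0.0, 0.0, 0),
}


def compare_submodels(pairs: pd.DataFrame, trait: str, seed: int = 0) -> pd.DataFrame:
    """Fit ACE, AE, CE and E to the same pairs; report -2lnL, AIC and LRT p.

    The likelihood-ratio p compares each submodel against the full ACE model
    with degrees of freedom equal to the number of dropped parameters (the
    naive chi-square reference, ignoring the boundary mixture).
    """
    full = fit_ace_ml_raw(pairs, trait, seed=seed)
    nll = full.nll
    rows = []
    for name, (a2_fix, c2_fix, k) in _SUBMODELS.items():
        if name == "ACE":
            a2, c2, fmin = full.a2, full.c2, -full.loglik
        elif a2_fix is None:  # AE: optimize a2 with c2 pinned
            res = optimize.minimize_scalar(
                lambda a2: nll(a2, c2_fix), bounds=(0.0, 1.0), method="bounded"
            )
            a2, c2, fmin = float(res.x), c2_fix, float(res.fun)
        elif c2_fix is None:  # CE
            res = optimize.minimize_scalar(
                lambda c2: nll(a2_fix, c2), bounds=(0.0, 1.0), method="bounded"
            )
            a2, c2, fmin = a2_fix, float(res.x), float(res.fun)
        else:  # E
            a2, c2, fmin = 0.0, 0.0, float(nll(0.0, 0.0))
        loglik = -fmin
        lrt = 2.0 * (full.loglik - loglik)
        df = 2 - k
        p = float(stats.chi2.sf(max(lrt, 0.0), df)) if df > 0 else float("nan")
        rows.append(
            {
                "model": name,
                "a2": a2,
                "c2": c2,
                "e2": 1.0 - a2 - c2,
                "loglik": loglik,
                "minus2ll": -2.0 * loglik,
                "aic": -2.0 * loglik + 2.0 * k,
                "lrt_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("model")
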