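"""Phenotype preparation and descriptive statistics for twin cohorts.

Covers the standard preparation steps of a twin/polygenic analysis: age and
sex residualisation, the rank-based van der Waerden normalisation, double
entry, intraclass and cross-trait correlations with Benjamini-Hochberg FDR
control, ANOVA variance shares for sex/zygosity, and Cronbach's alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationReport",
    "residualize",
    "vdw_transform",
    "double_enter",
    "intraclass_correlation",
    "correlation_matrix_fdr",
    "variance_by_sex_zygosity",
    "cronbach_alpha",
]


class DegenerateDataError(ValueError):
    """Raised when an operation is undefined on the supplied data."""


@dataclass
class CorrelationReport:
    """A correlation with its sample size, raw/FDR p-values and Fisher CI."""

    r: float
    n: int
    p_raw: float
    p_fdr: float | None = None
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def residualize(
    values: np.ndarray | pd.Series,
    age: np.ndarray | pd.Series,
    sex: np.ndarray | pd.Series,
) -> np.ndarray:
    """Residualise a phenotype on intercept + age + sex and re-standardise.

    Returns least-squares residuals scaled to mean 0, variance 1.  Missing
    values in any input propagate as NaN in the output.  A constant predictor
    is dropped with a warning; an all-missing phenotype is an error.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(age, dtype=float)
    s = np.asarray(sex, dtype=float)
    ok = ~(np.isnan(v) | np.isnan(a) | np.isnan(s))
    if not ok.any():
        raise DegenerateDataError("all phenotype values are missing")

    cols = [np.ones(ok.sum())]
    for name, pred in (("age", a[ok]), ("sex", s[ok])):
        if np.ptp(pred) == 0:
            warnings.warn(f"constant predictor {name!r} skipped in residualisation")
        else:
            cols.append(pred)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, v[ok], rcond=None)
    resid = v[ok] - X @ beta

    out = np.full_like(v, np.nan)
    sd = resid.std(ddof=0)
    if sd < 1e-12:
        warnings.warn("phenotype fully explained by age/sex; residuals degenerate")
        out[ok] = 0.0
    else:
        out[ok] = (resid - resid.mean()) / sd
    return out


def vdw_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Van der Waerden rank-based inverse-normal transform.

    Each value maps to Phi^{-1}(rank / (n + 1)) with average ranks for ties;
    missing values are preserved.  Undefined when all values are identical.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    n = int(ok.sum())
    if n < 3:
        raise DegenerateDataError("need at least 3 non-missing values")
    if np.ptp(v[ok]) == 0:
        raise DegenerateDataError("all values identical; rank transform undefined")
    ranks = stats.rankdata(v[ok], method="average")
    out = np.full_like(v, np.nan)
    out[ok] = stats.norm.ppf(ranks / (n + 1))
    return out


def double_enter(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stack both within-pair orderings: (x1,x2) followed by (x2,x1)."""
    return np.concatenate([x1, x2]), np.concatenate([x2, x1])


def intraclass_correlation(
    pairs: pd.DataFrame, trait: str, zygosity: str = "MZ"
) -> CorrelationReport:
    """Double-entry Pearson intraclass correlation for one zygosity group.

    ``zygosity="DZ"`` pools DZss and DZos pairs.  n is the number of complete
    pairs; the confidence interval uses the Fisher z approximation with the
    pair count as effective sample size.
    """
    if zygosity == "DZ":
        grp = pairs[pairs["zygosity"].str.startswith("DZ")]
    else:
        grp = pairs[pairs["zygosity"] == zygosity]
    x1 = grp[f"{trait}_1"].to_numpy(dtype=float)
    x2 = grp[f"{trait}_2"].to_numpy(dtype=float)
    ok = ~(np.isnan(x1) | np.isnan(x2))
    n_pairs = int(ok.sum())
    if n_pairs < 3:
        raise DegenerateDataError(
            f"need >= 3 complete pairs in group {zygosity!r}, got {n_pairs}"
        )
    d1, d2 = double_enter(x1[ok], x2[ok])
    r = float(np.corrcoef(d1, d2)[0, 1])
    # p from the t approximation at the pair count (double entry duplicates rows)
    p = _pearson_p(r, n_pairs)
    lo, hi = _fisher_ci(r, n_pairs)
    return CorrelationReport(r=r, n=n_pairs, p_raw=p, ci_low=lo, ci_high=hi)


def _pearson_p(r: float, n: int) -> float:
    if n <= 2 or abs(r) >= 1:
        return 0.0 if abs(r) >= 1 else float("nan")
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def correlation_matrix_fdr(
    left: pd.DataFrame, right: pd.DataFrame, min_n: int = 10
) -> pd.DataFrame:
    """All left x right Pearson correlations with BH-FDR adjusted p-values.

    Uses pairwise-complete observations.  The FDR family is the full set of
    left x right cells with a defined correlation.  Returns a tidy frame with
    columns (left, right, r, n, p_raw, p_fdr, ci_low, ci_high); cells with a
    zero-variance variable or too few observations carry NaN.
    """
    rows = []
    for lname in left.columns:
        for rname in right.columns:
            x = left[lname].to_numpy(dtype=float)
            y = right[rname].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            n = int(ok.sum())
            if n < min_n or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rows.append((lname, rname, np.nan, n, np.nan))
                continue
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            rows.append((lname, rname, r, n, _pearson_p(r, n)))
    out = pd.DataFrame(rows, columns=["left", "right", "r", "n", "p_raw"])
    out["p_fdr"] = np.nan
    defined = out["p_raw"].notna()
    if defined.any():
        out.loc[defined, "p_fdr"] = multipletests(
            out.loc[defined, "p_raw"], method="fdr_bh"
        )[1]
    cis = [
        _fisher_ci(r, n) if np.isfinite(r) else (np.nan, np.nan)
        for r, n in zip(out["r"], out["n"])
    ]
    out[["ci_low", "ci_high"]] = np.asarray(cis)
    return out


def variance_by_sex_zygosity(
    pairs: pd.DataFrame, trait: str, seed: int = 0
) -> dict[str, float]:
    """Eta-squared shares of sex, zygosity and the joint model.

    One twin per pair is selected at random (seeded) to keep observations
    independent, then a two-way ANOVA decomposes the phenotype's sum of
    squares.  The interaction is dropped (with a warning) when a sex x
    zygosity cell is empty.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rng = np.random.default_rng(seed)
    pick = rng.integers(1, 3, size=len(pairs))
    df = pd.DataFrame(
        {
            "y": np.where(pick == 1, pairs[f"{trait}_1"], pairs[f"{trait}_2"]),
            "sex": np.where(pick == 1, pairs["sex1"], pairs["sex2"]),
            "zygosity": pairs["zygosity"].to_numpy(),
        }
    ).dropna()

    cells = df.groupby(["sex", "zygosity"]).size()
    formula = "y ~ C(sex) * C(zygosity)"
    n_sex = df["sex"].nunique()
    n_zyg = df["zygosity"].nunique()
    if len(cells) < n_sex * n_zyg:
        warnings.warn("empty sex x zygosity cell; interaction term dropped")
        formula = "y ~ C(sex) + C(zygosity)"
    fit = smf.ols(formula, data=df).fit()
    tab = anova_lm(fit, typ=2)
    ss_total = tab["sum_sq"].sum()
    eta = {
        "sex": float(tab.loc["C(sex)", "sum_sq"] / ss_total),
        "zygosity": float(tab.loc["C(zygosity)", "sum_sq"] / ss_total),
    }
    eta["joint"] = float(1.0 - tab.loc["Residual", "sum_sq"] / ss_total)
    return eta


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item var) / var(total))."""
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise DegenerateDataError("need >= 3 individuals and >= 2 items")
    X = X[~np.isnan(X).any(axis=1)]
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var < 1e-12:
        raise DegenerateDataError("total score has zero variance")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))
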