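"""Polygenic-score prediction of phenotypes in unrelated individuals.

Per-score Pearson correlations with FDR control across the score x phenotype
family, and a joint multiple regression giving the multiple correlation R —
the standard quantification of how much phenotypic variance a battery of
genome-wide polygenic scores accounts for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ScoreMatrix", "GpsAssociation", "gps_correlations", "multiple_gps_regression"]


@dataclass
class ScoreMatrix:
    """Individuals x scores matrix, standardized column-wise on construction."""

    scores: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        std = self.scores.std(ddof=0)
        if (std < 1e-12).any():
            bad = list(std.index[std < 1e-12])
            raise ValueError(f"zero-variance score column(s): {bad}")
        self.scores = (self.scores - self.scores.mean()) / std

    @property
    def score_names(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class GpsAssociation:
    per_score: pd.DataFrame  # columns: r, p_raw, p_fdr, beta
    multiple_R: float
    R2: float
    adj_R2: float
    f_pvalue: float
    n: int
    dropped: list[str] = field(default_factory=list)


def _aligned(scores: ScoreMatrix, phenotype: np.ndarray | pd.Series):
    y = np.asarray(phenotype, dtype=float)
    if len(y) != len(scores.scores):
        raise ValueError(
            f"phenotype length {len(y)} does not match score rows {len(scores.scores)}"
        )
    X = scores.scores.to_numpy(dtype=float)
    ok = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    return X[ok], y[ok]


def gps_correlations(
    scores: ScoreMatrix, phenotype: np.ndarray | pd.Series, min_n: int = 50
) -> pd.DataFrame:
    """Per-score Pearson r against the phenotype, with BH-FDR p-values."""
    X, y = _aligned(scores, phenotype)
    if len(y) < min_n:
        raise ValueError(f"need n >= {min_n}, got {len(y)}")
    rows = []
    for j, name in enumerate(scores.score_names):
        r, p = stats.pearsonr(X[:, j], y)
        rows.append({"score": name, "r": float(r), "p_raw": float(p)})
    out = pd.DataFrame(rows).set_index("score")
    out["p_fdr"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


def multiple_gps_regression(
    scores: ScoreMatrix, phenotype: np.ndarray | pd.Series, min_n: int = 50
) -> GpsAssociation:
    """Joint least-squares regression of the phenotype on all scores.

    Reports per-score correlations (with FDR), joint betas with their signs,
    the multiple correlation R = sqrt(R2), adjusted R2 and the overall F-test
    p-value.  Rank-deficient score sets have offending columns dropped with a
    warning.
    """
    import statsmodels.api as sm

    per_score = gps_correlations(scores, phenotype, min_n=min_n)
    X, y = _aligned(scores, phenotype)
    names = list(scores.score_names)

    dropped: list[str] = []
    # drop trailing collinear columns until full rank
    while len(names) > 1 and np.linalg.matrix_rank(X) < X.shape[1]:
        dropped.append(names.pop())
        X = X[:, : len(names)]
    if dropped:
        warnings.warn(f"dropped collinear score column(s): {dropped}")
    if X.shape[1] >= len(y) / 10:
        warnings.warn("fewer than 10 observations per score; estimates unstable")

    fit = sm.OLS(y, sm.add_constant(X)).fit()
    per_score["beta"] = np.nan
    per_score.loc[names, "beta"] = fit.params[1:]
    R2 = float(fit.rsquared)
    return GpsAssociation(
        per_score=per_score,
        multiple_R=float(np.sqrt(max(R2, 0.0))),
        R2=R2,
        adj_R2=float(fit.rsquared_adj),
        f_pvalue=float(fit.f_pvalue),
        n=len(y),
        dropped=dropped,
    )
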