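"""Figure-style summaries: correlation heatmap, decomposition bars, Gsens scenarios."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["correlation_heatmap", "decomposition_bars", "gsens_scenario_plot"]


def correlation_heatmap(corr: pd.DataFrame, path: str, title: str = "") -> None:
    """Heatmap of a tidy (left, right, r) correlation frame."""
    mat = corr.pivot(index="left", columns="right", values="r")
    fig, ax = plt.subplots(figsize=(1.2 * mat.shape[1] + 2, 0.8 * mat.shape[0] + 2))
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(mat.shape[0]), mat.index)
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            ax.text(j, i, f"{mat.iat[i, j]:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="r")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def decomposition_bars(decomps: dict[str, object], path: str) -> None:
    """Stacked rphA/rphC/rphE proportion bars, one per trait pair."""
    names = list(decomps)
    props = np.array(
        [[d.prop_a, d.prop_c, d.prop_e] for d in decomps.values()]
    )
    fig, ax = plt.subplots(figsize=(1.5 * len(names) + 2, 4))
    bottom = np.zeros(len(names))
    for i, (lab, col) in enumerate(
        [("A (genetic)", "#2b6cb0"), ("C (shared env)", "#b76e22"), ("E (nonshared env)", "#4a9a4a")]
    ):
        ax.bar(names, props[:, i], bottom=bottom, label=lab, color=col)
        bottom += props[:, i]
    ax.set_ylabel("proportion of phenotypic correlation")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def gsens_scenario_plot(results: list, path: str) -> None:
    """Adjusted-effect point estimates per scenario (observed/SNP/twin)."""
    colors = {"observed": "#c23b3b", "snp_h2": "#2b6cb0", "twin_h2": "#3a8f3a"}
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for i, r in enumerate(results):
        lo, hi = r.ci if r.ci else (r.b_adjusted - 1.96 * r.se, r.b_adjusted + 1.96 * r.se)
        ax.errorbar(
            r.b_adjusted, i,
            xerr=[[r.b_adjusted - lo], [hi - r.b_adjusted]],
            fmt="o", color=colors.get(r.scenario, "k"), capsize=4,
        )
    ax.axvline(results[0].b_unadjusted, ls="--", color="grey", label="unadjusted")
    ax.set_yticks(range(len(results)), [r.scenario for r in results])
    ax.set_xlabel("adjusted exposure effect (Bxy)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
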