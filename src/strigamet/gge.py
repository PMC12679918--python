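"""GGE biplot engine: environment-centered SVD of a genotype x environment
mean-yield matrix and the "mean versus stability" view.

Centering each environment column removes the environment main effect, so the
singular value decomposition of the centered matrix captures genotype main
effect plus genotype x environment interaction (G + GE, hence "GGE").  The
average environment axis (AEA) runs from the biplot origin through the mean
of the environment markers in the PC1-PC2 plane; a genotype's projection onto
the AEA approximates its mean performance, and its perpendicular projection
(the AEA ordinate) its instability across environments, regardless of sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

SVP_MODES = {"genotype_focused": 1.0, "symmetric": 0.5, "environment_focused": 0.0}


@dataclass
class GgeModel:
    Y: pd.DataFrame  # genotypes x environments, raw means
    centered: pd.DataFrame
    svp_mode: str
    singular_values: np.ndarray
    genotype_scores: pd.DataFrame  # PC columns
    environment_scores: pd.DataFrame
    pct_explained: pd.Series
    degenerate: bool = False

    @property
    def n_pc(self) -> int:
        return len(self.singular_values)


def fit_gge(Y: pd.DataFrame, svp_mode: str = "genotype_focused") -> GgeModel:
    """Fit the GGE model to a genotype x environment mean matrix.

    Columns are environment-centered (no trait scaling), then decomposed by
    full SVD.  Genotype scores are U * S^f and environment scores V * S^(1-f)
    with f = 1 / 0.5 / 0 for genotype-focused / symmetric /
    environment-focused singular value partitioning.  Missing cells are
    refused (no imputation).  An all-equal matrix yields a degenerate model
    with zero scores, flagged explicitly.
    """
    if svp_mode not in SVP_MODES:
        raise ValueError(f"svp_mode must be one of {sorted(SVP_MODES)}")
    if Y.isna().to_numpy().any():
        cell = [(g, e) for g, e in zip(*np.where(Y.isna()))][0]
        raise ValueError(
            f"missing cell at genotype {Y.index[cell[0]]!r}, "
            f"environment {Y.columns[cell[1]]!r}; imputation is not supported"
        )
    if Y.shape[0] < 3 or Y.shape[1] < 2:
        raise ValueError("GGE needs >= 3 genotypes and >= 2 environments")
    M = Y.to_numpy(dtype=float)
    centered = M - M.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    total = float((s**2).sum())
    degenerate = total <= 1e-12 * max(1.0, float(np.abs(M).max()) ** 2)
    if degenerate:
        pct = np.zeros_like(s)
        gs = np.zeros_like(U)
        es = np.zeros_like(Vt.T)
    else:
        pct = 100.0 * s**2 / total
        f = SVP_MODES[svp_mode]
        gs = U * s**f
        es = Vt.T * s ** (1.0 - f)
    pcs = [f"PC{k + 1}" for k in range(len(s))]
    return GgeModel(
        Y=Y.copy(),
        centered=pd.DataFrame(centered, Y.index, Y.columns),
        svp_mode=svp_mode,
        singular_values=s,
        genotype_scores=pd.DataFrame(gs, index=Y.index, columns=pcs),
        environment_scores=pd.DataFrame(es, index=Y.columns, columns=pcs),
        pct_explained=pd.Series(pct, index=pcs, name="pct_explained"),
        degenerate=degenerate,
    )


def mean_vs_stability(model: GgeModel) -> pd.DataFrame:
    """Per-genotype AEA projections in the PC1-PC2 plane.

    Returns abscissa (mean-performance proxy), signed ordinate (instability),
    mean_rank (1 = largest abscissa) and stability_rank (1 = smallest
    |ordinate|).  The AEA direction is flipped if needed so the abscissa
    correlates positively with genotype marginal means.
    """
    if model.degenerate:
        raise ValueError("degenerate (all-equal) model: no AEA definable")
    if model.n_pc < 2:
        raise ValueError("mean-vs-stability view needs >= 2 principal components")
    env2 = model.environment_scores[["PC1", "PC2"]].to_numpy()
    aec = env2.mean(axis=0)
    norm = np.linalg.norm(aec)
    if norm < 1e-12:
        raise ValueError("average environment coordinate is zero: no AEA definable")
    aea = aec / norm
    gen2 = model.genotype_scores[["PC1", "PC2"]].to_numpy()
    absc = gen2 @ aea
    marginal = model.Y.mean(axis=1).to_numpy()
    if absc.std() > 0 and marginal.std() > 0 and np.corrcoef(absc, marginal)[0, 1] < 0:
        aea = -aea
        absc = -absc
    perp = np.array([-aea[1], aea[0]])
    ordin = gen2 @ perp
    return pd.DataFrame(
        {
            "abscissa": absc,
            "ordinate": ordin,
            "mean_rank": rankdata(-absc, method="average"),
            "stability_rank": rankdata(np.abs(ordin), method="average"),
        },
        index=model.Y.index,
    )


def select_entries(
    score: pd.Series,
    check_ids: list[str],
    k_best: int = 8,
    k_worst: int = 3,
    include_best_check: bool = True,
) -> list[str]:
    """Pick the GGE subset: top/bottom hybrids by a higher-is-better score,
    plus the best check."""
    hybrids = score.drop(index=[c for c in check_ids if c in score.index])
    if len(hybrids) < k_best + k_worst:
        raise ValueError(
            f"only {len(hybrids)} hybrids available for {k_best} best + {k_worst} worst"
        )
    ordered = hybrids.sort_values(ascending=False)
    chosen = list(ordered.index[:k_best]) + list(ordered.index[len(ordered) - k_worst :])
    if include_best_check:
        checks = score[[c for c in check_ids if c in score.index]]
        if checks.empty:
            raise ValueError("no checks available but include_best_check=True")
        chosen.append(checks.idxmax())
    return chosen


def plot_mean_vs_stability(model: GgeModel, stab: pd.DataFrame | None = None, ax=None):
    """Mean-vs-stability biplot: genotype/environment markers, the AEA with a
    single arrow, and its perpendicular ordinate through the origin."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    stab = stab if stab is not None else mean_vs_stability(model)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    g2 = model.genotype_scores[["PC1", "PC2"]]
    e2 = model.environment_scores[["PC1", "PC2"]]
    ax.scatter(g2["PC1"], g2["PC2"], marker="o", color="tab:blue", zorder=3)
    for name, row in g2.iterrows():
        ax.annotate(str(name), row.to_numpy(), fontsize=8, color="tab:blue")
    ax.scatter(e2["PC1"], e2["PC2"], marker="^", color="tab:red", zorder=3)
    for name, row in e2.iterrows():
        ax.annotate(str(name), row.to_numpy(), fontsize=8, color="tab:red")
    aec = e2.to_numpy().mean(axis=0)
    aea = aec / np.linalg.norm(aec)
    # orient like the returned abscissa
    if np.corrcoef(g2.to_numpy() @ aea, model.Y.mean(axis=1).to_numpy())[0, 1] < 0:
        aea = -aea
    lim = 1.15 * float(np.abs(np.vstack([g2.to_numpy(), e2.to_numpy()])).max())
    ax.annotate(
        "", xy=tuple(aea * lim), xytext=tuple(-aea * lim),
        arrowprops=dict(arrowstyle="-|>", color="green", lw=1.5),
    )
    perp = np.array([-aea[1], aea[0]])
    ax.plot([-perp[0] * lim, perp[0] * lim], [-perp[1] * lim, perp[1] * lim],
            color="green", ls="--", lw=1.0)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    pct = model.pct_explained
    ax.set_xlabel(f"PC1 ({pct['PC1']:.0f}%)")
    ax.set_ylabel(f"PC2 ({pct['PC2']:.0f}%)")
    ax.set_title(f"Mean vs stability (SVP: {model.svp_mode})")
    ax.set_aspect("equal")
    return ax.figure


def select_and_plot(
    yield_matrix: pd.DataFrame,
    score: pd.Series,
    check_ids: list[str],
    k_best: int = 8,
    k_worst: int = 3,
    include_best_check: bool = True,
    svp_mode: str = "genotype_focused",
    figure_path=None,
):
    """Subset the entry x environment yield matrix by index ranking, fit the
    GGE model, and render the mean-vs-stability figure.

    ``score`` is a higher-is-better ranking score per entry (base index for
    infested runs; negated RSI for *Striga*-free runs).  Returns
    (model, stability table, figure).
    """
    chosen = select_entries(score, check_ids, k_best, k_worst, include_best_check)
    missing = [g for g in chosen if g not in yield_matrix.index]
    if missing:
        raise ValueError(f"selected entries absent from yield matrix: {missing}")
    model = fit_gge(yield_matrix.loc[chosen], svp_mode=svp_mode)
    stab = mean_vs_stability(model)
    fig = plot_mean_vs_stability(model, stab)
    if figure_path is not None:
        fig.savefig(figure_path, bbox_inches="tight")
    return model, stab, fig


__all__ = [
    "SVP_MODES",
    "GgeModel",
    "fit_gge",
    "mean_vs_stability",
    "select_entries",
    "select_and_plot",
    "plot_mean_vs_stability",
]
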