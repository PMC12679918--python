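"""Combined analysis of variance for alpha-lattice multi-environment trials.

The model decomposes plot values over environments (E), replicates nested in
environments, incomplete blocks nested in replicates, hybrids (entries), and
the hybrid x environment interaction:

    y = mu + E + Rep(E) + Block(E x Rep) + Hybrid + Hybrid x E + error.

Sums of squares are sequential (Type I) in that order, computed by
orthogonalizing each term's indicator block against everything fitted before
it; on balanced complete layouts this coincides with the classical means
decomposition (and with Type III).  Hybrids are treated as fixed; the F-test
denominators follow the expected-mean-square logic of a mixed model with
random environments, replicates and blocks:

    Hybrid        vs Hybrid x E
    Hybrid x E    vs Error
    Environment   vs Rep(E)
    Rep(E), Block vs Error
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SOURCES = ["Environment", "Rep(E)", "Block(ExRep)", "Hybrid", "HybridxE", "Error"]

#: F-test denominator for each tested source.
DENOMINATORS = {
    "Environment": "Rep(E)",
    "Rep(E)": "Error",
    "Block(ExRep)": "Error",
    "Hybrid": "HybridxE",
    "HybridxE": "Error",
}

_TERMS = [
    ("Environment", ("env",)),
    ("Rep(E)", ("env", "rep")),
    ("Block(ExRep)", ("env", "rep", "block")),
    ("Hybrid", ("entry",)),
    ("HybridxE", ("entry", "env")),
]


def _indicator(records: pd.DataFrame, cols: tuple[str, ...]) -> np.ndarray:
    codes = records.groupby(list(cols), sort=True).ngroup().to_numpy()
    k = codes.max() + 1
    D = np.zeros((len(records), k))
    D[np.arange(len(records)), codes] = 1.0
    return D


def _check_connected(records: pd.DataFrame) -> None:
    presence = pd.crosstab(records["entry"], records["env"])
    missing = presence == 0
    if missing.to_numpy().any():
        entry = missing.any(axis=1).idxmax()
        env = missing.loc[entry].idxmax()
        raise ValueError(
            f"singular layout: entry {entry!r} has no plots in environment {env!r}"
        )


def _sequential_ss(records: pd.DataFrame, y: np.ndarray):
    """Sequential SS/df per term via blockwise orthogonalization.

    Each term's one-hot indicator block is residualized against the span of
    all preceding terms (including the intercept) and reduced by SVD; the
    term's df is the rank it adds and its SS the squared projection of y onto
    the added directions.
    """
    n = len(y)
    Q = np.full((n, 1), 1.0 / np.sqrt(n))
    rows = []
    for name, cols in _TERMS:
        D = _indicator(records, cols)
        # two rounds of Gram-Schmidt for numerical orthogonality
        for _ in range(2):
            D = D - Q @ (Q.T @ D)
        U, sv, _ = np.linalg.svd(D, full_matrices=False)
        tol = 1e-8 * np.sqrt(n)
        keep = sv > tol
        df = int(keep.sum())
        if df:
            Qa = U[:, keep]
            proj = Qa.T @ y
            ss = float(proj @ proj)
            Q = np.hstack([Q, Qa])
        else:
            ss = 0.0
        rows.append((name, df, ss))
    fitted = Q @ (Q.T @ y)
    resid = y - fitted
    ss_err = float(resid @ resid)
    df_err = n - Q.shape[1]
    rows.append(("Error", df_err, ss_err))
    return rows


@dataclass
class LsMeansResult:
    """Least-square entry means for one trait plus the LSD ingredients."""

    trait: str
    means: pd.Series  # indexed by entry
    error_ms: float
    error_df: float
    n_eff: float
    alpha: float = 0.05

    @property
    def lsd_value(self) -> float:
        return lsd(self.error_ms, self.error_df, self.n_eff, self.alpha)

    def table(self) -> pd.DataFrame:
        df = self.means.rename(self.trait).to_frame()
        return df


def combined_anova(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    """ANOVA table (source, df, sum_sq, mean_sq, f_value, p_value, denominator).

    Plots with a null trait value are dropped (their count is reported in
    ``df.attrs['n_dropped']``).  Raises on layouts where an entry is entirely
    absent from an environment.
    """
    data = records.dropna(subset=[trait])
    n_dropped = len(records) - len(data)
    if data["env"].nunique() < 2 or data["entry"].nunique() < 2:
        raise ValueError("combined ANOVA needs >=2 environments and >=2 entries")
    _check_connected(data)
    y = data[trait].to_numpy(dtype=float)
    rows = _sequential_ss(data, y)
    tab = pd.DataFrame(rows, columns=["source", "df", "sum_sq"])
    with np.errstate(invalid="ignore", divide="ignore"):
        tab["mean_sq"] = tab["sum_sq"] / tab["df"].replace(0, np.nan)
    ms = dict(zip(tab["source"], tab["mean_sq"]))
    dfs = dict(zip(tab["source"], tab["df"]))
    f_vals, p_vals, denoms = [], [], []
    for src in tab["source"]:
        den = DENOMINATORS.get(src)
        if den is None or not np.isfinite(ms.get(den, np.nan)) or ms[den] <= 0:
            f_vals.append(np.nan)
            p_vals.append(np.nan)
            denoms.append(den or "")
            continue
        f = ms[src] / ms[den]
        f_vals.append(f)
        p_vals.append(float(stats.f.sf(f, dfs[src], dfs[den])))
        denoms.append(den)
    tab["f_value"] = f_vals
    tab["p_value"] = p_vals
    tab["denominator"] = denoms
    tab.attrs["trait"] = trait
    tab.attrs["n_obs"] = len(data)
    tab.attrs["n_dropped"] = n_dropped
    return tab


def ls_means(records: pd.DataFrame, trait: str, alpha: float = 0.05) -> LsMeansResult:
    """Entry least-square means adjusted for environment, replicate and block.

    The additive model ``y ~ env + rep(env) + block(env, rep) + entry`` is fit
    by least squares (minimum-norm solution); each entry's LS mean is its
    predicted value averaged over every observed (env, rep, block) cell with
    equal weight.  On balanced complete data this equals the entry's raw mean.

    The LSD ingredients use the hybrid-comparison mean square — the
    Hybrid x E interaction MS that also serves as the hybrid F-test
    denominator — with effective replication = average plots per entry.
    """
    data = records.dropna(subset=[trait])
    if data["entry"].nunique() < 2:
        raise ValueError("LS means need >=2 entries")
    _check_connected(data)
    y = data[trait].to_numpy(dtype=float)
    n = len(data)

    blocks = [np.ones((n, 1))]
    for _, cols in _TERMS[:3]:  # env, rep(env), block(env, rep)
        blocks.append(_indicator(data, cols))
    cats = pd.Categorical(data["entry"])
    entries_d = np.zeros((n, len(cats.categories)))
    entries_d[np.arange(n), cats.codes] = 1.0
    entry_names = list(cats.categories)
    X = np.hstack(blocks + [entries_d])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    # reference grid: every observed nuisance cell, weighted equally
    nuis = np.hstack(blocks)
    cells = pd.DataFrame(nuis).drop_duplicates().to_numpy()
    c_nuis = cells.mean(axis=0)
    k_nuis = nuis.shape[1]
    base = float(c_nuis @ beta[:k_nuis])
    means = pd.Series(base + beta[k_nuis:], index=entry_names, name=trait).sort_index()

    anova_tab = combined_anova(records, trait) if data["env"].nunique() >= 2 else None
    if anova_tab is not None:
        ms = dict(zip(anova_tab["source"], anova_tab["mean_sq"]))
        dfs = dict(zip(anova_tab["source"], anova_tab["df"]))
        comp_src = "HybridxE" if dfs.get("HybridxE", 0) > 0 else "Error"
        error_ms, error_df = float(ms[comp_src]), float(dfs[comp_src])
    else:
        resid = y - X @ beta
        error_df = max(n - np.linalg.matrix_rank(X), 1)
        error_ms = float(resid @ resid) / error_df
    n_eff = float(stats.hmean(data.groupby("entry").size().to_numpy()))
    return LsMeansResult(trait, means, error_ms, error_df, n_eff, alpha)


def ls_means_table(
    records: pd.DataFrame, traits: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """LS means for several traits plus Mean/Max/Min/LSD summary footer rows."""
    cols = {}
    footer = {}
    for t in traits:
        res = ls_means(records, t, alpha)
        cols[t] = res.means
        footer[t] = {
            "Mean": res.means.mean(),
            "Max": res.means.max(),
            "Min": res.means.min(),
            f"LSD({alpha:g})": res.lsd_value,
        }
    body = pd.DataFrame(cols)
    foot = pd.DataFrame(footer)
    foot = foot.loc[["Mean", "Max", "Min", f"LSD({alpha:g})"]]
    return pd.concat([body, foot])


def lsd(error_ms: float, error_df: float, n_eff: float, alpha: float = 0.05) -> float:
    """Least significant difference: t(1-alpha/2, df) * sqrt(2 * MS / n_eff)."""
    if error_df < 1 or n_eff < 1:
        raise ValueError("error_df and n_eff must be >= 1")
    if error_ms < 0:
        raise ValueError("error mean square must be >= 0")
    t = stats.t.ppf(1.0 - alpha / 2.0, error_df)
    return float(t * np.sqrt(2.0 * error_ms / n_eff))


def significance_stars(p: float) -> str:
    """SAS-style significance flags at 0.05 / 0.01 / 0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


__all__ = [
    "SOURCES",
    "DENOMINATORS",
    "combined_anova",
    "ls_means",
    "ls_means_table",
    "LsMeansResult",
    "lsd",
    "significance_stars",
]
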