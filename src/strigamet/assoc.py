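"""Trait associations: Pearson correlations, cross-regime prediction
regressions, and forward stepwise regression of grain yield on agronomic
traits.

All operations work on entry-level least-square means (one value per hybrid),
the resolution at which breeders read such tables; the simple-regression and
correlation views are mutually consistent (R^2 of y~x equals r(x, y)^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided t-test p-values and n."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


@dataclass
class StepRecord:
    action: str  # "add" | "remove"
    trait: str
    partial_r2: float
    p_value: float


@dataclass
class RegressionResult:
    response: str
    predictors: list[str]
    intercept: float
    slopes: dict[str, float]
    r_squared: float
    n: int
    steps: list[StepRecord] = field(default_factory=list)

    @property
    def slope(self) -> float:
        """Convenience accessor for single-predictor fits."""
        if len(self.slopes) != 1:
            raise ValueError("slope is defined only for simple regressions")
        return next(iter(self.slopes.values()))


def correlate(means: pd.DataFrame, traits: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between trait columns.

    p-values are from the two-sided t test of H0: rho = 0.  A zero-variance
    trait yields undefined (NaN) correlations with a warning.
    """
    traits = traits or list(means.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if j < i:
                continue
            pair = means[[a, b]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                continue
            xa, xb = pair[a].to_numpy(float), pair[b].to_numpy(float)
            if xa.std() == 0 or xb.std() == 0:
                warnings.warn(f"zero-variance trait in pair ({a}, {b}); r undefined")
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            res = stats.pearsonr(xa, xb)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(traits)
    return CorrelationMatrix(
        r=pd.DataFrame(r, idx, idx),
        p=pd.DataFrame(p, idx, idx),
        n=pd.DataFrame(n, idx, idx),
    )


def two_triangle_table(
    upper: CorrelationMatrix, lower: CorrelationMatrix, stars=None
) -> pd.DataFrame:
    """Combined presentation table: one correlation set above the diagonal,
    the other below (classic infested-above / free-below layout)."""
    from .anova import significance_stars

    stars = stars or significance_stars
    traits = sorted(set(upper.r.columns) | set(lower.r.columns))
    out = pd.DataFrame("", index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if i == j:
                continue
            src = upper if j > i else lower
            if a in src.r.index and b in src.r.columns:
                val = src.r.loc[a, b]
                if np.isfinite(val):
                    out.loc[a, b] = f"{val:.2f}{stars(src.p.loc[a, b])}"
                    continue
            out.loc[a, b] = "-"
    return out


def _ols(y: np.ndarray, X: np.ndarray):
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    return model.fit()


def predict_cross_environment(x: pd.Series, y: pd.Series) -> RegressionResult:
    """OLS of a trait in one *Striga* regime on a trait in the other.

    ``x`` and ``y`` are entry-indexed means; entries are matched by index.
    Reports slope and R^2 — run it in both directions to assess whether
    performance in one regime predicts the other.
    """
    pair = pd.concat([x.rename("x"), y.rename("y")], axis=1).dropna()
    if len(pair) < 3:
        raise ValueError("cross-environment regression needs >= 3 matched entries")
    fit = _ols(pair["y"].to_numpy(float), pair["x"].to_numpy(float)[:, None])
    return RegressionResult(
        response=y.name or "y",
        predictors=[x.name or "x"],
        intercept=float(fit.params[0]),
        slopes={x.name or "x": float(fit.params[1])},
        r_squared=float(fit.rsquared),
        n=len(pair),
    )


def stepwise_forward(
    data: pd.DataFrame,
    response: str,
    candidates: list[str],
    sle: float = 0.15,
    sls: float = 0.15,
) -> RegressionResult:
    """Forward stepwise regression with entry/stay thresholds (SAS-style).

    At each step the candidate with the largest partial R^2 (increment to the
    model R^2) enters if its partial-F p-value is <= ``sle``; after each entry
    any included term whose p-value exceeds ``sls`` is removed.  Candidates
    nearly collinear with the included set (R^2 on it > 0.999) are skipped
    with a warning.  Each add/remove step records its partial R^2 (negative
    for removals), so the step partial R^2 values sum to the final model R^2.
    """
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate predictors")
    cols = [response] + list(candidates)
    d = data[cols].dropna()
    n = len(d)
    if n <= len(candidates) + 2:
        raise ValueError("too few observations for stepwise selection")
    y = d[response].to_numpy(float)
    included: list[str] = []
    steps: list[StepRecord] = []

    def fit_with(terms):
        if not terms:
            mu = y.mean()
            return None, 0.0
        f = _ols(y, d[terms].to_numpy(float))
        return f, float(f.rsquared)

    _, r2_cur = fit_with(included)
    while True:
        best = None
        for c in candidates:
            if c in included:
                continue
            if included:
                aux = _ols(d[c].to_numpy(float), d[included].to_numpy(float))
                if aux.rsquared > 0.999:
                    warnings.warn(f"candidate {c} nearly collinear with model; skipped")
                    continue
            fit, r2_new = fit_with(included + [c])
            partial = r2_new - r2_cur
            p_entry = float(fit.pvalues[-1])
            if best is None or partial > best[1]:
                best = (c, partial, p_entry, r2_new)
        if best is None or best[2] > sle:
            break
        c, partial, p_entry, r2_cur = best
        included.append(c)
        steps.append(StepRecord("add", c, partial, p_entry))
        # backward check against the stay threshold
        removed = True
        while removed and len(included) > 1:
            removed = False
            fit, r2_full = fit_with(included)
            pvals = dict(zip(included, fit.pvalues[1:]))
            worst = max(included, key=lambda t: pvals[t])
            if pvals[worst] > sls:
                included.remove(worst)
                _, r2_red = fit_with(included)
                steps.append(StepRecord("remove", worst, r2_red - r2_full, pvals[worst]))
                r2_cur = r2_red
                removed = True
    fit, r2_final = fit_with(included)
    if fit is None:
        return RegressionResult(response, [], float(y.mean()), {}, 0.0, n, steps)
    return RegressionResult(
        response=response,
        predictors=list(included),
        intercept=float(fit.params[0]),
        slopes={t: float(b) for t, b in zip(included, fit.params[1:])},
        r_squared=r2_final,
        n=n,
        steps=steps,
    )


__all__ = [
    "CorrelationMatrix",
    "RegressionResult",
    "StepRecord",
    "correlate",
    "two_triangle_table",
    "predict_cross_environment",
    "stepwise_forward",
]
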