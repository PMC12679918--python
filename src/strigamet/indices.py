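"""Selection indices for *Striga* trials.

Two complementary rankings are computed from entry least-square means:

* the *Striga* base index, used across infested environments — a linear index
  on standardized trait means,

      index = 2*MGY + EPP - (SHD1 + SHD2) - 1/2*(SEC1 + SEC2),

  where MGY is grain yield (t/ha), EPP ears per plant, SHD1/SHD2 host-damage
  scores at 8/10 weeks after planting and SEC1/SEC2 emerged-*Striga* counts
  at the same times.  A positive index marks a tolerant/resistant hybrid,
  a negative one a susceptible hybrid.

* the rank summation index (RSI), used across *Striga*-free environments —
  the sum of an entry's per-trait ranks (1 = best by the trait's
  orientation); the lowest total marks the most superior hybrid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .traits import TraitSpec, default_registry

BASE_INDEX_TRAITS = ["MGY", "EPP", "SHD1", "SHD2", "SEC1", "SEC2"]
RSI_TRAITS = ["YIELD", "EPP", "PLHT", "EASP", "PASP", "DYSK"]


def standardize(values) -> np.ndarray:
    """Center and scale to unit sample SD (ddof=1); constant input maps to zeros."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardization needs >= 2 entries")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def striga_base_index(ls_means: pd.DataFrame) -> pd.DataFrame:
    """Base index and tolerance classification from infested-environment LS means.

    Expects one row per entry with columns MGY (or YIELD), EPP, SHD1, SHD2,
    SEC1, SEC2.  All six components are standardized across entries before the
    weighted sum, so the index is scale-free and sums to zero over entries.
    Returns per-entry z-scores, the index, and the sign-based class
    (``tolerant/resistant`` if > 0, ``susceptible`` if < 0, ``boundary`` at
    exactly 0), sorted by descending index.
    """
    df = ls_means.copy()
    if "MGY" not in df.columns and "YIELD" in df.columns:
        df = df.rename(columns={"YIELD": "MGY"})
    missing = [t for t in BASE_INDEX_TRAITS if t not in df.columns]
    if missing:
        raise ValueError(f"base index missing component trait(s): {missing}")
    z = pd.DataFrame(
        {t: standardize(df[t].to_numpy()) for t in BASE_INDEX_TRAITS}, index=df.index
    )
    index = (
        2.0 * z["MGY"]
        + z["EPP"]
        - (z["SHD1"] + z["SHD2"])
        - 0.5 * (z["SEC1"] + z["SEC2"])
    )
    out = df[BASE_INDEX_TRAITS].copy()
    for t in BASE_INDEX_TRAITS:
        out[f"z_{t}"] = z[t]
    out["striga_base_index"] = index
    out["tolerance_class"] = np.select(
        [index > 0, index < 0], ["tolerant/resistant", "susceptible"], default="boundary"
    )
    return out.sort_values("striga_base_index", ascending=False)


def rank_summation_index(
    ls_means: pd.DataFrame,
    traits: list[str] | None = None,
    registry: dict[str, TraitSpec] | None = None,
    orientations: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rank summation index from *Striga*-free LS means.

    Each trait is ranked with 1 = best according to its orientation
    (``higher_better`` traits descending, ``lower_better`` ascending), ties
    receiving average ranks; the RSI is the per-entry sum of ranks.  Returns
    per-trait ranks and the total, sorted ascending (lowest RSI = most
    superior hybrid).

    Orientations come from ``orientations`` overrides, then the trait
    registry; a trait with no known orientation raises.
    """
    traits = traits or [t for t in RSI_TRAITS if t in ls_means.columns]
    registry = registry or default_registry()
    orientations = orientations or {}
    missing = [t for t in traits if t not in ls_means.columns]
    if missing:
        raise ValueError(f"RSI missing trait(s): {missing}")
    out = ls_means[traits].copy()
    ranks = {}
    for t in traits:
        orient = orientations.get(t) or (registry[t].orientation if t in registry else None)
        if orient not in ("higher_better", "lower_better"):
            raise ValueError(f"unknown ranking orientation for trait {t!r}")
        x = ls_means[t].to_numpy(dtype=float)
        ranks[t] = rankdata(-x if orient == "higher_better" else x, method="average")
        out[f"rank_{t}"] = ranks[t]
    out["rsi"] = np.sum(list(ranks.values()), axis=0)
    return out.sort_values("rsi", ascending=True)


__all__ = [
    "BASE_INDEX_TRAITS",
    "RSI_TRAITS",
    "standardize",
    "striga_base_index",
    "rank_summation_index",
]
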