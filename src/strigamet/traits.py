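"""Trait metadata, record validation, derived traits, and pre-analysis transforms.

The trait registry describes every phenotype measured on a maize trial plot:
its measurement scale, whether larger values are agronomically better, whether
it is log-transformed before analysis of variance, and in which *Striga*
treatment regimes it is defined at all.  Ratings (ear aspect, plant aspect,
*Striga* host-damage scores) are 1-9 ordinal scales where 1 is best; emerged
*Striga* plants are per-plot counts; flowering traits are days from planting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

TREATMENTS = ("infested", "free")
SCALES = ("continuous", "ordinal_1_9", "count", "days")
ORIENTATIONS = ("higher_better", "lower_better")

#: Identifier columns of the plot-record table, in canonical order.
ID_COLUMNS = ["env", "location", "year", "treatment", "rep", "block", "entry"]


@dataclass(frozen=True)
class TraitSpec:
    """Metadata for one measured or derived trait."""

    name: str
    scale: str
    orientation: str
    log_transform: bool = False
    treatments_defined: frozenset = field(
        default_factory=lambda: frozenset(TREATMENTS)
    )

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r} for trait {self.name}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"unknown orientation {self.orientation!r} for trait {self.name}"
            )
        if not self.treatments_defined <= set(TREATMENTS):
            raise ValueError(f"bad treatments for trait {self.name}")


def _spec(name, scale, orientation, log=False, treatments=TREATMENTS):
    return TraitSpec(name, scale, orientation, log, frozenset(treatments))


def default_registry() -> dict[str, TraitSpec]:
    """Registry for the standard *Striga* trial trait set.

    Ratings and emergence counts are right-skewed in the field and are flagged
    for a log10(x+1) transform before ANOVA.  Plant aspect (PASP) is scored
    only in *Striga*-free plots; damage scores and emergence counts only in
    infested plots.
    """
    return {
        s.name: s
        for s in [
            _spec("YIELD", "continuous", "higher_better"),
            _spec("PLHT", "continuous", "higher_better"),
            _spec("EHT", "continuous", "higher_better"),
            _spec("EPP", "continuous", "higher_better"),
            _spec("EASP", "ordinal_1_9", "lower_better", log=True),
            _spec("PASP", "ordinal_1_9", "lower_better", log=True, treatments=("free",)),
            _spec("DYSK", "days", "lower_better"),
            _spec("DAN", "days", "lower_better"),
            _spec("ASI", "days", "lower_better"),
            _spec("SHD1", "ordinal_1_9", "lower_better", log=True, treatments=("infested",)),
            _spec("SHD2", "ordinal_1_9", "lower_better", log=True, treatments=("infested",)),
            _spec("SEC1", "count", "lower_better", log=True, treatments=("infested",)),
            _spec("SEC2", "count", "lower_better", log=True, treatments=("infested",)),
        ]
    }


def registry_to_yaml(registry: dict[str, TraitSpec]) -> str:
    payload = {
        name: {
            "scale": s.scale,
            "orientation": s.orientation,
            "log_transform": s.log_transform,
            "treatments_defined": sorted(s.treatments_defined),
        }
        for name, s in registry.items()
    }
    return yaml.safe_dump(payload, sort_keys=True)


def registry_from_yaml(text: str) -> dict[str, TraitSpec]:
    payload = yaml.safe_load(text)
    return {
        name: TraitSpec(
            name=name,
            scale=d["scale"],
            orientation=d["orientation"],
            log_transform=bool(d.get("log_transform", False)),
            treatments_defined=frozenset(d.get("treatments_defined", TREATMENTS)),
        )
        for name, d in payload.items()
    }


def anthesis_silking_interval(dan, dysk):
    """Anthesis-silking interval in days: days-to-silking minus days-to-anthesis.

    Negative values (protandry reversal, silks before pollen shed) are allowed.
    Null inputs propagate to a null output.
    """
    if dan is None or dysk is None:
        return None
    if isinstance(dan, (int, float)) and isinstance(dysk, (int, float)):
        if math.isnan(dan) or math.isnan(dysk):
            return float("nan")
        return dysk - dan
    return np.asarray(dysk, dtype=float) - np.asarray(dan, dtype=float)


def grain_yield_t_ha(
    field_weight_kg: float,
    moisture_pct: float,
    shelling_pct: float = 80.0,
    plot_area_m2: float = 2.25,
) -> float:
    """Plot grain yield in t/ha from cob field weight.

    Field weight is shelled at ``shelling_pct`` and adjusted to 15 % grain
    moisture, then scaled from the plot area to a hectare::

        yield = w * (shelling/100) * (100 - moisture)/(100 - 15) / area * 10

    The factor 10 converts kg/m^2 to t/ha.
    """
    if field_weight_kg <= 0:
        raise ValueError("field weight must be positive")
    if not (0 < moisture_pct <= 100):
        raise ValueError("moisture percentage must be in (0, 100]")
    if plot_area_m2 <= 0:
        raise ValueError("plot area must be positive")
    adj = (100.0 - moisture_pct) / 85.0
    return field_weight_kg * (shelling_pct / 100.0) * adj / plot_area_m2 * 10.0


def plant_density_per_ha(
    row_spacing_m: float, hill_spacing_m: float, plants_per_hill: int
) -> int:
    """Stand density (plants/ha) implied by row x hill spacing, rounded to integer."""
    if row_spacing_m <= 0 or hill_spacing_m <= 0:
        raise ValueError("spacings must be positive")
    return int(round(plants_per_hill / (row_spacing_m * hill_spacing_m) * 10000.0))


def log_transform(x):
    """log10(x + 1); the +1 offset admits zero emergence counts."""
    x = np.asarray(x, dtype=float)
    if np.nanmin(x, initial=0.0) < 0:
        raise ValueError("log transform requires non-negative values")
    return np.log10(x + 1.0)


def apply_transforms(
    records: pd.DataFrame, registry: dict[str, TraitSpec] | None = None
) -> pd.DataFrame:
    """Return a copy with log-flagged traits replaced by log10(x+1).

    Untransformed traits are carried over bit-identically.  The set of
    transformed columns is recorded in ``df.attrs['transformed']`` so report
    writers can label back-transformed scales.
    """
    registry = registry or default_registry()
    out = records.copy()
    transformed = {}
    for name, spec in registry.items():
        if spec.log_transform and name in out.columns:
            vals = out[name].to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError(f"negative value in {name} under log transform")
            out[name] = np.log10(vals + 1.0)
            transformed[name] = "log10(x+1)"
    out.attrs["transformed"] = transformed
    return out


def validate_records(
    records: pd.DataFrame, registry: dict[str, TraitSpec] | None = None
) -> None:
    """Validate a plot-record table against the trait registry.

    Raises ``ValueError`` listing every violation found: missing identifier
    columns, ordinal values outside [1, 9], negative counts, non-positive
    yields, and trait values present in a treatment where the trait is
    undefined (e.g. *Striga* scores in a *Striga*-free environment).
    """
    registry = registry or default_registry()
    problems: list[str] = []
    for col in ID_COLUMNS:
        if col not in records.columns:
            problems.append(f"missing identifier column {col!r}")
    if problems:
        raise ValueError("; ".join(problems))
    treatment = records["treatment"].astype(str)
    for name, spec in registry.items():
        if name not in records.columns:
            continue
        vals = pd.to_numeric(records[name], errors="coerce")
        present = vals.notna()
        if spec.scale == "ordinal_1_9":
            bad = present & ((vals < 1) | (vals > 9) | (vals != np.round(vals)))
            if bad.any():
                problems.append(
                    f"{name}: {int(bad.sum())} values outside integer 1-9 scale"
                )
        elif spec.scale == "count":
            bad = present & (vals < 0)
            if bad.any():
                problems.append(f"{name}: {int(bad.sum())} negative counts")
        if name == "YIELD":
            bad = present & (vals <= 0)
            if bad.any():
                problems.append(f"YIELD: {int(bad.sum())} non-positive values")
        undefined = ~treatment.isin(spec.treatments_defined)
        stray = present & undefined
        if stray.any():
            envs = sorted(records.loc[stray, "env"].unique())
            problems.append(
                f"{name}: defined only for {sorted(spec.treatments_defined)} but "
                f"present in {envs}"
            )
    if problems:
        raise ValueError("invalid plot records: " + "; ".join(problems))


def percent_reduction(reference: float, stressed: float) -> float:
    """Percent loss of ``stressed`` relative to ``reference`` (e.g. yield under stress)."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (reference - stressed) / reference


def percent_advantage(candidate: float, check: float) -> float:
    """Percent superiority of ``candidate`` over ``check``."""
    if check == 0:
        raise ValueError("check value must be non-zero")
    return 100.0 * (candidate - check) / check


__all__ = [
    "TraitSpec",
    "default_registry",
    "registry_to_yaml",
    "registry_from_yaml",
    "anthesis_silking_interval",
    "grain_yield_t_ha",
    "plant_density_per_ha",
    "log_transform",
    "apply_transforms",
    "validate_records",
    "percent_reduction",
    "percent_advantage",
    "ID_COLUMNS",
]
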