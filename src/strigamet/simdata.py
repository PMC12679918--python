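"""Synthetic multi-environment maize trial generator.

Emulates a resolvable incomplete-block (alpha-lattice) hybrid trial run in
contrasting *Striga hermonthica* regimes: each environment is a location x
year x treatment (infested / free) combination, every replicate partitions
the full entry list into small blocks, and every plot carries the standard
trait set (grain yield, heights, ears per plant, aspect ratings, flowering
dates, and — in infested plots only — *Striga* damage scores at 8 and 10
weeks after planting plus emerged-*Striga* counts).

Ground truth is explicit so that downstream estimators can be checked for
parameter recovery: yields follow the additive mixed model

    y = mu + G_i + E_j + GE_ij + R_k(j) + B_l(jk) + e,

with all effects Gaussian, and infested-plot yield is additionally penalized
multiplicatively by host damage, ``y * (1 - penalty * (SHD2 - 1))``.  A
per-entry latent susceptibility drives damage scores, emergence counts and
(weakly) the aspect ratings, producing the sign structure typical of field
data: damage correlates negatively with yield and ears per plant, positively
with ear/plant aspect scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import traits as traits_mod


class Environment(NamedTuple):
    location: str
    year: int
    treatment: str  # "infested" | "free"

    @property
    def label(self) -> str:
        return f"{self.location}-{self.year}-{self.treatment}"


def default_environments(drop_free_abuja_2016: bool = True) -> list[Environment]:
    """Four infested + three free environments (two locations x two years,
    with the free trial at the first location in the first year dropped, as
    happens when land is unavailable)."""
    envs = []
    for loc in ("Abuja", "Mokwa"):
        for year in (2016, 2017):
            envs.append(Environment(loc, year, "infested"))
    for loc in ("Abuja", "Mokwa"):
        for year in (2016, 2017):
            if drop_free_abuja_2016 and (loc, year) == ("Abuja", 2016):
                continue
            envs.append(Environment(loc, year, "free"))
    return envs


@dataclass
class TrialDesign:
    """Layout parameters of one multi-environment alpha-lattice trial."""

    n_hybrids: int = 150
    n_checks: int = 6
    environments: list = field(default_factory=default_environments)
    reps_per_env: int = 2
    block_size: int = 12
    blocks_per_rep: int = 13
    row_spacing_m: float = 0.75
    hill_spacing_m: float = 0.40
    plants_per_hill: int = 2
    plot_length_m: float = 3.0
    seed: int = 2016

    def __post_init__(self):
        # accept (location, year, treatment) sequences, e.g. from JSON manifests
        self.environments = [
            e if isinstance(e, Environment) else Environment(*e)
            for e in self.environments
        ]

    @property
    def n_entries(self) -> int:
        return self.n_hybrids + self.n_checks

    @property
    def plot_area_m2(self) -> float:
        # single-row plots: length x row spacing
        return self.plot_length_m * self.row_spacing_m

    def entry_names(self) -> list[str]:
        return [f"H{i + 1:03d}" for i in range(self.n_hybrids)] + [
            f"CHK{i + 1}" for i in range(self.n_checks)
        ]

    def check_names(self) -> list[str]:
        return [f"CHK{i + 1}" for i in range(self.n_checks)]

    def validate(self, require_both_treatments: bool = False) -> None:
        if self.block_size * self.blocks_per_rep != self.n_entries:
            raise ValueError(
                f"block geometry {self.blocks_per_rep} blocks x {self.block_size} "
                f"plots does not tile {self.n_entries} entries"
            )
        if self.reps_per_env < 1 or not self.environments:
            raise ValueError("need at least one replicate and one environment")
        treatments = {e.treatment for e in self.environments}
        if not treatments <= {"infested", "free"}:
            raise ValueError(f"unknown treatments {treatments}")
        if require_both_treatments and treatments != {"infested", "free"}:
            raise ValueError(
                "cross-environment analyses need at least one infested and one "
                "free environment"
            )


@dataclass
class GroundTruth:
    """True simulation parameters; variances in (t/ha)^2.

    ``latent_susceptibility`` is a per-entry standardized susceptibility to
    *Striga*; ``tolerance_class`` partitions entries into tolerant and
    susceptible groups (assigned directly at hybrid level).
    """

    tolerance_class: np.ndarray
    latent_susceptibility: np.ndarray
    mu_yield: float = 4.9
    var_genotype: float = 0.02
    var_env: float = 0.40
    var_gxe: float = 0.05
    var_rep: float = 0.01
    var_block: float = 0.02
    var_error: float = 0.20
    striga_damage_slope: float = 1.1
    emergence_mean_tolerant: float = 10.0
    emergence_mean_susceptible: float = 24.0
    yield_penalty_per_damage: float = 0.085
    nb_dispersion: float = 2.0

    @classmethod
    def default(
        cls, n_entries: int = 156, seed: int = 0, frac_tolerant: float = 0.75, **over
    ) -> "GroundTruth":
        """Draw per-entry classes and susceptibilities; other fields from defaults."""
        rng = np.random.default_rng(seed)
        n_tol = int(round(frac_tolerant * n_entries))
        classes = np.array(["tolerant"] * n_tol + ["susceptible"] * (n_entries - n_tol))
        rng.shuffle(classes)
        s = np.where(
            classes == "tolerant",
            rng.normal(-0.4, 0.55, n_entries),
            rng.normal(1.2, 0.55, n_entries),
        )
        return cls(tolerance_class=classes, latent_susceptibility=s, **over)

    def validate(self, n_entries: int | None = None) -> None:
        for name in ("var_genotype", "var_env", "var_gxe", "var_rep", "var_block", "var_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.yield_penalty_per_damage <= 0.2:
            raise ValueError("yield_penalty_per_damage must be in [0, 0.2]")
        classes = set(np.asarray(self.tolerance_class))
        if not classes <= {"tolerant", "susceptible"}:
            raise ValueError(f"unknown tolerance classes {classes}")
        if len(self.tolerance_class) != len(self.latent_susceptibility):
            raise ValueError("class and susceptibility arrays differ in length")
        if n_entries is not None and len(self.tolerance_class) != n_entries:
            raise ValueError("ground truth sized for a different entry count")

    def to_json(self) -> str:
        d = asdict(self)
        d["tolerance_class"] = list(map(str, self.tolerance_class))
        d["latent_susceptibility"] = [float(x) for x in self.latent_susceptibility]
        return json.dumps(d, indent=2)


def build_design(design: TrialDesign) -> pd.DataFrame:
    """Field layout: one row per plot with env/rep/block/entry assignment.

    Within each replicate the entry list is randomly partitioned into
    ``blocks_per_rep`` disjoint blocks of ``block_size`` (a seeded random
    resolvable partition; alpha(0,1) efficiency optimization is out of scope —
    downstream analyses need only the blocking factor).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    entries = np.array(design.entry_names())
    rows = []
    for env in design.environments:
        for rep in range(1, design.reps_per_env + 1):
            perm = rng.permutation(entries)
            for b in range(design.blocks_per_rep):
                for entry in perm[b * design.block_size : (b + 1) * design.block_size]:
                    rows.append(
                        (env.label, env.location, env.year, env.treatment, rep, b + 1, entry)
                    )
    return pd.DataFrame(rows, columns=traits_mod.ID_COLUMNS)


def _round_score(latent: np.ndarray) -> np.ndarray:
    return np.clip(np.round(latent), 1, 9)


def simulate_trial(design: TrialDesign, truth: GroundTruth | None = None) -> pd.DataFrame:
    """Simulate one full multi-environment trial as a plot-record table.

    Determinism: identical (design, truth, design.seed) give identical output.
    Trait columns undefined for a plot's treatment are NaN (PASP in infested
    plots; SHD/SEC in free plots).
    """
    if truth is None:
        truth = GroundTruth.default(design.n_entries, seed=design.seed)
    design.validate()
    truth.validate(design.n_entries)

    layout = build_design(design)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 7_919]))

    entries = design.entry_names()
    e_idx = layout["entry"].map({e: i for i, e in enumerate(entries)}).to_numpy()
    env_labels = [e.label for e in design.environments]
    j_idx = layout["env"].map({e: i for i, e in enumerate(env_labels)}).to_numpy()
    infested = (layout["treatment"] == "infested").to_numpy()
    n = len(layout)
    n_ent, n_env = design.n_entries, len(env_labels)

    # entry-level latents: q = standardized general agronomic quality
    q = rng.normal(0.0, 1.0, n_ent)
    G = np.sqrt(truth.var_genotype) * q
    s = np.asarray(truth.latent_susceptibility, dtype=float)
    tol = np.asarray(truth.tolerance_class) == "tolerant"

    E = rng.normal(0.0, np.sqrt(truth.var_env), n_env)
    GE = rng.normal(0.0, np.sqrt(truth.var_gxe), (n_ent, n_env))
    # rep and block effects keyed by their nesting cells
    rep_codes = layout.groupby(["env", "rep"], sort=False).ngroup().to_numpy()
    blk_codes = layout.groupby(["env", "rep", "block"], sort=False).ngroup().to_numpy()
    R = rng.normal(0.0, np.sqrt(truth.var_rep), rep_codes.max() + 1)
    B = rng.normal(0.0, np.sqrt(truth.var_block), blk_codes.max() + 1)
    eps = rng.normal(0.0, np.sqrt(truth.var_error), n)

    y0 = truth.mu_yield + G[e_idx] + E[j_idx] + GE[e_idx, j_idx] + R[rep_codes] + B[blk_codes] + eps

    # per-environment agronomic shifts for heights and flowering
    ph_env = rng.normal(0.0, 5.0, n_env)
    dy_env = rng.normal(0.0, 2.0, n_env)

    s_plot = s[e_idx]
    q_plot = q[e_idx]
    inf = infested.astype(float)

    # Striga damage: shared plot latent -> correlated 8- and 10-week scores
    shd_lat = 5.0 + truth.striga_damage_slope * s_plot + rng.normal(0.0, 0.8, n)
    shd1 = _round_score(shd_lat - 0.5 + rng.normal(0.0, 0.4, n))
    shd2 = _round_score(shd_lat + rng.normal(0.0, 0.4, n))
    shd2 = np.maximum(shd2, shd1 - 1)  # damage does not recover by >1 class

    # emerged Striga: gamma-Poisson (negative binomial) with shared plot rate
    class_mean = np.where(tol, truth.emergence_mean_tolerant, truth.emergence_mean_susceptible)
    lam = (
        class_mean[e_idx]
        * np.exp(0.3 * s_plot)
        * rng.gamma(truth.nb_dispersion, 1.0 / truth.nb_dispersion, n)
    )
    sec1 = rng.poisson(0.75 * lam).astype(float)
    sec2 = rng.poisson(1.25 * lam).astype(float)

    yield_t = y0 * np.where(infested, 1.0 - truth.yield_penalty_per_damage * (shd2 - 1.0), 1.0)
    yield_t = np.maximum(yield_t, 0.05)

    epp = np.clip(
        0.9 + 0.5 * G[e_idx] - (0.12 + 0.15 * s_plot) * inf + rng.normal(0.0, 0.10, n),
        0.1,
        2.0,
    ).round(2)
    easp = _round_score(5.0 - 1.0 * q_plot + 0.8 * s_plot * inf + rng.normal(0.0, 1.0, n))
    pasp = _round_score(5.0 - 1.1 * q_plot + 0.15 * s_plot + rng.normal(0.0, 1.0, n))
    plht = 165.0 + 8.0 * q_plot - 3.0 * s_plot * inf + ph_env[j_idx] + rng.normal(0.0, 8.0, n)
    eht = 0.55 * plht + rng.normal(0.0, 6.0, n)
    dan = np.round(50.0 - 0.4 * q_plot + dy_env[j_idx] + rng.normal(0.0, 1.2, n))
    asi = np.round(2.0 + 0.3 * s_plot * inf + rng.normal(0.0, 0.8, n))
    dysk = dan + asi

    out = layout.copy()
    out["YIELD"] = np.round(yield_t, 4)
    out["PLHT"] = np.round(plht, 1)
    out["EHT"] = np.round(eht, 1)
    out["EPP"] = epp
    out["EASP"] = easp
    out["PASP"] = np.where(infested, np.nan, pasp)
    out["DYSK"] = dysk
    out["DAN"] = dan
    out["ASI"] = dysk - dan
    out["SHD1"] = np.where(infested, shd1, np.nan)
    out["SHD2"] = np.where(infested, shd2, np.nan)
    out["SEC1"] = np.where(infested, sec1, np.nan)
    out["SEC2"] = np.where(infested, sec2, np.nan)
    return out


def write_records_csv(records: pd.DataFrame, path, header_comments: list[str] | None = None):
    """Plot-record CSV with optional '#' comment header lines."""
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        records.to_csv(fh, index=False)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    return df


def write_truth_json(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())


__all__ = [
    "Environment",
    "default_environments",
    "TrialDesign",
    "GroundTruth",
    "build_design",
    "simulate_trial",
    "write_records_csv",
    "read_records_csv",
    "write_truth_json",
]
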