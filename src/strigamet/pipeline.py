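"""End-to-end trial analysis: simulate/load -> validate -> transform -> ANOVA
-> selection indices -> associations -> GGE, with every table written as a
commented CSV and the full run recorded in a JSON manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import anova as anova_mod
from . import assoc as assoc_mod
from . import gge as gge_mod
from . import indices as indices_mod
from . import simdata
from . import traits as traits_mod

log = logging.getLogger("strigamet")

COMBINED_TRAITS = ["YIELD", "PLHT", "EPP", "EASP", "EHT", "DYSK", "DAN", "ASI"]
INFESTED_TRAITS = COMBINED_TRAITS + ["SHD1", "SHD2", "SEC1", "SEC2"]
FREE_TRAITS = COMBINED_TRAITS + ["PASP"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    outdir: str = "strigamet_out"
    seed: int = 2016
    input_csv: str | None = None  # exactly one of input_csv / simulate
    simulate: bool = True
    design: dict = field(default_factory=dict)  # TrialDesign overrides
    truth: dict = field(default_factory=dict)  # GroundTruth overrides
    alpha: float = 0.05
    sle: float = 0.15
    sls: float = 0.15
    svp_mode: str = "genotype_focused"
    k_best: int = 8
    k_worst: int = 3
    log_level: str = "INFO"

    def __post_init__(self):
        if bool(self.input_csv) == bool(self.simulate):
            raise ValueError("exactly one of input_csv / simulate must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.setdefault("simulate", "input_csv" not in payload)
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)


def _write_csv(df: pd.DataFrame, path: Path, comments: list[str], index=True):
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=index)


def _anova_report(records: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Mean-square table (sources x traits) with significance stars."""
    cols = {}
    df_col = None
    for t in traits:
        tab = anova_mod.combined_anova(records, t)
        if df_col is None:
            df_col = pd.Series(tab["df"].to_numpy(), index=tab["source"], name="df")
        vals = []
        for _, row in tab.iterrows():
            star = anova_mod.significance_stars(row["p_value"]) if row["denominator"] else ""
            vals.append(f"{row['mean_sq']:.4g}{star}")
        cols[t] = pd.Series(vals, index=tab["source"])
    out = pd.DataFrame({"df": df_col, **cols})
    out.index.name = "source"
    return out


def _entry_env_yield_matrix(records: pd.DataFrame) -> pd.DataFrame:
    return records.pivot_table(index="entry", columns="env", values="YIELD", aggfunc="mean")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of output paths and key objects."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = [f"strigamet {__version__}", f"seed={config.seed}"]
    registry = traits_mod.default_registry()
    outputs: dict = {}

    # ------------------------------------------------------------------ input
    if config.simulate:
        design = simdata.TrialDesign(seed=config.seed, **config.design)
        truth = simdata.GroundTruth.default(
            design.n_entries, seed=config.seed, **config.truth
        )
        records = simdata.simulate_trial(design, truth)
        simdata.write_records_csv(records, outdir / "records.csv", head + ["stage=simulate"])
        simdata.write_truth_json(truth, outdir / "ground_truth.json")
        outputs["records"] = outdir / "records.csv"
        check_ids = design.check_names()
    else:
        records = simdata.read_records_csv(config.input_csv)
        check_ids = sorted(e for e in records["entry"].unique() if str(e).startswith("CHK"))
    log.info("loaded %d plot records (%d entries, %d environments)",
             len(records), records["entry"].nunique(), records["env"].nunique())

    traits_mod.validate_records(records, registry)
    if "ASI" not in records.columns and {"DAN", "DYSK"} <= set(records.columns):
        records["ASI"] = traits_mod.anthesis_silking_interval(records["DAN"], records["DYSK"])

    transformed = traits_mod.apply_transforms(records, registry)
    regimes = {
        t: records[records["treatment"] == t]
        for t in ("infested", "free")
        if (records["treatment"] == t).any()
    }
    for name in ("infested", "free"):
        if name not in regimes:
            log.warning("no %s environments in the input; skipping %s-only analyses", name, name)

    # ------------------------------------------------------------------ anova
    def anova_traits_for(df, wanted):
        return [
            t for t in wanted
            if t in df.columns and df[t].notna().any() and df.groupby("env")[t].nunique().min() > 0
        ]

    if len(regimes) == 2:
        tab = _anova_report(transformed, anova_traits_for(transformed, COMBINED_TRAITS))
        _write_csv(tab, outdir / "anova_combined.csv", head + ["stage=anova_combined",
                   "log10(x+1)-transformed: " + ",".join(transformed.attrs["transformed"])])
        outputs["anova_combined"] = outdir / "anova_combined.csv"
    for name, wanted in (("infested", INFESTED_TRAITS), ("free", FREE_TRAITS)):
        if name not in regimes:
            continue
        sub_t = transformed[transformed["treatment"] == name]
        if sub_t["env"].nunique() < 2:
            log.warning("single %s environment: per-regime ANOVA skipped", name)
            continue
        tab = _anova_report(sub_t, anova_traits_for(sub_t, wanted))
        _write_csv(tab, outdir / f"anova_{name}.csv", head + [f"stage=anova_{name}"])
        outputs[f"anova_{name}"] = outdir / f"anova_{name}.csv"

    # -------------------------------------------------------- LS means (raw)
    ls = {}
    for name, wanted in (("infested", INFESTED_TRAITS), ("free", FREE_TRAITS)):
        if name not in regimes or regimes[name]["env"].nunique() < 2:
            continue
        sub = regimes[name]
        traits_here = [t for t in wanted if t in sub.columns and sub[t].notna().any()]
        table = anova_mod.ls_means_table(sub, traits_here, config.alpha)
        ls[name] = table.iloc[: -4]  # entry rows without the footer
        _write_csv(table, outdir / f"lsmeans_{name}.csv",
                   head + [f"stage=lsmeans_{name}", "footer rows: Mean/Max/Min/LSD"])
        outputs[f"lsmeans_{name}"] = outdir / f"lsmeans_{name}.csv"

    # ---------------------------------------------------------------- indices
    base_idx = rsi = None
    if "infested" in ls:
        base_idx = indices_mod.striga_base_index(ls["infested"])
        _write_csv(base_idx, outdir / "indices_infested.csv",
                   head + ["stage=striga_base_index"])
        outputs["indices_infested"] = outdir / "indices_infested.csv"
    if "free" in ls:
        rsi = indices_mod.rank_summation_index(ls["free"], registry=registry)
        _write_csv(rsi, outdir / "indices_free.csv", head + ["stage=rank_summation_index"])
        outputs["indices_free"] = outdir / "indices_free.csv"

    # ----------------------------------------------------------- associations
    corr = {}
    for name, wanted in (("infested", INFESTED_TRAITS), ("free", FREE_TRAITS)):
        if name in ls:
            use = [t for t in wanted if t in ls[name].columns and t != "DAN" and t != "ASI" and t != "EHT"]
            corr[name] = assoc_mod.correlate(ls[name], use)
    if len(corr) == 2:
        two = assoc_mod.two_triangle_table(corr["infested"], corr["free"])
        _write_csv(two, outdir / "correlations.csv",
                   head + ["stage=correlations", "infested above diagonal, free below"])
        outputs["correlations"] = outdir / "correlations.csv"
    elif corr:
        name, only = next(iter(corr.items()))
        _write_csv(only.r.round(4), outdir / "correlations.csv",
                   head + [f"stage=correlations ({name} only)"])
        outputs["correlations"] = outdir / "correlations.csv"

    for name, cands in (
        ("infested", ["PLHT", "EPP", "EASP", "DYSK", "SHD1", "SHD2", "SEC1", "SEC2"]),
        ("free", ["PLHT", "EPP", "EASP", "PASP", "DYSK"]),
    ):
        if name not in ls:
            continue
        avail = [c for c in cands if c in ls[name].columns]
        res = assoc_mod.stepwise_forward(ls[name], "YIELD", avail, config.sle, config.sls)
        steps = pd.DataFrame(
            [(s.action, s.trait, s.partial_r2, s.p_value) for s in res.steps],
            columns=["action", "trait", "partial_r2", "p_value"],
        )
        steps.attrs["model_r2"] = res.r_squared
        _write_csv(steps, outdir / f"stepwise_{name}.csv",
                   head + [f"stage=stepwise_{name}", f"model R2={res.r_squared:.4f}"],
                   index=False)
        outputs[f"stepwise_{name}"] = outdir / f"stepwise_{name}.csv"

    if {"infested", "free"} <= set(ls):
        pairs = [
            ("YIELD(free)", ls["free"]["YIELD"], "YIELD(infested)", ls["infested"]["YIELD"]),
            ("YIELD(infested)", ls["infested"]["YIELD"], "YIELD(free)", ls["free"]["YIELD"]),
        ]
        if "PASP" in ls["free"].columns and "SHD2" in ls["infested"].columns:
            pairs += [
                ("PASP(free)", ls["free"]["PASP"], "SHD2(infested)", ls["infested"]["SHD2"]),
                ("SHD2(infested)", ls["infested"]["SHD2"], "PASP(free)", ls["free"]["PASP"]),
            ]
        rows = []
        for xn, x, yn, yv in pairs:
            r = assoc_mod.predict_cross_environment(x.rename(xn), yv.rename(yn))
            rows.append((xn, yn, r.slope, r.intercept, r.r_squared, r.n))
        cross = pd.DataFrame(rows, columns=["x", "y", "slope", "intercept", "r_squared", "n"])
        _write_csv(cross, outdir / "cross_prediction.csv",
                   head + ["stage=cross_prediction"], index=False)
        outputs["cross_prediction"] = outdir / "cross_prediction.csv"

    # -------------------------------------------------------------------- gge
    for name, score in (("infested", None if base_idx is None else base_idx["striga_base_index"]),
                        ("free", None if rsi is None else -rsi["rsi"])):
        if score is None or regimes[name]["env"].nunique() < 2:
            continue
        mat = _entry_env_yield_matrix(regimes[name])
        try:
            model, stab, fig = gge_mod.select_and_plot(
                mat, score, check_ids, config.k_best, config.k_worst,
                svp_mode=config.svp_mode, figure_path=outdir / f"gge_{name}.svg",
            )
        except ValueError as err:
            log.warning("GGE (%s) skipped: %s", name, err)
            continue
        scores = pd.concat([model.genotype_scores[["PC1", "PC2"]], stab], axis=1)
        _write_csv(scores, outdir / f"gge_{name}.csv",
                   head + [f"stage=gge_{name}",
                           f"PC1={model.pct_explained['PC1']:.1f}% "
                           f"PC2={model.pct_explained['PC2']:.1f}%"])
        outputs[f"gge_{name}"] = outdir / f"gge_{name}.csv"
        outputs[f"gge_{name}_figure"] = outdir / f"gge_{name}.svg"
        import matplotlib.pyplot as plt

        plt.close(fig)

    # --------------------------------------------------------------- manifest
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "strigamet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": sorted(str(p.name) for p in outputs.values()),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = outdir / "run_manifest.json"
    return outputs


def run_from_manifest(manifest_path) -> dict:
    """Re-execute a run exactly as recorded in its manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return run_pipeline(RunConfig(**manifest["config"]))


__all__ = ["RunConfig", "run_pipeline", "run_from_manifest",
           "COMBINED_TRAITS", "INFESTED_TRAITS", "FREE_TRAITS"]
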