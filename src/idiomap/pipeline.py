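"""End-to-end orchestration: simulate -> parcellate -> variability ->
group stats -> behaviour, with deterministic seeding and a run manifest.

Each stage consumes and produces plain TSV tables in the output
directory; a JSON manifest records the configuration, the per-stage
seeds (derived from the global seed by stage-name hashing, so stages can
be rerun independently) and a content hash of every table.  Rerunning
with the same config and seed reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour as bhv
from . import cohort, group_stats, parcellation, variability

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "subset_filter",
    "stage_seed",
]

FLOAT_FMT = "%.12g"


class PipelineError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-analysis run.

    preset:
        ``primary`` (whole sample), ``male-only`` (drop female rows before
        all statistics), ``adhd-strata`` (four-way ADHD x IQ strata ANCOVA
        on the autistic subsample), ``force-linear`` (battery with every
        term linear).
    """

    seed: int = 0
    out_dir: str = "idiomap_out"
    preset: str = "primary"
    cohort_preset: str = "table1"  # or "balanced"
    n_per_group: int = 30          # balanced preset only
    n_rois: int = 284
    fd_exclude: bool = True
    n_permutations: int = 0        # >0 enables the ROI permutation contrast
    battery_scheme: str = "whole"
    term_plan: str = "ks"

    def validate(self) -> None:
        if self.preset not in ("primary", "male-only", "adhd-strata",
                               "force-linear"):
            raise PipelineError(f"unknown preset {self.preset!r}")
        if self.cohort_preset not in ("table1", "balanced"):
            raise PipelineError(
                f"unknown cohort preset {self.cohort_preset!r}")
        if self.n_rois < 2:
            raise PipelineError("n_rois must be >= 2")
        if 0 < self.n_permutations < 100:
            raise PipelineError("n_permutations must be 0 or >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


def subset_filter(phenotype: pd.DataFrame, rule: str) -> pd.DataFrame:
    """Apply a sensitivity-analysis subset/stratification rule.

    ``male-only`` drops female rows; ``adhd-strata`` restricts to the
    autistic subsample and relabels ``group`` into four ADHD x IQ strata.
    """
    if rule == "male-only":
        return phenotype[phenotype["sex"].astype(str) == "M"].copy()
    if rule == "adhd-strata":
        if "adhd" not in phenotype.columns:
            raise PipelineError(
                "adhd-strata rule requires an 'adhd' column")
        asc = phenotype[phenotype["diagnostic_group"] == "ASC"].copy()
        flag = asc["adhd"].astype(bool).map({True: "+ADHD", False: "-ADHD"})
        asc["group"] = asc["group"].astype(str) + flag
        return asc
    raise PipelineError(f"unknown subset rule {rule!r}")


def _write(df: pd.DataFrame, path: Path, index: bool) -> str:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage and return the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashes: dict[str, str] = {}
    tables: dict[str, str] = {}

    def save(name, df, index):
        path = out / f"{name}.tsv"
        hashes[name] = _write(df, path, index)
        tables[name] = str(path)

    # --- simulate -------------------------------------------------------
    sim_seed = stage_seed(config.seed, "simulate")
    if config.cohort_preset == "table1":
        cfg = cohort.table1_config(seed=sim_seed, n_rois=config.n_rois)
    else:
        cfg = cohort.balanced_config(seed=sim_seed,
                                     n_per_group=config.n_per_group,
                                     n_rois=config.n_rois)
    phenotype, matrix = cohort.generate_cohort(cfg)

    if config.preset == "male-only":
        phenotype = subset_filter(phenotype, "male-only")
        matrix = matrix.loc[phenotype["id"]]
    save("phenotype", phenotype, index=False)
    save("activation_matrix", matrix, index=True)

    # --- parcellate stage: motion exclusion on the assembled matrix -----
    if config.fd_exclude:
        fd = phenotype.set_index("id")["mean_fd"]
        kept, excluded, thr = parcellation.apply_fd_exclusion(fd)
        report = pd.DataFrame({
            "id": list(fd.index),
            "mean_fd": fd.to_numpy(),
            "excluded": [i in set(excluded) for i in fd.index],
        })
        report.attrs["threshold"] = thr
        save("fd_exclusion", report, index=False)
        phenotype = phenotype[phenotype["id"].isin(kept)]
        matrix = matrix.loc[phenotype["id"]]

    # --- variability ----------------------------------------------------
    distmat = variability.distance_matrix(matrix)
    scores = variability.variability_scores(distmat, phenotype)
    save("distance_matrix", distmat, index=True)
    save("variability_scores", scores, index=True)

    # --- group statistics ----------------------------------------------
    stats_df = phenotype.merge(scores.reset_index(), on="id")
    response = f"variability_{config.battery_scheme}"

    if config.preset == "adhd-strata":
        strata = subset_filter(stats_df, "adhd-strata")
        anc = group_stats.ancova_main_effect(strata, response,
                                             reference=None)
        posthoc = group_stats.pairwise_posthoc(strata, response)
    else:
        anc3 = group_stats.ancova_main_effect(stats_df, response)
        anc2 = group_stats.ancova_main_effect(
            stats_df, response, group="diagnostic_group")
        anc = anc3
        posthoc = group_stats.pairwise_posthoc(stats_df, response)
        two = pd.DataFrame([{
            "factor": "diagnostic_group", "F": anc2.f_value,
            "p": anc2.p_value, "eta_p2": anc2.eta_p2,
            "df_effect": anc2.df_effect, "df_resid": anc2.df_resid,
        }])
        save("ancova_two_group", two, index=False)

    main_tbl = pd.DataFrame([{
        "factor": anc.group_col, "F": anc.f_value, "p": anc.p_value,
        "eta_p2": anc.eta_p2, "df_effect": anc.df_effect,
        "df_resid": anc.df_resid,
    }])
    save("ancova_main", main_tbl, index=False)
    save("ancova_covariates", anc.covariate_table, index=False)
    save("posthoc", posthoc, index=False)

    if config.n_permutations:
        roi = group_stats.roi_group_contrast(
            matrix, stats_df.set_index("id")["diagnostic_group"],
            covariates=stats_df.set_index("id")[["age", "sex", "mean_fd"]],
            n_permutations=config.n_permutations,
            seed=stage_seed(config.seed, "roi-contrast"))
        save("roi_contrast", roi, index=True)

    # --- behaviour battery ---------------------------------------------
    battery = bhv.run_battery(
        scores, phenotype, scheme=config.battery_scheme,
        force_linear=(config.preset == "force-linear"),
        term_plan=config.term_plan)
    save("battery", battery, index=False)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("simulate", "roi-contrast")},
        "n_participants": int(len(phenotype)),
        "tables": tables,
        "hashes": hashes,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
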