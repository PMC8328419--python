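"""End-to-end orchestration: simulate -> derive -> impute -> resample ->
metrics -> partition -> trends, under one config with per-stage seeds.

A single base seed deterministically derives one sub-seed per stochastic
stage, so any stage can be rerun in isolation and the whole pipeline is
byte-reproducible. Every stage writes its table as CSV into the output
directory and the run ends with a provenance manifest (config hash,
seeds, row counts per stage, undefined-metric counts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fd_metrics, gradient_models, imputation, partitioning, resampling
from .synthetic import (
    SimulationParams, StudyDesign, knockout_missing, simulate_measurements,
    simulate_traits,
)
from .traits import MEASUREMENTS, TRAITS, derive_trait_table, normalize_traits

logger = logging.getLogger("deepfd.pipeline")

STAGES = ("simulate", "derive", "impute", "resample", "metrics", "partition", "trends")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; round-trips through YAML unchanged."""

    base_seed: int = 0
    out_dir: str = "results/pipeline"
    #: stages to run, in canonical order
    stages: tuple[str, ...] = STAGES
    # simulation
    n_species: int = 144
    sigma2_S: float = 2.0
    sigma2_I: float = 1.0
    sigma2_I_depth_slope: float = 0.0
    sigma2_S_lat_slope: float = 0.0
    missing_rate: float = 0.04
    # imputation
    imputation_runs: int = 20
    imputation_trees: int = 300
    imputation_max_iter: int = 20
    # resampling / metrics
    n_rep: int = 100
    fhv_samples_per_point: int = 10_000
    min_s_fhv: int = 5
    # trait handling
    log_total_length: bool = False
    mpfd_i_per_species_mean: bool = False

    def stage_seeds(self) -> dict[str, int]:
        """One sub-seed per stochastic stage, derived from the base seed."""
        ss = np.random.SeedSequence(self.base_seed)
        children = ss.spawn(len(STAGES))
        return {
            stage: int(child.generate_state(1)[0] % (2**31 - 1))
            for stage, child in zip(STAGES, children)
        }

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def digest(self) -> str:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        return hashlib.sha256(
            yaml.safe_dump(data, sort_keys=True).encode()
        ).hexdigest()[:16]


METRIC_NAMES = ["FHV", "MPFD", "MNND", "VPFD", "VNND"]
INDIVIDUAL_METRICS = ["MPFD_I", "Prop_I"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return the output tables.

    Returns a dict with keys among: morpho, occurrences, individuals,
    cell_metrics, partition, trends, manifest.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {"config_hash": config.digest(), "seeds": seeds, "stages": {}}
    outputs: dict = {}

    def log_stage(stage, t0, **counts):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2), **counts}
        logger.info("stage=%s %s (%.1fs)", stage, counts, time.time() - t0)

    design = StudyDesign()
    params = SimulationParams(
        n_species=config.n_species, sigma2_S=config.sigma2_S,
        sigma2_I=config.sigma2_I,
        sigma2_I_depth_slope=config.sigma2_I_depth_slope,
        sigma2_S_lat_slope=config.sigma2_S_lat_slope,
        seed=seeds["simulate"],
    )

    if "simulate" in config.stages:
        t0 = time.time()
        sim = simulate_traits(design, params)
        morpho = simulate_measurements(sim.individuals, seed=seeds["simulate"] + 1)
        if config.missing_rate > 0:
            # missingness arises from video measurement; museum specimens are
            # well-preserved and complete, guaranteeing the fallback pool
            bruv_mask = morpho["source"] == "bruv"
            knocked = knockout_missing(
                morpho[bruv_mask], config.missing_rate, seed=seeds["simulate"] + 2
            )
            museum = morpho[~bruv_mask].copy()
            museum["n_missing"] = 0
            museum["exceeds_max_missing"] = False
            morpho = pd.concat([knocked, museum]).sort_index()
        morpho.to_csv(out_dir / "morpho_records.csv", index=False)
        sim.occurrences.to_csv(out_dir / "occurrences.csv", index=False)
        sim.species_means.to_csv(out_dir / "truth_species_means.csv", index=False)
        sim.cell_truth.to_csv(out_dir / "truth_cells.csv", index=False)
        outputs.update(morpho=morpho, occurrences=sim.occurrences, sim=sim)
        log_stage("simulate", t0, individuals=len(morpho),
                  occurrences=len(sim.occurrences))

    if "impute" in config.stages and outputs.get("morpho") is not None:
        t0 = time.time()
        filled, audit = imputation.impute(
            outputs["morpho"], n_runs=config.imputation_runs,
            n_trees=config.imputation_trees,
            max_iter=config.imputation_max_iter, seed=seeds["impute"],
        )
        audit.to_csv(out_dir / "imputation_audit.csv", index=False)
        outputs["morpho"] = filled
        log_stage("impute", t0, imputed_values=len(audit))

    if "derive" in config.stages and outputs.get("morpho") is not None:
        t0 = time.time()
        morpho = outputs["morpho"]
        complete = morpho[morpho[MEASUREMENTS].notna().all(axis=1)]
        individuals = derive_trait_table(complete)
        individuals.to_csv(out_dir / "individual_traits.csv", index=False)
        outputs["individuals"] = individuals
        log_stage("derive", t0, complete=len(complete),
                  dropped=len(morpho) - len(complete))

    if "resample" in config.stages or "metrics" in config.stages:
        t0 = time.time()
        tables = resampling.build_replicates(
            outputs["occurrences"], outputs["individuals"],
            n_rep=config.n_rep, seed=seeds["resample"],
        )
        per_rep = []
        for r, table in enumerate(tables):
            cm = fd_metrics.compute_cell_metrics(
                table, min_s_fhv=config.min_s_fhv,
                fhv_samples_per_point=config.fhv_samples_per_point,
                seed=seeds["metrics"] + r,
            )
            cm.insert(0, "replicate", r)
            per_rep.append(cm)
        all_metrics = pd.concat(per_rep, ignore_index=True)
        all_metrics.to_csv(out_dir / "replicate_metrics.csv", index=False)
        averaged = resampling.average_metrics(
            all_metrics, METRIC_NAMES + ["S"],
            cell_cols=("depth_m", "location", "latitude_s"),
        )
        averaged.to_csv(out_dir / "cell_metrics.csv", index=False)
        outputs["cell_metrics"] = averaged
        log_stage("resample", t0, replicates=len(tables),
                  undefined_fhv=int(all_metrics["FHV"].isna().sum()))

    if "partition" in config.stages:
        t0 = time.time()
        bruv = outputs["individuals"]
        bruv = bruv[bruv["source"] == "bruv"]
        norm, _ = normalize_traits(bruv, log_total_length=config.log_total_length)
        part = partitioning.partition_cells(norm, trait_cols=TRAITS)
        part.to_csv(out_dir / "partition.csv", index=False)
        outputs["partition"] = part
        log_stage("partition", t0, cells=len(part),
                  undefined=int(part["Prop_I"].isna().sum()))

    if "trends" in config.stages:
        t0 = time.time()
        cm = outputs["cell_metrics"]
        part = outputs["partition"]
        merged = cm.merge(
            part[["depth_m", "location", "latitude_s", "MPFD_I", "Prop_I"]],
            on=["depth_m", "location", "latitude_s"], how="outer",
        )
        rows = []
        degrees: dict[str, dict[str, int]] = {}
        for metric in METRIC_NAMES + INDIVIDUAL_METRICS:
            transform = "log10" if metric in gradient_models.LOG10_METRICS else "none"
            degrees[metric] = {}
            for fixed in ("depth", "latitude"):
                spec = gradient_models.TrendSpec(
                    response=metric, fixed_gradient=fixed, transform=transform
                )
                try:
                    fit = gradient_models.fit_mixed_trend(merged, spec)
                except Exception as exc:
                    rows.append({"metric": metric, "analysis": fixed,
                                 "flag": f"failed:{exc}"})
                    continue
                degrees[metric][fixed] = fit.degree
                rows.append({
                    "metric": metric, "analysis": fixed, "degree": fit.degree,
                    "linear_coef": fit.coefficients.iloc[1],
                    "linear_p": fit.pvalues.iloc[1],
                    "r2_marginal": fit.r2_marginal,
                    "r2_conditional": fit.r2_conditional,
                    "flag": fit.flag,
                })
            if len(degrees[metric]) == 2:
                rep = gradient_models.interaction_test(
                    merged, metric, degrees[metric]["depth"],
                    degrees[metric]["latitude"], transform=transform,
                )
                rows.append({
                    "metric": metric, "analysis": "interaction",
                    "branch": rep.branch, "statistic": rep.statistic,
                    "linear_coef": rep.coefficient, "linear_p": rep.pvalue,
                    "flag": rep.flag,
                })
        trends = pd.DataFrame(rows)
        trends.to_csv(out_dir / "trends.csv", index=False)
        outputs["trends"] = trends
        log_stage("trends", t0, fits=len(trends))

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    outputs["manifest"] = manifest
    return outputs
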