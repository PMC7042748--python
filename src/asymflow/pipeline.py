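"""End-to-end orchestration: simulate or load, then run the analysis stages.

Stages run in dependency order; each stage writes its own artifact files so
it can also be run standalone through the CLI with the same file contracts.
A stage failure halts its dependents with the stage name attached.  The
report bundle is a JSON document whose every number comes from a stage
output, plus a provenance block (config echo, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymigrate import MigrationConfig, run_migration_mcmc
from .growthgdd import fit_growth_model
from .ibdmantel import (
    PairwiseMatrix,
    ibd_regression,
    load_catchment_fixture,
    mantel_test,
)
from .kinstructure import (
    classify_dyads,
    dedupe_full_sibs,
    dyads_to_frame,
    site_pair_counts,
)
from .ldne import ld_ne
from .pitclass import classify_movements, default_solar_table, nocturnal_fraction
from .popgenstats import (
    fis_by_group_locus,
    filter_individuals,
    flag_problem_loci,
    pairwise_fst,
    summary_table,
)
from .synthcatch import SimulationConfig, default_antennae, simulate_dataset
from .pitclass import SpawningWindow

log = logging.getLogger("asymflow")


@dataclass
class RunConfig:
    """Pipeline configuration; every threshold is a named key."""

    outdir: str = "asymflow_run"
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate", "qc", "growth", "telemetry", "popgen", "ibd", "ne", "kin",
        "migrate",
    )
    simulation: dict = field(default_factory=dict)
    min_scored_loci: int = 10
    fis_qc_threshold: float = 0.15
    fis_qc_min_groups: int = 6
    maf_threshold: float = 0.02
    lr_accept: float = 0.9
    maturity_sd_multiplier: float = 1.0
    n_perm_fst: int = 199
    n_perm_mantel: int = 9999
    mcmc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return the report bundle (also written
    to ``<outdir>/report.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
        },
        "stages": {},
    }
    state: dict = {}

    def run_stage(name: str, fn) -> None:
        if name not in config.stages:
            return
        t0 = _time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - provenance matters here
            raise StageError(name, exc) from exc
        dt = _time.perf_counter() - t0
        log.info("stage %s finished in %.2fs", name, dt)
        report["stages"][name] = {"seconds": round(dt, 3), **(result or {})}

    # ---- simulate --------------------------------------------------------
    def stage_simulate() -> dict:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        sim = SimulationConfig(**sim_kwargs)
        dataset = simulate_dataset(sim)
        dataset.write(out / "simulated")
        state["dataset"] = dataset
        return {
            "n_genotyped": dataset.genotypes.n_individuals,
            "n_detections": int(len(dataset.detections)),
            "realized_migrants": {
                k: v for k, v in dataset.truth.items() if k.startswith("migrant")
            },
        }

    run_stage("simulate", stage_simulate)
    if "dataset" not in state:
        raise StageError("simulate", RuntimeError("no dataset available"))
    dataset = state["dataset"]

    # ---- qc --------------------------------------------------------------
    def stage_qc() -> dict:
        table, counts = filter_individuals(
            dataset.genotypes, min_scored=config.min_scored_loci
        )
        fis = fis_by_group_locus(table)
        flagged = flag_problem_loci(
            fis,
            fis_threshold=config.fis_qc_threshold,
            min_groups=config.fis_qc_min_groups,
        )
        state["table"] = table.drop_loci(flagged) if flagged else table
        return {**counts, "flagged_loci": sorted(flagged)}

    run_stage("qc", stage_qc)
    table = state.get("table", dataset.genotypes)

    # ---- growth ----------------------------------------------------------
    def stage_growth() -> dict:
        model = fit_growth_model(dataset.captures, dataset.temperatures)
        model.to_json(out / "growth_model.json")
        state["growth_model"] = model
        return asdict(model)

    run_stage("growth", stage_growth)

    # ---- telemetry -------------------------------------------------------
    def stage_telemetry() -> dict:
        windows = [SpawningWindow.for_season(2017), SpawningWindow.for_season(2018)]
        records, tab = classify_movements(
            dataset.detections, default_antennae(), windows
        )
        tab.to_csv(out / "behavior_summary.csv", index=False)
        solar = default_solar_table(
            dataset.detections["timestamp"].dt.date.min(),
            dataset.detections["timestamp"].dt.date.max(),
        )
        noct = nocturnal_fraction(dataset.detections, solar)
        overall = tab[tab["season"] == "overall"].set_index("stream")
        return {
            "nocturnal_fraction": noct,
            "outflow_total": int(overall.loc["outflow_upper", "total"]),
            "outflow_exclusive": int(overall.loc["outflow_upper", "exclusive"]),
            "inflow_total": int(overall.loc["inflow", "total"]),
            "inflow_exclusive": int(overall.loc["inflow", "exclusive"]),
            "both": int(overall.loc["outflow_upper", "both"]),
        }

    run_stage("telemetry", stage_telemetry)

    # ---- popgen ----------------------------------------------------------
    def stage_popgen() -> dict:
        summ = summary_table(table)
        summ.to_csv(out / "summary_stats.csv", index=False)
        fst = pairwise_fst(table, n_perm=config.n_perm_fst, seed=config.seed)
        fst.to_csv(out / "pairwise_fst.csv", index=False)
        state["fst"] = fst
        return {
            "groups": summ["group"].tolist(),
            "mean_he": float(summ["He"].mean()),
            "max_theta": float(fst["theta"].max()),
        }

    run_stage("popgen", stage_popgen)

    # ---- ibd (catchment fixture) ----------------------------------------
    def stage_ibd() -> dict:
        geo, gen = load_catchment_fixture()
        mantel = mantel_test(geo, gen, n_perm=config.n_perm_mantel, seed=config.seed)
        fit = ibd_regression(geo, gen)
        return {
            "mantel_z": mantel.z,
            "mantel_p": mantel.p,
            "ibd_slope": fit.slope,
            "ibd_r_squared": fit.r_squared,
        }

    run_stage("ibd", stage_ibd)

    # ---- ne --------------------------------------------------------------
    def stage_ne() -> dict:
        rows = {}
        for group in table.group_names():
            est = ld_ne(table, group, maf_threshold=config.maf_threshold)
            rows[group] = {
                "ne": est.ne if np.isfinite(est.ne) else "Infinite",
                "ci": [
                    v if np.isfinite(v) else "Infinite" for v in est.ci
                ],
                "mean_r2": est.mean_r2,
            }
        pd.DataFrame(rows).T.to_csv(out / "ne_estimates.csv")
        return {"ne": rows}

    run_stage("ne", stage_ne)

    # ---- kin -------------------------------------------------------------
    def stage_kin() -> dict:
        dyads = classify_dyads(table, lr_threshold=config.lr_accept)
        frame = dyads_to_frame(dyads)
        frame[frame["accepted"]].to_csv(out / "dyads.csv", index=False)
        hs_counts = site_pair_counts(dyads, "HS")
        hs_counts.to_csv(out / "halfsib_site_pairs.csv")
        deduped, removed = dedupe_full_sibs(table, dyads)
        state["table_deduped"] = deduped
        accepted = frame[frame["accepted"]]
        return {
            "n_pairs_scored": int(len(frame)),
            "accepted_by_category": accepted["category"].value_counts().to_dict(),
            "mixed_site_halfsib": int(
                (accepted["mixed_site"] & (accepted["category"] == "HS")).sum()
            ),
            "full_sibs_removed": len(removed),
        }

    run_stage("kin", stage_kin)

    # ---- migrate ---------------------------------------------------------
    def stage_migrate() -> dict:
        mcmc_kwargs = dict(config.mcmc)
        mcmc_kwargs.setdefault("seed", config.seed)
        mig_table = state.get("table_deduped", table)
        posterior = run_migration_mcmc(
            mig_table, ("inflow", "outflow"), MigrationConfig(**mcmc_kwargs)
        )
        return {
            "means": posterior.means,
            "credible_intervals": {
                k: list(v) for k, v in posterior.credible_intervals.items()
            },
            "r_hat": posterior.r_hat,
            "converged": posterior.converged,
        }

    run_stage("migrate", stage_migrate)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
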