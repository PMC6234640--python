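"""End-to-end orchestration of the empirical analysis and simulation study.

Each stage reads and writes plain TSV files so any stage can be re-run
on its own; every output directory gets a machine-readable manifest
carrying the seed and a hash of the configuration, making reruns
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import popstats
from .ascertainment import SimConfig, aggregate_replicates, run_replicates
from .grs import CorrectionConstants, score_table
from .panel import Panel, joint_sfs_counts
from .synthetic import read_disease_table, read_genotypes


@dataclass(frozen=True)
class RunConfig:
    """Paths, toggles, and simulation settings for one pipeline run."""

    panel: str
    loci: str | None = None
    genotypes: str | None = None
    outdir: str = "out"
    seed: int = 0
    sfs_bins: int = 10
    daf_bin_width: float = 0.2
    correction: tuple[float, float] = (0.1902, 0.1082)
    # simulation-study grid
    study_pops: tuple[str, ...] = ("AFR", "AMR", "EAS", "EUR", "SAS", "MIX")
    platforms: tuple[str, ...] = ("WGS",)
    risk_states: tuple[str, ...] = ("ancestral", "derived")
    n_reps: int = 10
    sim: dict = field(default_factory=dict)  # overrides for SimConfig fields

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "panel" not in raw:
            raise ValueError(f"config {path} must be a mapping with a 'panel' key")
        for key in ("study_pops", "platforms", "risk_states", "correction"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(outdir: Path, config: RunConfig, stage: str, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def run_empirical_analysis(config: RunConfig) -> dict[str, Path]:
    """Category summaries, state differences, DAF bins, joint SFS, GRS tables.

    Returns a mapping of output names to written paths; any stage error
    aborts with the failing stage named.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "load"
    try:
        panel = Panel.read_tsv(config.panel)
        if config.loci is None:
            raise ValueError("empirical analysis needs a disease-locus table")
        loci = read_disease_table(config.loci)

        stage = "category_summaries"
        summaries = popstats.category_summaries(loci, panel)
        path = outdir / "category_summary.tsv"
        summaries.to_csv(path, sep="\t", index=False)
        outputs["category_summary"] = path

        stage = "state_differences"
        d = popstats.frequency_difference_by_state(loci, panel)
        prop_anc = float((loci["risk_state"] == "ancestral").mean())
        sd = pd.DataFrame(
            [
                {
                    "delta_ancestral": d.delta_ancestral,
                    "delta_derived": d.delta_derived,
                    "frac_higher_afr_ancestral": d.frac_higher_afr_ancestral,
                    "frac_higher_afr_derived": d.frac_higher_afr_derived,
                    "n_ancestral": d.n_ancestral,
                    "n_derived": d.n_derived,
                    "prop_ancestral": prop_anc,
                    "delta_overall": popstats.overall_weighted_difference(
                        d.delta_ancestral, d.delta_derived, prop_anc
                    ),
                }
            ]
        )
        path = outdir / "state_differences.tsv"
        sd.to_csv(path, sep="\t", index=False)
        outputs["state_differences"] = path

        stage = "daf_bins"
        bins = popstats.daf_bin_differences(loci, panel, bin_width=config.daf_bin_width)
        path = outdir / "daf_bins.tsv"
        bins.to_csv(path, sep="\t", index=False)
        outputs["daf_bins"] = path

        stage = "joint_sfs"
        m = joint_sfs_counts(panel, "EUR", "AFR", bins=config.sfs_bins)
        path = outdir / "joint_sfs_EUR_AFR.tsv"
        pd.DataFrame(m).to_csv(path, sep="\t", index=False, header=False)
        outputs["joint_sfs"] = path

        if config.genotypes is not None:
            stage = "risk_scores"
            genotypes = read_genotypes(config.genotypes)
            constants = CorrectionConstants(*config.correction)
            scores = score_table(genotypes, loci, constants=constants)
            path = outdir / "scores.tsv"
            scores.to_csv(path, sep="\t", index=False)
            outputs["scores"] = path
    except Exception as err:
        raise RuntimeError(f"empirical analysis failed at stage {stage!r}: {err}") from err

    _write_manifest(outdir, config, "empirical", {"outputs": sorted(str(p) for p in outputs.values()),
                                                  "n_panel": len(panel), "n_loci": len(loci)})
    outputs["manifest"] = outdir / "manifest.json"
    return outputs


def run_simulation_study(config: RunConfig) -> dict[str, Path]:
    """Replicated discovery simulations over the configured grid.

    One summary row per (platform, study population, risk state) cell:
    across-replicate means and SDs of the population contrasts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        panel = Panel.read_tsv(config.panel)
        stage = "simulate"
        rows = []
        for platform in config.platforms:
            for study_pop in config.study_pops:
                for risk_state in config.risk_states:
                    cfg = SimConfig(
                        platform=platform,
                        study_pop=study_pop,
                        risk_state=risk_state,
                        seed=config.seed,
                        **config.sim,
                    )
                    agg = aggregate_replicates(run_replicates(panel, cfg, config.n_reps))
                    agg["platform"] = platform
                    agg["study_pop"] = study_pop
                    agg["risk_state"] = risk_state
                    rows.append(agg)
        table = pd.DataFrame(rows)
        front = ["platform", "study_pop", "risk_state"]
        table = table[front + [c for c in table.columns if c not in front]]
        path = outdir / "simulation_summary.tsv"
        table.to_csv(path, sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"simulation study failed at stage {stage!r}: {err}") from err

    _write_manifest(outdir, config, "simulate", {"n_panel": len(panel), "n_cells": len(rows)})
    return {"simulation_summary": path, "manifest": outdir / "manifest.json"}
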