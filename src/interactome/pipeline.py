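"""End-to-end orchestration: simulate -> deconvolve -> crosstalk ->
consensus -> survival -> correlate, with a JSON artifact manifest.

A single global seed drives the synthetic stage; all downstream stages
are deterministic functions of their inputs, so identical config + seed
gives byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from interactome import io as iio
from interactome.association import correlation_long, spearman_matrix, write_correlations
from interactome.consensus import consensus_genes
from interactome.crosstalk import AXES, CrosstalkConfig, extract_axis_genes, rc_scores
from interactome.deconvolution import deconvolve
from interactome.io import ValidationError, atomic_write
from interactome.survival import run_survival_screen, write_screen_results
from interactome.synthio import SimulationConfig, config_from_dict, generate_bundle, write_bundle

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters for a full synthetic-pipeline run."""

    outdir: str = "pipeline_out"
    seed: int = 0
    simulation: SimulationConfig | None = None
    crosstalk: CrosstalkConfig = field(default_factory=CrosstalkConfig)
    min_sets: int = 2
    endpoints: tuple[str, ...] = ("os", "dfs")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        ct = raw.pop("crosstalk", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = config_from_dict(sim)
        if ct is not None:
            cfg.crosstalk = CrosstalkConfig(**ct)
        if cfg.endpoints:
            cfg.endpoints = tuple(cfg.endpoints)
        return cfg


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the manifest dict.

    Any stage failure raises with the stage name attached, leaving no
    partial artifact for that stage (all writes are atomic).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, path: Path, n_rows: int) -> None:
        manifest["stages"].setdefault(stage, {})[path.name] = {
            "path": str(path),
            "rows": int(n_rows),
        }

    stage = "simulate"
    try:
        sim_config = config.simulation or SimulationConfig(seed=config.seed)
        if config.simulation is not None and config.simulation.seed != config.seed:
            sim_config = SimulationConfig(
                **{**sim_config.__dict__, "seed": config.seed}
            )
        bundle = generate_bundle(sim_config)
        sim_dir = outdir / "simulated"
        paths = write_bundle(bundle, sim_dir)
        for name, p in paths.items():
            path = Path(p)
            if name == "expression":
                record(stage, path, len(bundle.expression))
            elif name == "clinical":
                record(stage, path, len(bundle.clinical))
            elif name == "catalog":
                record(stage, path, len(bundle.catalog))
            else:
                record(stage, path, -1)

        stage = "deconvolve"
        profiles = deconvolve(bundle.expression, bundle.purity)
        profiles_path = outdir / "compartment_profiles.tsv"
        iio.write_profiles(profiles, profiles_path)
        record(stage, profiles_path, len(profiles))

        stage = "crosstalk"
        rc = rc_scores(profiles, bundle.catalog, config.crosstalk)
        rc_path = outdir / "rc_scores.csv"
        iio.write_rc_table(rc, rc_path)
        record(stage, rc_path, len(rc))
        axis_genes = extract_axis_genes(rc, config.crosstalk)
        for axis in (*AXES, "all"):
            p = outdir / f"axis_genes_{axis}.txt"
            iio.write_gene_set(axis_genes[axis], p)
            record(stage, p, len(axis_genes[axis]))

        stage = "consensus"
        consensus = consensus_genes(bundle.evidence, min_sets=config.min_sets)
        consensus_path = outdir / "consensus_genes.csv"
        with atomic_write(consensus_path) as tmp:
            consensus.to_csv(tmp, index=False)
        record(stage, consensus_path, len(consensus))
        gene_list = consensus["gene"].tolist()

        stage = "survival"
        for endpoint in config.endpoints:
            screen = run_survival_screen(
                bundle.expression, bundle.clinical, gene_list, endpoint
            )
            p = outdir / f"survival_{endpoint}.csv"
            write_screen_results(screen, p)
            record(stage, p, len(screen))

        stage = "correlate"
        testable = [g for g in gene_list if g in bundle.expression.index]
        if len(testable) >= 2:
            rho, pv = spearman_matrix(bundle.expression, testable)
            long_table = correlation_long(rho, pv)
        else:
            long_table = pd.DataFrame(
                columns=["gene_a", "gene_b", "rho", "p", "strong"]
            )
        corr_path = outdir / "correlations.csv"
        write_correlations(long_table, corr_path)
        record(stage, corr_path, len(long_table))
    except Exception as exc:
        raise ValidationError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    with atomic_write(manifest_path) as tmp:
        tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
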