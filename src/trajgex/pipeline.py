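"""End-to-end orchestration: simulate -> preprocess -> variance partition
-> differential expression -> trajectory clustering -> enrichment.

Every stage writes its outputs as TSV under an output directory and the
run is summarized in a JSON manifest (parameters, seed, per-stage gene
counts, consensus correlation, moderation prior).  Re-running with the
same configuration and seed reproduces all outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, de, enrich, io, preprocess, simulate
from .clustering import cluster_trajectories
from .simulate import MHC_CHROM, MHC_END, MHC_START
from .varpart import variance_fractions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Flat configuration for :func:`run_all`."""

    outdir: str = "trajgex_run"
    seed: int = 0
    # simulation
    n_subjects: int = 40
    n_genes: int = 2000
    retention_prob: float = 0.5
    amplitude_log2: float = 1.0
    subject_sd: float = 0.5
    residual_sd: float = 0.5
    # analysis
    df: int = 3
    fc_threshold: float = 1.10
    alpha: float = 0.05
    grid_step: float = 0.5
    k_clusters: int = 24
    linkage: str = "average"
    # optional external inputs
    expression: str | None = None  # skip simulation when given
    samples: str | None = None
    annotation: str | None = None
    gmt: str | None = None
    varpart_genes: int = 200  # cap on genes entering the variance partition
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order and return the JSON-ready manifest."""
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "trajgex_version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": [],
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)
        return time.time()

    # -- simulate (or load) ------------------------------------------------
    t0 = stage("simulate")
    if config.expression:
        expr = io.read_expression(config.expression)
        samples = io.read_samples(config.samples)
        annotation = (
            io.read_annotation(config.annotation) if config.annotation else None
        )
        truth = None
    else:
        sim = simulate.simulate_dataset(
            simulate.SimulationConfig(
                n_subjects=config.n_subjects,
                n_genes=config.n_genes,
                retention_prob=config.retention_prob,
                amplitude_log2=config.amplitude_log2,
                subject_sd=config.subject_sd,
                residual_sd=config.residual_sd,
                seed=config.seed,
            )
        )
        expr, samples, annotation, truth = (
            sim.expression, sim.samples, sim.annotation, sim.truth,
        )
        io.write_expression(expr, outdir / "expression.tsv")
        io.write_samples(samples, outdir / "samples.tsv")
        io.write_annotation(annotation, outdir / "annotation.tsv")
        io.write_truth(truth, outdir / "ground_truth.tsv")
    io.check_sample_alignment(expr, samples)
    manifest["n_genes"] = int(expr.shape[0])
    manifest["n_samples"] = int(expr.shape[1])
    logger.info("simulate: %.1fs", time.time() - t0)

    # -- preprocess --------------------------------------------------------
    t0 = stage("preprocess")
    expr = preprocess.quantile_normalize(expr)
    io.write_expression(expr, outdir / "expression.normalized.tsv")
    logger.info("preprocess: %.1fs", time.time() - t0)

    # -- variance partition ------------------------------------------------
    t0 = stage("varpart")
    vp_expr = expr.iloc[: config.varpart_genes]
    fractions = variance_fractions(vp_expr, samples, df=config.df)
    io.write_table(fractions, outdir / "variance_fractions.tsv")
    manifest["varpart_genes"] = int(len(vp_expr))
    manifest["varpart_median_fractions"] = {
        k: round(float(v), 4) for k, v in fractions.median().items()
    }
    logger.info("varpart: %.1fs", time.time() - t0)

    # -- differential expression -------------------------------------------
    t0 = stage("de")
    res = de.run_de(
        expr,
        samples,
        df=config.df,
        fc_threshold=config.fc_threshold,
        alpha=config.alpha,
        grid_step=config.grid_step,
    )
    io.write_table(res.table.join(res.trajectories), outdir / "de_results.tsv")
    manifest["consensus_rho"] = round(res.rho, 4)
    manifest["d0"] = res.d0 if res.d0 == float("inf") else round(res.d0, 3)
    manifest["s0_sq"] = round(res.s0_sq, 6)
    manifest["n_de_genes"] = int(res.table["de_flag"].sum())
    logger.info("de: %.1fs (%d DE genes)", time.time() - t0, manifest["n_de_genes"])

    # -- trajectory clustering ----------------------------------------------
    t0 = stage("cluster")
    de_genes = res.de_genes
    if len(de_genes) >= 2:
        assign = cluster_trajectories(
            res.trajectories.loc[de_genes],
            k=config.k_clusters,
            method=config.linkage,
        )
        io.write_table(assign.labels, outdir / "clusters.tsv")
        io.write_table(assign.cluster_means, outdir / "cluster_means.tsv")
        manifest["n_clusters"] = int(assign.labels["cluster"].nunique())
        manifest["archetype_counts"] = (
            assign.labels["archetype"].value_counts().to_dict()
        )
        flagged = set(de_genes)
    else:
        logger.warning("cluster: fewer than 2 DE genes; stage skipped")
        manifest["n_clusters"] = 0
        flagged = set(de_genes)
    logger.info("cluster: %.1fs", time.time() - t0)

    # -- enrichment ---------------------------------------------------------
    t0 = stage("enrich")
    universe = set(expr.index)
    rows = {}
    if annotation is not None:
        categories = {
            "t1d": set(annotation.index[annotation["is_t1d"]]),
            "mhc_region": enrich.region_filter(
                annotation, MHC_CHROM, MHC_START, MHC_END
            ),
        }
        for name, cat in categories.items():
            if not cat:
                continue
            r = enrich.fisher_exact_2x2(
                enrich.build_contingency(flagged, cat, universe)
            )
            rows[name] = {
                "odds_ratio": round(r.odds_ratio, 3),
                "p": r.p,
                "table": dataclasses.asdict(r.table),
            }
    manifest["enrichment"] = rows
    if config.gmt:
        sets = enrich.read_gmt(config.gmt)
        ora = enrich.ora_gene_sets(flagged, universe, sets, alpha=config.alpha)
        ora.to_csv(outdir / "ora_results.tsv", sep="\t", index=False)
        manifest["n_significant_sets"] = int(ora["significant"].sum())
    logger.info("enrich: %.1fs", time.time() - t0)

    manifest["runtime_s"] = round(time.time() - t_start, 1)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
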