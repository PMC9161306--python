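"""End-to-end pipeline: preprocess -> concordance -> null simulation ->
clustering -> enrichment -> network, with a JSON run manifest.

All stage outputs are plain TSV (GraphML for the network); reruns with an
identical configuration and inputs produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import (assignment_frame, cluster_patterns, default_ensemble,
                         genotype_distances, overlapping_clusters,
                         patterns_from_summaries)
from .concordance import pair_table
from .dataset import read_measurements
from .enrichment import bin_label_sets, profile_scores, rank_list, scaled_ranks
from .network import (aggregate_bins, build_network, compare_genotypes,
                      filter_connections, write_graphml)
from .null_model import SimulationMode, SimulationSpec, fpr_curve, simulate_dataset
from .preprocessing import apply_outlier_masks, summarize_dataset, summary_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; every field has a recorded default."""

    input: str = ""
    annotation: str | None = None
    outdir: str = "concoex_out"
    alpha_flat: float = 0.05
    outlier_threshold: float = 5.0
    ic_network: float = 7.0
    ic_screening: float = 6.0
    spearman_alpha: float = 0.05
    cluster_method: str = "kmeans"
    cluster_k: int = 13
    top_fraction_interactions: float = 0.10
    top_fraction_molecules: float = 0.25
    sim_modes: list[str] = field(default_factory=lambda: [m.value for m in SimulationMode])
    sim_seed: int = 0
    sim_reps: int = 3
    bin_depth: int | None = None
    random_state: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load YAML or JSON config; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    logger.info("stage output %s: %d rows", path.name, len(df))


def _file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages; returns a name -> path map of written artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    datasets = read_measurements(config.input)
    genotypes = sorted(datasets)
    logger.info("stage preprocess: %d genotypes", len(genotypes))

    summaries = {}
    for gt in genotypes:
        apply_outlier_masks(datasets[gt], config.outlier_threshold)
        summaries[gt] = summarize_dataset(datasets[gt], config.alpha_flat)
    summary = pd.concat([summary_frame(summaries[gt]) for gt in genotypes],
                        ignore_index=True)
    artifacts["summary"] = outdir / "summary.tsv"
    _write(summary, artifacts["summary"])

    pairs = {gt: pair_table(datasets[gt], summaries[gt]) for gt in genotypes}
    all_pairs = pd.concat(pairs.values(), ignore_index=True)
    artifacts["pairs"] = outdir / "pairs.tsv"
    _write(all_pairs, artifacts["pairs"])

    # null simulation and FPR curves
    curves = []
    for gt in genotypes:
        for r in range(config.sim_reps):
            for mode in config.sim_modes:
                seed = (config.sim_seed + 7919 * r
                        + 104729 * list(SimulationMode).index(SimulationMode(mode)))
                sim = simulate_dataset(datasets[gt], summaries[gt],
                                       SimulationSpec(mode=mode, seed=seed))
                sim_sums = summarize_dataset(sim, config.alpha_flat)
                sim_pairs = pair_table(sim, sim_sums)
                for measure in ("ic", "rho"):
                    cf = fpr_curve(pairs[gt], sim_pairs, measure).to_frame()
                    cf.insert(0, "genotype", gt)
                    cf.insert(1, "mode", mode)
                    cf.insert(2, "rep", r)
                    curves.append(cf)
    artifacts["fpr_curves"] = outdir / "fpr_curves.tsv"
    _write(pd.concat(curves, ignore_index=True), artifacts["fpr_curves"])

    # clustering of metabolite patterns, pooled over genotypes
    patterns = [p for gt in genotypes
                for p in patterns_from_summaries(summaries[gt]["metabolite"])]
    n_nonflat = sum(not p.is_flat for p in patterns)
    k = min(config.cluster_k, max(2, n_nonflat - 1))
    if k != config.cluster_k:
        logger.warning("cluster_k reduced from %d to %d (only %d non-flat patterns)",
                       config.cluster_k, k, n_nonflat)
    assignments = [cluster_patterns(patterns, config.cluster_method, k,
                                    config.random_state)]
    if len(genotypes) >= 2:
        assignments.append(overlapping_clusters(patterns, config.cluster_method, k,
                                                config.random_state))
        ensemble = default_ensemble(patterns, k, config.random_state)
        dgt = genotype_distances(patterns, ensemble)
        artifacts["genotype_distance"] = outdir / "genotype_distance.tsv"
        _write(dgt, artifacts["genotype_distance"])
    artifacts["clusters"] = outdir / "cluster_assignments.tsv"
    _write(assignment_frame(assignments), artifacts["clusters"])

    # over-representation of metabolites (and bins, if annotated) in the
    # ic-sorted interaction table
    annotation = (pd.read_csv(config.annotation, sep="\t")
                  if config.annotation else None)
    scores_met, scores_bin = {}, {}
    for gt in genotypes:
        ranked = rank_list(pairs[gt], "ic", "desc")
        met_labels = ranked["metabolite_id"].tolist()
        entities = sorted(set(met_labels))
        scores_met[gt] = profile_scores(met_labels, entities,
                                        config.top_fraction_interactions)
        if annotation is not None:
            bin_labels = bin_label_sets(ranked["phosphopeptide_id"], annotation,
                                        config.bin_depth)
            bins = sorted({b for s in bin_labels for b in s})
            scores_bin[gt] = profile_scores(bin_labels, bins,
                                            config.top_fraction_interactions)
    artifacts["enrichment_metabolites"] = outdir / "enrichment_metabolites.tsv"
    _write(scaled_ranks(scores_met), artifacts["enrichment_metabolites"])
    if scores_bin:
        artifacts["enrichment_bins"] = outdir / "enrichment_bins.tsv"
        _write(scaled_ranks(scores_bin), artifacts["enrichment_bins"])

    # network
    connections = pd.concat(
        [filter_connections(pairs[gt], config.ic_network, config.spearman_alpha)
         for gt in genotypes], ignore_index=True)
    artifacts["connections"] = outdir / "connections.tsv"
    _write(connections, artifacts["connections"])
    if annotation is not None and not connections.empty:
        edges = aggregate_bins(connections, annotation, config.bin_depth)
        artifacts["network_edges"] = outdir / "network_edges.tsv"
        _write(edges, artifacts["network_edges"])
        if not edges.empty:
            g = build_network(edges)
            artifacts["network_graphml"] = outdir / "network.graphml"
            write_graphml(g, artifacts["network_graphml"])
            if edges["genotype"].nunique() >= 2:
                artifacts["genotype_comparison"] = outdir / "genotype_comparison.tsv"
                _write(compare_genotypes(edges), artifacts["genotype_comparison"])

    manifest = {
        "config": asdict(config),
        "input_sha256": _file_sha256(config.input),
        "genotypes": genotypes,
        "version": __version__,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    artifacts["manifest"] = outdir / "manifest.json"
    artifacts["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return artifacts
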