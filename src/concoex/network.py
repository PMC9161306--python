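"""Connection filtering and metabolite-bin network assembly.

A *connection* is a metabolite-phosphopeptide pair whose concordance
index matches or exceeds a threshold (default 7 for network building; 6
is the screening default), whose Spearman p-value is significant, and
whose partners are both non-flat.  Connections are aggregated per
(metabolite, functional bin, genotype) with the arithmetic mean of the
member I_C values as edge weight, and assembled into a bipartite
multigraph with one parallel edge per genotype.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import truncate_bin

logger = logging.getLogger(__name__)

NETWORK_IC_MIN = 7.0
SCREENING_IC_MIN = 6.0
DEFAULT_ALPHA = 0.05


def filter_connections(pair_table: pd.DataFrame, ic_min: float = NETWORK_IC_MIN,
                       alpha: float = DEFAULT_ALPHA,
                       discordant: bool = False) -> pd.DataFrame:
    """Rows passing the I_C, Spearman-significance and non-flat filters.

    With ``discordant=True`` the mirror filter ic <= -ic_min selects
    discordant pairs instead.  The result is deterministically ordered by
    (metabolite_id, phosphopeptide_id).
    """
    ic = pair_table["ic"]
    passing = (ic <= -ic_min) if discordant else (ic >= ic_min)
    keep = (passing
            & (pair_table["rho_p"] <= alpha)
            & ~pair_table["flat_m"].astype(bool)
            & ~pair_table["flat_p"].astype(bool))
    out = pair_table.loc[keep].sort_values(
        ["metabolite_id", "phosphopeptide_id"], kind="mergesort").reset_index(drop=True)
    logger.info("kept %d / %d pairs as connections (ic_min=%s, alpha=%s, discordant=%s)",
                len(out), len(pair_table), ic_min, alpha, discordant)
    return out


def aggregate_bins(connections: pd.DataFrame, annotation: pd.DataFrame,
                   bin_depth: int | None = None) -> pd.DataFrame:
    """Mean-I_C edges per (metabolite, truncated bin, genotype).

    A phosphopeptide mapping to several bins contributes a connection to
    each; unannotated phosphopeptides fall into bin "unknown" (logged).
    """
    if connections.empty:
        return pd.DataFrame(columns=["metabolite_id", "bin_code", "genotype",
                                     "mean_ic", "n_connections"])
    mapping: dict[str, set[str]] = {}
    for mid, code in zip(annotation["molecule_id"], annotation["bin_code"]):
        mapping.setdefault(str(mid), set()).add(truncate_bin(code, bin_depth))
    unannotated = sorted(set(connections["phosphopeptide_id"]) - set(mapping))
    if unannotated:
        logger.warning("%d phosphopeptides without annotation -> bin 'unknown'",
                       len(unannotated))
    rows = []
    for rec in connections.itertuples(index=False):
        for bin_code in sorted(mapping.get(rec.phosphopeptide_id, {"unknown"})):
            rows.append((rec.metabolite_id, bin_code, rec.genotype, rec.ic))
    exploded = pd.DataFrame(rows, columns=["metabolite_id", "bin_code", "genotype", "ic"])
    edges = (exploded.groupby(["metabolite_id", "bin_code", "genotype"], as_index=False)
             .agg(mean_ic=("ic", "mean"), n_connections=("ic", "size")))
    return edges.sort_values(["metabolite_id", "bin_code", "genotype"],
                             kind="mergesort").reset_index(drop=True)


def build_network(edges: pd.DataFrame) -> nx.MultiGraph:
    """Bipartite metabolite <-> bin multigraph, one parallel edge per genotype."""
    if edges.empty:
        raise ValueError("no edges to build a network from")
    g = nx.MultiGraph()
    for rec in edges.itertuples(index=False):
        met = f"met:{rec.metabolite_id}"
        bn = f"bin:{rec.bin_code}"
        g.add_node(met, type="metabolite", label=rec.metabolite_id, bipartite=0)
        g.add_node(bn, type="bin", label=str(rec.bin_code), bipartite=1)
        g.add_edge(met, bn, key=rec.genotype, genotype=rec.genotype,
                   mean_ic=float(rec.mean_ic), n_connections=int(rec.n_connections))
    return g


def degree_table(g: nx.MultiGraph) -> pd.DataFrame:
    """Total and per-genotype degree of every node."""
    genotypes = sorted({d["genotype"] for _, _, d in g.edges(data=True)})
    rows = []
    for node, data in g.nodes(data=True):
        row = {"node": data["label"], "type": data["type"], "degree": g.degree(node)}
        for gt in genotypes:
            row[f"degree_{gt}"] = sum(1 for _, _, d in g.edges(node, data=True)
                                      if d["genotype"] == gt)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["type", "node"],
                                          kind="mergesort").reset_index(drop=True)


def compare_genotypes(edges: pd.DataFrame) -> pd.DataFrame:
    """Per-node degree and summed edge weight per genotype, with flags.

    Needs edges from >= 2 genotypes.  For every metabolite and bin node
    the table reports per-genotype degree, summed mean_ic, and a
    presence flag, enabling presence/absence comparison across genotypes.
    """
    genotypes = sorted(edges["genotype"].unique())
    if len(genotypes) < 2:
        raise ValueError("genotype comparison needs edges from >= 2 genotypes")
    rows = []
    for node_type, id_col in (("metabolite", "metabolite_id"), ("bin", "bin_code")):
        for node in sorted(edges[id_col].unique()):
            sub = edges[edges[id_col] == node]
            row = {"node": node, "type": node_type}
            for gt in genotypes:
                gsub = sub[sub["genotype"] == gt]
                row[f"degree_{gt}"] = int(len(gsub))
                row[f"weight_{gt}"] = float(gsub["mean_ic"].sum())
                row[f"present_{gt}"] = bool(len(gsub))
            degrees = [row[f"degree_{gt}"] for gt in genotypes]
            row["degree_range"] = int(max(degrees) - min(degrees))
            rows.append(row)
    return pd.DataFrame(rows)


def write_graphml(g: nx.MultiGraph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_gml(g: nx.MultiGraph, path: str | Path) -> None:
    nx.write_gml(g, str(path))
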