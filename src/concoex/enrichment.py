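"""Over-representation profiles along ranked lists.

For an entity (a functional bin or a metabolite) occurring K times in a
ranked list of length N, position n of its profile is the one-sided
Fisher exact (hypergeometric tail) p-value of the 2x2 table

    [[n - k,            k    ],
     [(N - K) - (n - k), K - k]]

where k counts occurrences within the top n.  n runs from 1 to the top
10% (interaction tables) or top 25% (molecule tables) of the list, and a
Bonferroni factor equal to the number of profile positions is applied.
The profile is condensed into a weighted score x_k = w^T v with
v = -log10(adjusted p) and descending weights w = (n_top, ..., 1), so
enrichment near the very top of the list weighs most; per genotype the
x_k are ranked and normalized to scaled ranks rho_SC = rank/(count+1) in
(0, 1), lower = more over-represented.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TOP_FRACTIONS = {"interactions": 0.10, "molecules": 0.25}


def _membership(sorted_labels, entity: str) -> np.ndarray:
    """Boolean occurrence vector; elements may carry one label or a set."""
    out = np.zeros(len(sorted_labels), dtype=bool)
    for i, lab in enumerate(sorted_labels):
        if isinstance(lab, (set, frozenset, list, tuple)):
            out[i] = entity in lab
        else:
            out[i] = lab == entity
    return out


def occurrence_profile(is_entity: np.ndarray, top_fraction: float = 0.10) -> pd.DataFrame:
    """Per-position raw and Bonferroni-adjusted enrichment p-values.

    Vectorized over positions: p_raw(n) = P[X >= k(n)] for
    X ~ Hypergeom(N, K, n), identical to the one-sided Fisher exact test
    for enrichment.
    """
    is_entity = np.asarray(is_entity, dtype=bool)
    N = is_entity.size
    K = int(is_entity.sum())
    if K == 0:
        raise ValueError("entity does not occur in the list")
    n_top = int(np.floor(top_fraction * N))
    if n_top < 1:
        raise ValueError(f"top fraction {top_fraction} of N={N} leaves no positions")
    ns = np.arange(1, n_top + 1)
    ks = np.cumsum(is_entity)[:n_top]
    p_raw = stats.hypergeom.sf(ks - 1, N, K, ns)
    p_adj = np.minimum(p_raw * n_top, 1.0)
    return pd.DataFrame({"position_n": ns, "k": ks, "p_raw": p_raw, "p_adjusted": p_adj})


def fisher_profile(sorted_labels, entity: str, top_fraction: float = 0.10) -> pd.DataFrame:
    """Enrichment profile of one entity along a ranked label list."""
    return occurrence_profile(_membership(sorted_labels, entity), top_fraction)


def weighted_score(p_adjusted: np.ndarray) -> float:
    """x_k = sum_i (n_top - i + 1) * (-log10 p_adj_i), weights descending."""
    v = -np.log10(np.asarray(p_adjusted, dtype=float))
    n_top = v.size
    w = np.arange(n_top, 0, -1, dtype=float)
    return float(w @ v)


def profile_scores(sorted_labels, entities, top_fraction: float = 0.10) -> dict[str, float]:
    """Weighted over-representation score for each entity on one list."""
    return {e: weighted_score(fisher_profile(sorted_labels, e, top_fraction)["p_adjusted"])
            for e in entities}


def scaled_ranks(scores_by_genotype: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Scaled ranks rho_SC per genotype plus the cross-genotype mean.

    Entities are ranked per genotype by x_k descending (rank 1 = most
    over-represented; ties broken by entity label), then normalized to
    rank/(count+1).  The output is sorted ascending by mean rho_SC.
    """
    genotypes = sorted(scores_by_genotype)
    entities = sorted({e for g in genotypes for e in scores_by_genotype[g]})
    if len(entities) < 2:
        raise ValueError("scaled ranks need >= 2 entities")
    rows = {e: {"entity": e} for e in entities}
    for g in genotypes:
        scores = scores_by_genotype[g]
        order = sorted(entities, key=lambda e: (-scores.get(e, 0.0), e))
        count = len(order)
        for rank, e in enumerate(order, start=1):
            rows[e][f"x_k_{g}"] = scores.get(e, 0.0)
            rows[e][f"rho_sc_{g}"] = rank / (count + 1)
    df = pd.DataFrame(list(rows.values()))
    df["mean_rho_sc"] = df[[f"rho_sc_{g}" for g in genotypes]].mean(axis=1)
    return df.sort_values(["mean_rho_sc", "entity"], kind="mergesort").reset_index(drop=True)


def rank_list(table: pd.DataFrame, sort_key: str, direction: str = "desc",
              id_columns: list[str] | None = None) -> pd.DataFrame:
    """Deterministically sorted copy of a table (ties broken by ids)."""
    if sort_key not in table.columns:
        raise ValueError(f"unknown sort key {sort_key!r}")
    if direction not in ("asc", "desc"):
        raise ValueError(f"direction must be 'asc' or 'desc', got {direction!r}")
    if id_columns is None:
        id_columns = [c for c in ("metabolite_id", "phosphopeptide_id", "molecule_id")
                      if c in table.columns]
    ascending = [direction == "asc"] + [True] * len(id_columns)
    return (table.sort_values([sort_key] + id_columns, ascending=ascending,
                              kind="mergesort").reset_index(drop=True))


def truncate_bin(code: str, depth: int | None = None) -> str:
    """Truncate a dotted Mapman-style bin code to its leading levels.

    depth=1 keeps the top-level category (e.g. "34.19" -> "34"); None
    keeps the full code.
    """
    if depth is None:
        return code
    if depth < 1:
        raise ValueError("bin depth must be >= 1")
    return ".".join(str(code).split(".")[:depth])


def bin_label_sets(ids, annotation: pd.DataFrame, depth: int | None = None) -> list[frozenset]:
    """Per-element sets of (truncated) bin codes for a sequence of molecule ids."""
    mapping: dict[str, set[str]] = {}
    for mid, code in zip(annotation["molecule_id"], annotation["bin_code"]):
        mapping.setdefault(str(mid), set()).add(truncate_bin(code, depth))
    return [frozenset(mapping.get(str(i), {"unknown"})) for i in ids]
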