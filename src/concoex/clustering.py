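"""Pattern clustering and the between-genotype distance d_GT.

Standardized condition-mean patterns (4-vector z-scores over DR, DS, NR,
NS) are grouped per genotype, or pooled across genotypes, with k-means
(k-means++ seeding, 100 restarts, <= 300 iterations) or Ward hierarchical
clustering on Euclidean distance.  Flat molecules are kept out of the
partition and assigned the reserved cluster label "Z".

The between-genotype distance d_GT of a molecule combines (i) the
weighted fraction of clustering configurations and genotype pairs in
which the molecule's cluster labels differ, and (ii) the sum of pairwise
Euclidean distances between its patterns across genotypes, normalized by
the dataset maximum.  Both components lie in [0, 1]; equal weights by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score

from .preprocessing import ConditionSummary

logger = logging.getLogger(__name__)

FLAT_LABEL = "Z"
KMEANS_RESTARTS = 100
KMEANS_MAX_ITER = 300


@dataclass
class PatternVector:
    """Standardized condition-mean pattern of one molecule in one genotype."""

    molecule_id: str
    genotype: str
    z: np.ndarray  # 4-vector, order (DR, DS, NR, NS)
    is_flat: bool


def patterns_from_summaries(summaries: dict[str, ConditionSummary]) -> list[PatternVector]:
    """Pattern vectors from a {molecule_id: ConditionSummary} mapping.

    Molecules whose z-scores are undefined (all condition means equal)
    are treated as flat regardless of the Kruskal-Wallis verdict.
    """
    out = []
    for s in summaries.values():
        flat = s.is_flat or not np.all(np.isfinite(s.zscores))
        z = s.zscores if np.all(np.isfinite(s.zscores)) else np.zeros(4)
        out.append(PatternVector(s.molecule_id, s.genotype, z, flat))
    return out


@dataclass
class ClusterAssignment:
    """Labels of one clustering configuration; flat molecules carry "Z"."""

    config_id: str
    labels: dict[tuple[str, str], str]  # (molecule_id, genotype) -> label

    def label(self, molecule_id: str, genotype: str) -> str:
        return self.labels[(molecule_id, genotype)]


def _partition(z: np.ndarray, method: str, k: int, random_state: int) -> np.ndarray:
    if method == "kmeans":
        km = KMeans(n_clusters=k, init="k-means++", n_init=KMEANS_RESTARTS,
                    max_iter=KMEANS_MAX_ITER, random_state=random_state)
        return km.fit_predict(z)
    if method == "hierarchical":
        hc = AgglomerativeClustering(n_clusters=k, metric="euclidean", linkage="ward")
        return hc.fit_predict(z)
    raise ValueError(f"unknown clustering method {method!r}")


def cluster_patterns(patterns: list[PatternVector], method: str = "kmeans",
                     k: int = 13, random_state: int = 0) -> ClusterAssignment:
    """Partition non-flat patterns into k clusters; flat ones get "Z".

    Raises on k < 2 or k exceeding the number of non-flat patterns.
    """
    nonflat = [p for p in patterns if not p.is_flat]
    if k < 2 or k > len(nonflat):
        raise ValueError(f"k={k} out of range for {len(nonflat)} non-flat patterns")
    z = np.stack([p.z for p in nonflat])
    raw = _partition(z, method, k, random_state)
    config_id = f"{method}-k{k}"
    labels: dict[tuple[str, str], str] = {}
    for p, lab in zip(nonflat, raw):
        labels[(p.molecule_id, p.genotype)] = f"C{int(lab):02d}"
    for p in patterns:
        if p.is_flat:
            labels[(p.molecule_id, p.genotype)] = FLAT_LABEL
    return ClusterAssignment(config_id, labels)


def overlapping_clusters(patterns: list[PatternVector], method: str = "kmeans",
                         k: int = 13, random_state: int = 0) -> ClusterAssignment:
    """Single clustering over pooled (molecule, genotype) patterns.

    Each molecule receives one label per genotype, so label changes
    between genotypes become directly comparable.
    """
    genotypes = {p.genotype for p in patterns}
    if len(genotypes) < 2:
        raise ValueError("overlapping clustering needs patterns from >= 2 genotypes")
    assignment = cluster_patterns(patterns, method, k, random_state)
    assignment.config_id = f"overall-{assignment.config_id}"
    return assignment


def cluster_mean_pattern(assignment: ClusterAssignment,
                         patterns: list[PatternVector]) -> dict[str, np.ndarray]:
    """Arithmetic mean z-vector of each cluster's members."""
    groups: dict[str, list[np.ndarray]] = {}
    for p in patterns:
        lab = assignment.labels.get((p.molecule_id, p.genotype))
        if lab is None:
            continue
        groups.setdefault(lab, []).append(p.z)
    means = {}
    for lab in sorted(groups):
        if not groups[lab]:
            logger.warning("cluster %s empty; omitted", lab)
            continue
        means[lab] = np.mean(np.stack(groups[lab]), axis=0)
    return means


def silhouette_scan(patterns: list[PatternVector], k_range: range,
                    random_state: int = 0) -> tuple[int, dict[int, float]]:
    """Mean silhouette of k-means over a k-range; returns the argmax k."""
    nonflat = [p for p in patterns if not p.is_flat]
    z = np.stack([p.z for p in nonflat])
    scores = {}
    for k in k_range:
        if k < 2 or k >= len(nonflat):
            continue
        labels = _partition(z, "kmeans", k, random_state)
        scores[k] = float(silhouette_score(z, labels))
    if not scores:
        raise ValueError("no admissible k in range")
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


def default_ensemble(patterns: list[PatternVector], k: int = 13,
                     random_state: int = 0) -> list[ClusterAssignment]:
    """{hierarchical, k-means} x {k-2, k, k+2} label configurations."""
    nonflat = sum(not p.is_flat for p in patterns)
    ensemble = []
    for method in ("kmeans", "hierarchical"):
        for kk in (k - 2, k, k + 2):
            if 2 <= kk <= nonflat:
                ensemble.append(cluster_patterns(patterns, method, kk, random_state))
    if not ensemble:
        raise ValueError("no admissible ensemble configuration")
    return ensemble


@dataclass
class GenotypeDistance:
    molecule_id: str
    d_gt: float
    change_component: float
    euclid_component: float


def genotype_distances(patterns: list[PatternVector],
                       ensemble: list[ClusterAssignment],
                       w_change: float = 0.5,
                       w_euclid: float = 0.5) -> pd.DataFrame:
    """d_GT per molecule, sorted descending.

    The change component averages, over ensemble configurations and
    genotype pairs, the indicator of differing cluster labels; the
    Euclidean component is the molecule's summed pairwise pattern
    distance across genotypes divided by the dataset maximum.  Molecules
    flat in all genotypes (or present in < 2) get NaN.
    """
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    if not np.isclose(w_change + w_euclid, 1.0):
        raise ValueError("weights must sum to 1")
    by_mol: dict[str, dict[str, PatternVector]] = {}
    for p in patterns:
        by_mol.setdefault(p.molecule_id, {})[p.genotype] = p

    rows = []
    euclid_raw: dict[str, float] = {}
    for mid, per_gt in by_mol.items():
        gts = sorted(g for g, p in per_gt.items() if not p.is_flat)
        if len(gts) < 2:
            rows.append((mid, np.nan, np.nan))
            continue
        changes = []
        for asg in ensemble:
            for g1, g2 in combinations(gts, 2):
                changes.append(asg.label(mid, g1) != asg.label(mid, g2))
        change = float(np.mean(changes))
        esum = sum(float(np.linalg.norm(per_gt[g1].z - per_gt[g2].z))
                   for g1, g2 in combinations(gts, 2))
        euclid_raw[mid] = esum
        rows.append((mid, change, esum))

    emax = max(euclid_raw.values(), default=0.0)
    out = []
    for mid, change, esum in rows:
        if not np.isfinite(change):
            out.append((mid, np.nan, np.nan, np.nan))
            continue
        euclid = esum / emax if emax > 0 else 0.0
        out.append((mid, w_change * change + w_euclid * euclid, change, euclid))
    df = pd.DataFrame(out, columns=["molecule_id", "d_gt", "change_component",
                                    "euclid_component"])
    return df.sort_values("d_gt", ascending=False, kind="mergesort").reset_index(drop=True)


def assignment_frame(assignments: list[ClusterAssignment]) -> pd.DataFrame:
    rows = [(mid, gt, asg.config_id, lab)
            for asg in assignments
            for (mid, gt), lab in sorted(asg.labels.items())]
    return pd.DataFrame(rows, columns=["molecule_id", "genotype", "config_id", "cluster"])
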