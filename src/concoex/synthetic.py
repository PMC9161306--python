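"""Synthetic study datasets with planted pattern archetypes.

The generator emulates the study's dimensions — 42 metabolites and 3,330
phosphopeptides per genotype, 3 genotypes, 4 conditions (DR, DS, NR, NS)
with 4-6 biological replicates — with additive Gaussian noise on the
log2 scale and four planted pattern archetypes:

* ``tissue_dominant``  (-1, +1, -1, +1)   shoot vs root
* ``time_dominant``    (+1, +1, -1, -1)   day vs night
* ``interaction``      (+1, -1, -1, +1)   tissue x time interaction
* ``flat``             ( 0,  0,  0,  0)

Each molecule receives an archetype and a polarity sign; replicate
values are baseline + sign * effect_size * base_pattern + N(0, noise_sd).
Pair-level ground truth follows from the assignments: two non-flat
molecules sharing an archetype are *concordant* with equal polarity,
*discordant* with opposite polarity, and *independent* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import CONDITIONS
from .dataset import METABOLITE, PHOSPHOPEPTIDE, ReplicateSeries, StudyDataset

ARCHETYPES: dict[str, np.ndarray] = {
    "tissue_dominant": np.array([-1.0, 1.0, -1.0, 1.0]),
    "time_dominant": np.array([1.0, 1.0, -1.0, -1.0]),
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
    "flat": np.zeros(4),
}

#: archetype mixture proportions used when none are given
DEFAULT_MIXTURE = {"tissue_dominant": 0.3, "time_dominant": 0.3,
                   "interaction": 0.2, "flat": 0.2}
DEFAULT_EFFECT_SIZE = 2.0   # log2 units between opposing conditions' means
DEFAULT_NOISE_SD = 0.5      # log2 units, replicate-level Gaussian noise
DEFAULT_GENOTYPES = ("wild_type", "pgm", "sweet11_12")
DEFAULT_REPLICATES = (4, 6)
BASELINE_MEAN = 10.0        # log2 units, molecule-specific abundance offset
BASELINE_SD = 2.0


@dataclass
class SyntheticStudy:
    """Datasets plus the archetype assignment and pair-level ground truth."""

    datasets: dict[str, StudyDataset]
    assignments: pd.DataFrame  # molecule_id, molecule_class, archetype, sign
    flipped: dict[str, set[str]] = field(default_factory=dict)

    def truth(self, genotype: str | None = None) -> pd.DataFrame:
        """Pair truth table (metabolite_id, phosphopeptide_id, relation).

        Sign flips applied to a genotype reverse the polarity of the
        flipped molecules in that genotype's truth.
        """
        a = self.assignments
        flips = self.flipped.get(genotype, set()) if genotype else set()
        mets = a[a.molecule_class == METABOLITE]
        phos = a[a.molecule_class == PHOSPHOPEPTIDE]

        def eff_sign(row):
            return -row.sign if row.molecule_id in flips else row.sign

        m_ids = mets.molecule_id.to_numpy()
        p_ids = phos.molecule_id.to_numpy()
        m_arch = mets.archetype.to_numpy()
        p_arch = phos.archetype.to_numpy()
        m_sign = np.array([eff_sign(r) for r in mets.itertuples(index=False)])
        p_sign = np.array([eff_sign(r) for r in phos.itertuples(index=False)])

        nm, np_ = len(m_ids), len(p_ids)
        same_arch = (m_arch[:, None] == p_arch[None, :])
        nonflat = (m_arch[:, None] != "flat") & (p_arch[None, :] != "flat")
        same_sign = (m_sign[:, None] == p_sign[None, :])
        relation = np.where(same_arch & nonflat,
                            np.where(same_sign, "concordant", "discordant"),
                            "independent")
        return pd.DataFrame({
            "metabolite_id": np.repeat(m_ids, np_),
            "phosphopeptide_id": np.tile(p_ids, nm),
            "relation": relation.ravel(),
        })


def _validate_mixture(mixture: dict[str, float]) -> dict[str, float]:
    unknown = set(mixture) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes in mixture: {sorted(unknown)}")
    total = sum(mixture.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"mixture proportions must sum to 1, got {total}")
    if any(v < 0 for v in mixture.values()):
        raise ValueError("mixture proportions must be non-negative")
    return mixture


def generate_dataset(n_metabolites: int = 42,
                     n_phospho: int = 3330,
                     genotypes=DEFAULT_GENOTYPES,
                     replicates: tuple[int, int] = DEFAULT_REPLICATES,
                     mixture: dict[str, float] | None = None,
                     effect_size: float = DEFAULT_EFFECT_SIZE,
                     noise_sd: float = DEFAULT_NOISE_SD,
                     seed: int = 0,
                     flip: dict[str, list[str]] | None = None) -> SyntheticStudy:
    """Generate a fully specified synthetic study.

    Archetype and polarity assignments are shared across genotypes;
    ``flip`` optionally reverses the polarity of named molecules in a
    given genotype (used to plant between-genotype pattern changes).
    Deterministic under ``seed``.
    """
    mixture = _validate_mixture(dict(mixture) if mixture else dict(DEFAULT_MIXTURE))
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    names = list(mixture)
    probs = np.array([mixture[n] for n in names])

    def assign(prefix: str, cls: str, n: int) -> pd.DataFrame:
        arch = rng.choice(names, size=n, p=probs)
        sign = rng.choice([1, -1], size=n)
        sign = np.where(arch == "flat", 1, sign)  # polarity meaningless for flat
        return pd.DataFrame({
            "molecule_id": [f"{prefix}{i:04d}" for i in range(n)],
            "molecule_class": cls,
            "archetype": arch,
            "sign": sign,
        })

    assignments = pd.concat([assign("M", METABOLITE, n_metabolites),
                             assign("P", PHOSPHOPEPTIDE, n_phospho)],
                            ignore_index=True)
    baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=len(assignments))

    flip = {g: set(v) for g, v in (flip or {}).items()}
    unknown_gt = set(flip) - set(genotypes)
    if unknown_gt:
        raise ValueError(f"flip names unknown genotypes: {sorted(unknown_gt)}")

    datasets: dict[str, StudyDataset] = {}
    lo, hi = replicates
    for gt in genotypes:
        mets: dict[str, ReplicateSeries] = {}
        phos: dict[str, ReplicateSeries] = {}
        for (row, baseline) in zip(assignments.itertuples(index=False), baselines):
            sgn = -row.sign if row.molecule_id in flip.get(gt, set()) else row.sign
            pattern = baseline + sgn * effect_size * ARCHETYPES[row.archetype]
            values = {}
            for ci, cond in enumerate(CONDITIONS):
                n_rep = int(rng.integers(lo, hi + 1))
                values[cond] = rng.normal(pattern[ci], noise_sd, size=n_rep)
            series = ReplicateSeries(row.molecule_id, row.molecule_class, gt, values)
            (mets if row.molecule_class == METABOLITE else phos)[row.molecule_id] = series
        datasets[gt] = StudyDataset(gt, mets, phos, provenance={"seed": seed, "synthetic": True})
    return SyntheticStudy(datasets=datasets,
                          assignments=assignments[["molecule_id", "molecule_class",
                                                   "archetype", "sign"]],
                          flipped=flip)


def evaluate_recovery(predicted: pd.DataFrame, truth: pd.DataFrame,
                      relation: str = "concordant") -> dict[str, float]:
    """Precision and recall of predicted pairs against planted truth.

    ``predicted`` needs metabolite_id and phosphopeptide_id columns (e.g.
    the output of filter_connections).  Precision is NaN when nothing was
    predicted.  Raises if predicted pairs name molecules outside the
    truth universe.
    """
    truth_pairs = set(zip(truth["metabolite_id"], truth["phosphopeptide_id"]))
    pred_pairs = set(zip(predicted["metabolite_id"], predicted["phosphopeptide_id"]))
    if not pred_pairs <= truth_pairs:
        raise ValueError("predicted pairs contain molecules absent from the truth table")
    positives = set(zip(truth.loc[truth["relation"] == relation, "metabolite_id"],
                        truth.loc[truth["relation"] == relation, "phosphopeptide_id"]))
    tp = len(pred_pairs & positives)
    precision = tp / len(pred_pairs) if pred_pairs else float("nan")
    recall = tp / len(positives) if positives else float("nan")
    return {"precision": precision, "recall": recall,
            "n_predicted": len(pred_pairs), "n_true": len(positives)}
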