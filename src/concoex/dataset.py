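"""Replicate-level data containers and TSV/CSV ingestion.

Measurements are log2-scale metabolite concentrations or phosphopeptide
LFQ intensities, indexed by molecule x genotype x condition x replicate.
Two table dialects are read:

* long format with header
  ``molecule_id, molecule_class, genotype, condition, replicate, value``;
* wide format with one column per condition-replicate (``DR_1 ... NS_6``),
  blank cells meaning missing, plus ``molecule_id, molecule_class, genotype``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .conditions import CONDITIONS

logger = logging.getLogger(__name__)

METABOLITE = "metabolite"
PHOSPHOPEPTIDE = "phosphopeptide"
MOLECULE_CLASSES = (METABOLITE, PHOSPHOPEPTIDE)

LONG_COLUMNS = ["molecule_id", "molecule_class", "genotype", "condition", "replicate", "value"]


@dataclass
class ReplicateSeries:
    """All replicate measurements of one molecule in one genotype.

    ``values[c]`` holds the log2-scale replicate values of condition ``c``;
    ``outlier_mask[c]`` marks values excluded from downstream statistics.
    """

    molecule_id: str
    molecule_class: str
    genotype: str
    values: dict[str, np.ndarray]
    outlier_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.molecule_class not in MOLECULE_CLASSES:
            raise ValueError(f"molecule_class must be one of {MOLECULE_CLASSES}, got {self.molecule_class!r}")
        for c in self.values:
            self.values[c] = np.asarray(self.values[c], dtype=float)
            if not np.all(np.isfinite(self.values[c])):
                raise ValueError(f"non-finite value for molecule {self.molecule_id!r}, condition {c}")
        for c in self.values:
            if c not in self.outlier_mask:
                self.outlier_mask[c] = np.zeros(len(self.values[c]), dtype=bool)

    def kept(self, condition: str) -> np.ndarray:
        """Unmasked replicate values of one condition (empty if absent)."""
        if condition not in self.values:
            return np.empty(0)
        return self.values[condition][~self.outlier_mask[condition]]

    def n_kept(self, condition: str) -> int:
        return int(self.kept(condition).size)


@dataclass
class StudyDataset:
    """Replicate-level measurements of one genotype, split by molecule class."""

    genotype: str
    metabolites: dict[str, ReplicateSeries]
    phosphopeptides: dict[str, ReplicateSeries]
    provenance: dict = field(default_factory=dict)

    def block(self, molecule_class: str) -> dict[str, ReplicateSeries]:
        if molecule_class == METABOLITE:
            return self.metabolites
        if molecule_class == PHOSPHOPEPTIDE:
            return self.phosphopeptides
        raise ValueError(f"unknown molecule class {molecule_class!r}")

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for blk in (self.metabolites, self.phosphopeptides):
            for series in blk.values():
                for cond in CONDITIONS:
                    if cond not in series.values:
                        continue
                    for r, v in enumerate(series.values[cond], start=1):
                        rows.append((series.molecule_id, series.molecule_class,
                                     series.genotype, cond, r, v))
        return pd.DataFrame(rows, columns=LONG_COLUMNS)


def _series_from_long(df: pd.DataFrame) -> Iterable[ReplicateSeries]:
    for (mid, mclass, gt), grp in df.groupby(["molecule_id", "molecule_class", "genotype"], sort=True):
        values = {}
        for cond, sub in grp.groupby("condition"):
            sub = sub.sort_values("replicate")
            values[str(cond)] = sub["value"].to_numpy(dtype=float)
        yield ReplicateSeries(str(mid), str(mclass), str(gt), values)


def datasets_from_long_frame(df: pd.DataFrame) -> dict[str, StudyDataset]:
    """Build one StudyDataset per genotype from a long-format table."""
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long-format table lacks columns {missing}")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}")
    out: dict[str, StudyDataset] = {}
    for series in _series_from_long(df):
        ds = out.setdefault(series.genotype, StudyDataset(series.genotype, {}, {}))
        blk = ds.block(series.molecule_class)
        if series.molecule_id in blk:
            raise ValueError(f"duplicate molecule id {series.molecule_id!r} in class "
                             f"{series.molecule_class} of genotype {series.genotype}")
        blk[series.molecule_id] = series
    return out


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    id_cols = ["molecule_id", "molecule_class", "genotype"]
    value_cols = [c for c in df.columns if c not in id_cols]
    rows = []
    for _, row in df.iterrows():
        for col in value_cols:
            cond, _, rep = col.partition("_")
            if cond not in CONDITIONS or not rep.isdigit():
                raise ValueError(f"wide-format column {col!r} is not of the form COND_i")
            v = row[col]
            if pd.isna(v) or v == "":
                continue
            rows.append((row["molecule_id"], row["molecule_class"], row["genotype"],
                         cond, int(rep), float(v)))
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def read_measurements(path: str | Path) -> dict[str, StudyDataset]:
    """Read a measurement table (long or wide, TSV or CSV) into datasets."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "condition" not in df.columns:
        df = _wide_to_long(df)
    logger.info("read %d measurement rows from %s", len(df), path)
    return datasets_from_long_frame(df)


def write_measurements(datasets: Mapping[str, StudyDataset], path: str | Path) -> None:
    """Write datasets as a long-format TSV (round-trips at full precision)."""
    frames = [ds.to_long_frame() for ds in datasets.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.17g")
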