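"""Outlier removal, per-condition summaries, and flat-pattern classification.

For every molecule the replicate groups of the four conditions are reduced
to per-condition means and sample standard deviations, a between/within
variance ratio, a Kruskal-Wallis p-value and a standardized (z-score)
pattern over the four condition means.  A molecule whose Kruskal-Wallis
p-value exceeds ``alpha_flat`` shows no significant difference between any
two conditions and is classified *flat*.

Outliers are flagged per molecule per condition group with the
Iglewicz-Hoaglin modified z-score |0.6745 (x - median) / MAD| > 5, with the
mean-absolute-deviation fallback (scale 1.2533) when the MAD is zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import CONDITIONS
from .dataset import ReplicateSeries, StudyDataset

logger = logging.getLogger(__name__)

MODIFIED_ZSCORE_CONSTANT = 0.6745   # makes MAD consistent for normal data
MEANAD_SCALE = 1.2533               # fallback scale for the mean absolute deviation
DEFAULT_OUTLIER_THRESHOLD = 5.0
DEFAULT_ALPHA_FLAT = 0.05


def log2_transform(table: pd.DataFrame, value_column: str = "value") -> pd.DataFrame:
    """Replace every measurement by its base-2 logarithm.

    Raises
    ------
    ValueError
        If any value is non-positive; the message names the offending
        molecule and condition when those columns are present.
    """
    out = table.copy()
    values = out[value_column].to_numpy(dtype=float)
    bad = ~(values > 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        row = out.iloc[i]
        mol = row.get("molecule_id", "<unknown>")
        cond = row.get("condition", "<unknown>")
        raise ValueError(
            f"non-positive value {values[i]!r} for molecule {mol!r}, condition {cond!r}: "
            "cannot log2-transform"
        )
    out[value_column] = np.log2(values)
    return out


def flag_outliers(series, threshold: float = DEFAULT_OUTLIER_THRESHOLD) -> np.ndarray:
    """Boolean mask of outliers by the modified z-score.

    ``mask[i]`` is True iff ``|0.6745 (x_i - median) / MAD| > threshold``.
    When the MAD is zero the mean absolute deviation from the mean scaled
    by 1.2533 replaces it; when that is also zero nothing is flagged.
    Series with fewer than 3 values are never flagged (a warning is
    emitted: the statistic is meaningless there).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        warnings.warn(f"series of length {x.size} < 3: outlier flagging skipped", stacklevel=2)
        return np.zeros(x.size, dtype=bool)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad > 0:
        mz = MODIFIED_ZSCORE_CONSTANT * (x - med) / mad
    else:
        meanad = np.mean(np.abs(x - np.mean(x)))
        if meanad == 0:
            return np.zeros(x.size, dtype=bool)
        mz = (x - med) / (MEANAD_SCALE * meanad)
    return np.abs(mz) > threshold


def apply_outlier_masks(dataset: StudyDataset,
                        threshold: float = DEFAULT_OUTLIER_THRESHOLD) -> StudyDataset:
    """Flag outliers per molecule per condition group, in place."""
    n_flagged = 0
    for blk in (dataset.metabolites, dataset.phosphopeptides):
        for series in blk.values():
            for cond, vals in series.values.items():
                if vals.size < 3:
                    continue  # too few values; leave unflagged, as in flag_outliers
                mask = flag_outliers(vals, threshold)
                series.outlier_mask[cond] = mask
                n_flagged += int(mask.sum())
    logger.info("genotype %s: flagged %d outlying measurements", dataset.genotype, n_flagged)
    return dataset


@dataclass
class ConditionSummary:
    """Per-molecule condition-level summary statistics.

    Absent conditions (fewer than 2 usable replicates) carry NaN mean/sd
    and n = 0.  ``zscores`` standardize the four condition means with
    population (n) normalization; when all means are equal they are NaN.
    """

    molecule_id: str
    molecule_class: str
    genotype: str
    mean: dict[str, float]
    sd: dict[str, float]
    n: dict[str, int]
    variance_ratio: float
    kw_p: float
    is_flat: bool
    zscores: np.ndarray

    @property
    def present(self) -> list[str]:
        return [c for c in CONDITIONS if self.n.get(c, 0) >= 2]

    def mean_vector(self) -> np.ndarray:
        return np.array([self.mean.get(c, np.nan) for c in CONDITIONS])

    def sd_vector(self) -> np.ndarray:
        return np.array([self.sd.get(c, np.nan) for c in CONDITIONS])


def pattern_zscores(means: np.ndarray) -> np.ndarray:
    """Population-standardized pattern over condition means (NaN if all equal)."""
    m = np.asarray(means, dtype=float)
    ok = np.isfinite(m)
    centred = m - np.nanmean(m)
    spread = np.sqrt(np.nanmean(centred[ok] ** 2))
    if spread == 0:
        return np.full(m.shape, np.nan)
    return centred / spread


def summarize(series: ReplicateSeries, alpha_flat: float = DEFAULT_ALPHA_FLAT) -> ConditionSummary:
    """Summarize one molecule: condition means/sds, variance ratio, flatness.

    The variance ratio is the sample variance of the condition means over
    the pooled within-condition variance; the flatness verdict compares
    the Kruskal-Wallis p over the replicate groups with ``alpha_flat``.

    Raises
    ------
    ValueError
        If fewer than 2 conditions retain >= 2 unmasked replicates.
    """
    mean, sd, n = {}, {}, {}
    groups = []
    for cond in CONDITIONS:
        vals = series.kept(cond)
        if vals.size >= 2:
            mean[cond] = float(np.mean(vals))
            sd[cond] = float(np.std(vals, ddof=1))
            n[cond] = int(vals.size)
            groups.append(vals)
        else:
            mean[cond] = np.nan
            sd[cond] = np.nan
            n[cond] = 0
    if len(groups) < 2:
        raise ValueError(
            f"molecule {series.molecule_id!r} has fewer than 2 usable conditions; excluded"
        )

    means_arr = np.array([mean[c] for c in CONDITIONS])
    present_means = means_arr[np.isfinite(means_arr)]
    between = float(np.var(present_means, ddof=1))
    pooled_num = sum((g.size - 1) * np.var(g, ddof=1) for g in groups)
    pooled_den = sum(g.size - 1 for g in groups)
    within = pooled_num / pooled_den
    variance_ratio = between / within if within > 0 else (0.0 if between == 0 else np.inf)

    if all(np.ptp(g) == 0 for g in groups) and np.ptp(np.concatenate(groups)) == 0:
        kw_p = 1.0  # identical values everywhere: kruskal is undefined, pattern is flat
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kw_p = float(stats.kruskal(*groups).pvalue)

    return ConditionSummary(
        molecule_id=series.molecule_id,
        molecule_class=series.molecule_class,
        genotype=series.genotype,
        mean=mean, sd=sd, n=n,
        variance_ratio=float(variance_ratio),
        kw_p=kw_p,
        is_flat=bool(kw_p > alpha_flat),
        zscores=pattern_zscores(means_arr),
    )


def summarize_dataset(dataset: StudyDataset,
                      alpha_flat: float = DEFAULT_ALPHA_FLAT) -> dict[str, dict[str, ConditionSummary]]:
    """Summaries for every molecule, keyed by class then molecule id.

    Molecules with fewer than 2 usable conditions are excluded with a
    logged reason.
    """
    out: dict[str, dict[str, ConditionSummary]] = {"metabolite": {}, "phosphopeptide": {}}
    for cls, blk in (("metabolite", dataset.metabolites),
                     ("phosphopeptide", dataset.phosphopeptides)):
        for mid, series in blk.items():
            try:
                out[cls][mid] = summarize(series, alpha_flat)
            except ValueError as exc:
                logger.warning("excluding %s %s: %s", cls, mid, exc)
    return out


def summary_frame(summaries: dict[str, dict[str, ConditionSummary]]) -> pd.DataFrame:
    """Flatten summaries into the tabular output dialect."""
    rows = []
    for cls in ("metabolite", "phosphopeptide"):
        for s in summaries[cls].values():
            row = {"molecule_id": s.molecule_id, "molecule_class": cls, "genotype": s.genotype}
            for c in CONDITIONS:
                row[f"mean_{c}"] = s.mean[c]
                row[f"sd_{c}"] = s.sd[c]
                row[f"n_{c}"] = s.n[c]
            row["variance_ratio"] = s.variance_ratio
            row["kw_p"] = s.kw_p
            row["is_flat"] = s.is_flat
            for c, z in zip(CONDITIONS, s.zscores):
                row[f"z_{c}"] = z
            rows.append(row)
    return pd.DataFrame(rows)
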