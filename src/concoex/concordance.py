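"""The concordance index I_C and the Spearman co-filter.

For one molecule, each of the 12 ordered condition pairs ``(j | i)``
yields a *condition deviation*

    d_k = (mean_j - mean_i) / sd_i,

i.e. the difference of condition means expressed in multiples of the
reference condition's sample standard deviation.  Two molecules M and P
are compared by the *combined condition deviations*

    z_k(M, P) = sign(d_k(M)) sign(d_k(P)) min(|d_k(M)|, |d_k(P)|),

which are discretized into five magnitude classes

    |z| in [1,2) -> 0.25, [2,3) -> 1, [3,5) -> 1.5, [5,10) -> 1.75,
    [10, inf) -> 2        (sign preserved; |z| < 1 -> 0).

The negative and positive components sum to I_C(-) <= 0 and I_C(+) >= 0,
and I_C = I_C(-) + I_C(+) in [-24, 24].  Positive I_C marks concordant
patterns, negative I_C discordant ones.  A Spearman rank correlation over
replicate-paired measurements provides an independent significance filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import CONDITIONS, PAIR_INDEX, PAIR_LABELS
from .dataset import ReplicateSeries, StudyDataset
from .preprocessing import ConditionSummary

logger = logging.getLogger(__name__)

N_PAIRS = 12
IC_MAX = 24.0  # 12 components, each of magnitude at most 2

#: lower bounds of the deviation classes and their component magnitudes
CLASS_BOUNDS = np.array([1.0, 2.0, 3.0, 5.0, 10.0])
CLASS_COMPONENTS = np.array([0.25, 1.0, 1.5, 1.75, 2.0])


@dataclass
class DeviationVector:
    """Condition deviations of one molecule over the 12 ordered pairs.

    Pairs touching a condition absent from the data carry ``valid=False``
    and contribute neutrally downstream.
    """

    molecule_id: str
    d: np.ndarray          # shape (12,), units of reference-condition sd
    valid: np.ndarray      # shape (12,), bool

    pair_labels = PAIR_LABELS


def _deviations(means: np.ndarray, sds: np.ndarray, present: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized deviation computation.

    Parameters are arrays over molecules: means/sds shape (n, 4), present
    shape (n, 4) bool.  Returns (d, valid) of shape (n, 12).  A zero
    reference sd with a genuine mean difference yields a signed infinity
    sentinel (lands in the outermost deviation class).
    """
    n = means.shape[0]
    d = np.zeros((n, N_PAIRS))
    valid = np.zeros((n, N_PAIRS), dtype=bool)
    for k, (j, i) in enumerate(PAIR_INDEX):
        ok = present[:, i] & present[:, j]
        valid[:, k] = ok
        diff = means[:, j] - means[:, i]
        sd_i = sds[:, i]
        with np.errstate(divide="ignore", invalid="ignore"):
            dk = np.where(sd_i > 0, diff / np.where(sd_i > 0, sd_i, 1.0),
                          np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
        d[:, k] = np.where(ok, dk, 0.0)
    return d, valid


def condition_deviations(summary: ConditionSummary) -> DeviationVector:
    """All 12 condition deviations d_k of one molecule."""
    present = np.array([summary.n.get(c, 0) >= 2 for c in CONDITIONS])
    if not present.any():
        raise ValueError(f"molecule {summary.molecule_id!r}: no conditions present")
    d, valid = _deviations(summary.mean_vector()[None, :],
                           summary.sd_vector()[None, :],
                           present[None, :])
    return DeviationVector(summary.molecule_id, d[0], valid[0])


def combine_deviations(dM: DeviationVector, dP: DeviationVector) -> np.ndarray:
    """z_k = sign(d_k(M)) sign(d_k(P)) min(|d_k(M)|, |d_k(P)|); invalid -> 0."""
    both = dM.valid & dP.valid
    z = np.sign(dM.d) * np.sign(dP.d) * np.minimum(np.abs(dM.d), np.abs(dP.d))
    return np.where(both, np.nan_to_num(z, nan=0.0), 0.0)


def discretize_deviation(z):
    """Map a combined deviation to its concordance-index component.

    Odd and non-decreasing; accepts scalars or arrays.  Infinite
    sentinels land in the outermost class (component magnitude 2).
    """
    z = np.asarray(z, dtype=float)
    az = np.abs(z)
    idx = np.searchsorted(CLASS_BOUNDS, az, side="right")  # 0 = below class 1
    mag = np.where(idx > 0, CLASS_COMPONENTS[np.maximum(idx - 1, 0)], 0.0)
    out = np.sign(z) * mag
    return out if out.ndim else float(out)


@dataclass
class ConcordanceResult:
    """Concordance of one (metabolite, phosphopeptide) pair."""

    z: np.ndarray            # 12 combined deviations
    components: np.ndarray   # 12 discretized components, quarter-integers
    ic_neg: float
    ic_pos: float
    ic: float


def concordance_index(dM: DeviationVector, dP: DeviationVector) -> ConcordanceResult:
    """I_C of a pair from its two deviation vectors."""
    z = combine_deviations(dM, dP)
    comp = discretize_deviation(z)
    ic_neg = float(comp[comp < 0].sum())
    ic_pos = float(comp[comp > 0].sum())
    return ConcordanceResult(z=z, components=comp, ic_neg=ic_neg, ic_pos=ic_pos,
                             ic=ic_neg + ic_pos)


# ---------------------------------------------------------------------------
# Spearman co-filter


def _paired_values(M: ReplicateSeries, P: ReplicateSeries) -> tuple[np.ndarray, np.ndarray]:
    """Observations paired by (condition, replicate index).

    Within each condition the unmasked values of both molecules are
    paired in stored order and truncated to the smaller replicate count.
    """
    xs, ys = [], []
    for cond in CONDITIONS:
        a, b = M.kept(cond), P.kept(cond)
        m = min(a.size, b.size)
        if m:
            xs.append(a[:m])
            ys.append(b[:m])
    if not xs:
        return np.empty(0), np.empty(0)
    return np.concatenate(xs), np.concatenate(ys)


def spearman_pair(M: ReplicateSeries, P: ReplicateSeries) -> tuple[float, float, int]:
    """Spearman rho (midrank ties), two-sided t-approximation p, and n.

    Fewer than 4 paired points give p = 1 (and a logged warning), so the
    significance filter always removes such pairs.
    """
    x, y = _paired_values(M, P)
    n = int(x.size)
    if n < 4:
        logger.warning("pair (%s, %s): only %d paired observations; p set to 1",
                       M.molecule_id, P.molecule_id, n)
        return np.nan, 1.0, n
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    with np.errstate(invalid="ignore"):
        rho = float(np.corrcoef(rx, ry)[0, 1])
    if not np.isfinite(rho):
        return np.nan, 1.0, n
    p = _spearman_p(np.array([rho]), np.array([n]))[0]
    return rho, float(p), n


def _spearman_p(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p via the t-approximation on n paired points."""
    rho = np.clip(rho, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / (1.0 - rho ** 2))
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), 0.0)
    return np.where((n < 4) | ~np.isfinite(rho), 1.0, np.minimum(p, 1.0))


# ---------------------------------------------------------------------------
# Pair table


def _padded_value_matrix(series_list: list[ReplicateSeries], width: int) -> np.ndarray:
    """Kept values compacted per condition and NaN-padded to a fixed width."""
    out = np.full((len(series_list), 4 * width), np.nan)
    for r, s in enumerate(series_list):
        for ci, cond in enumerate(CONDITIONS):
            v = s.kept(cond)
            out[r, ci * width: ci * width + v.size] = v
    return out


def _vectorized_spearman(vm: np.ndarray, vp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """rho, p, n for the cartesian product of rows of vm and of vp.

    Matches spearman_pair: NaN-intersection of the compacted per-condition
    blocks (built with a shared per-condition width) is exactly pairing by
    replicate index with truncation to the smaller count.
    """
    nm, np_ = vm.shape[0], vp.shape[0]
    X = np.repeat(vm, np_, axis=0)
    Y = np.tile(vp, (nm, 1))
    mask = np.isfinite(X) & np.isfinite(Y)
    X = np.where(mask, X, np.nan)
    Y = np.where(mask, Y, np.nan)
    n = mask.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rx = stats.rankdata(X, axis=1, nan_policy="omit")
        ry = stats.rankdata(Y, axis=1, nan_policy="omit")
        mx = np.nanmean(rx, axis=1, keepdims=True)
        my = np.nanmean(ry, axis=1, keepdims=True)
        cov = np.nansum((rx - mx) * (ry - my), axis=1)
        vx = np.nansum((rx - mx) ** 2, axis=1)
        vy = np.nansum((ry - my) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = cov / np.sqrt(vx * vy)
    p = _spearman_p(rho, n)
    return rho, p, n


def concordance_table(metabolites: list[tuple[ConditionSummary, ReplicateSeries]],
                      phosphopeptides: list[tuple[ConditionSummary, ReplicateSeries]],
                      genotype: str,
                      include_components: bool = False) -> pd.DataFrame:
    """Full pair table: one row per (metabolite, phosphopeptide) pair.

    Both inputs pair a ConditionSummary with its ReplicateSeries.  Raises
    on duplicate molecule ids within a class.  The row count is exactly
    ``len(metabolites) * len(phosphopeptides)``.
    """
    if not metabolites or not phosphopeptides:
        raise ValueError("both molecule lists must be non-empty")
    for name, lst in (("metabolite", metabolites), ("phosphopeptide", phosphopeptides)):
        ids = [s.molecule_id for s, _ in lst]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate {name} ids: {dup}")

    def block_arrays(lst):
        means = np.stack([s.mean_vector() for s, _ in lst])
        sds = np.stack([s.sd_vector() for s, _ in lst])
        present = np.stack([[s.n.get(c, 0) >= 2 for c in CONDITIONS] for s, _ in lst])
        return _deviations(means, sds, present)

    dm, vm_valid = block_arrays(metabolites)
    dp, vp_valid = block_arrays(phosphopeptides)

    # combined deviations for all pairs: (nm, np, 12)
    both = vm_valid[:, None, :] & vp_valid[None, :, :]
    with np.errstate(invalid="ignore"):
        z = (np.sign(dm)[:, None, :] * np.sign(dp)[None, :, :]
             * np.minimum(np.abs(dm)[:, None, :], np.abs(dp)[None, :, :]))
    z = np.where(both, np.nan_to_num(z, nan=0.0), 0.0)
    comp = discretize_deviation(z)
    ic_pos = np.where(comp > 0, comp, 0.0).sum(axis=2)
    ic_neg = np.where(comp < 0, comp, 0.0).sum(axis=2)
    n_valid = both.sum(axis=2)

    all_series = [ser for _, ser in metabolites] + [ser for _, ser in phosphopeptides]
    width = max((s.n_kept(c) for s in all_series for c in CONDITIONS), default=0)
    rho, rho_p, n_rho = _vectorized_spearman(
        _padded_value_matrix([ser for _, ser in metabolites], width),
        _padded_value_matrix([ser for _, ser in phosphopeptides], width))

    nm, np_ = len(metabolites), len(phosphopeptides)
    met_ids = np.array([s.molecule_id for s, _ in metabolites])
    phos_ids = np.array([s.molecule_id for s, _ in phosphopeptides])
    flat_m = np.array([s.is_flat for s, _ in metabolites])
    flat_p = np.array([s.is_flat for s, _ in phosphopeptides])

    table = pd.DataFrame({
        "metabolite_id": np.repeat(met_ids, np_),
        "phosphopeptide_id": np.tile(phos_ids, nm),
        "genotype": genotype,
        "ic_neg": ic_neg.ravel(),
        "ic_pos": ic_pos.ravel(),
        "ic": (ic_neg + ic_pos).ravel(),
        "rho": rho,
        "rho_p": rho_p,
        "n_rho": n_rho,
        "flat_m": np.repeat(flat_m, np_),
        "flat_p": np.tile(flat_p, nm),
        "n_valid_components": n_valid.ravel(),
    })
    if include_components:
        flat_comp = comp.reshape(nm * np_, N_PAIRS)
        for k, lab in enumerate(PAIR_LABELS):
            table[f"comp_{lab}"] = flat_comp[:, k]
    return table


def pair_table(dataset: StudyDataset,
               summaries: dict[str, dict[str, ConditionSummary]],
               include_components: bool = False) -> pd.DataFrame:
    """Convenience wrapper pairing a dataset with its summaries."""
    mets = [(summaries["metabolite"][m], dataset.metabolites[m])
            for m in summaries["metabolite"]]
    phos = [(summaries["phosphopeptide"][p], dataset.phosphopeptides[p])
            for p in summaries["phosphopeptide"]]
    return concordance_table(mets, phos, dataset.genotype, include_components)
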