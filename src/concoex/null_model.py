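"""Moment-matched null simulation and false-positive calibration.

To judge how many high-concordance pairs arise by chance, molecules are
replaced by random surrogates matched to their experimental moments: a
three-parameter (location, shape, scale) Gamma distribution is fitted by
the method of moments to a molecule's four condition means, one surrogate
mean is drawn per condition, and replicate values are then drawn from a
normal around the drawn mean with the molecule's experimental
per-condition standard deviation.  Three simulation modes randomize the
metabolite block, the phosphopeptide block, or both.  The FPR curve
compares, threshold by threshold, the share of pairs exceeding a value in
experimental vs simulated pair tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import CONDITIONS
from .dataset import ReplicateSeries, StudyDataset
from .preprocessing import ConditionSummary

logger = logging.getLogger(__name__)

MIN_SKEWNESS = 0.05  # below this, fit the reflected values instead


class SimulationMode(str, Enum):
    randomize_metabolites = "randomize_metabolites"
    randomize_phosphopeptides = "randomize_phosphopeptides"
    randomize_both = "randomize_both"


@dataclass
class GammaFit:
    """Three-parameter Gamma fit of a molecule's condition means.

    ``mirrored`` marks fits to the reflected values (non-positive sample
    skewness); draws are reflected back.  ``constant`` is the degenerate
    zero-variance case, reproducing the constant value.
    """

    shape: float
    scale: float
    location: float
    mirrored: bool = False
    constant: float | None = None

    def draw(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.constant is not None:
            return np.full(size, self.constant)
        x = rng.gamma(self.shape, self.scale, size=size) + self.location
        return -x if self.mirrored else x


def fit_condition_mean_distribution(summary: ConditionSummary) -> GammaFit:
    """Method-of-moments Gamma fit to the available condition means.

    Matching mean, variance and skewness gives shape = 4 / g1^2,
    scale = sd |g1| / 2 and location = mean - shape * scale.  Skewness
    at or below 0.05 (incl. negative) triggers fitting the reflected
    values; zero variance yields a degenerate constant fit.
    """
    means = summary.mean_vector()
    means = means[np.isfinite(means)]
    if means.size < 3:
        raise ValueError(
            f"molecule {summary.molecule_id!r}: {means.size} < 3 usable condition means")
    m = float(np.mean(means))
    v = float(np.var(means, ddof=1))
    if v == 0:
        return GammaFit(shape=1.0, scale=1.0, location=0.0, constant=m)
    g1 = float(stats.skew(means, bias=True))
    mirrored = g1 <= MIN_SKEWNESS
    if mirrored:
        m, g1 = -m, float(stats.skew(-means, bias=True))
    g1 = max(g1, MIN_SKEWNESS)  # cap the shape when the sample is near-symmetric
    shape = 4.0 / g1 ** 2
    scale = float(np.sqrt(v) * g1 / 2.0)
    location = m - shape * scale
    return GammaFit(shape=shape, scale=scale, location=location, mirrored=mirrored)


def simulate_molecule(series: ReplicateSeries, summary: ConditionSummary,
                      fit: GammaFit, rng: np.random.Generator) -> ReplicateSeries:
    """Surrogate molecule: Gamma-drawn condition means, normal replicates.

    Replicate counts per condition equal the experimental (kept) counts;
    the normal spread is the experimental per-condition sample sd (a
    condition with zero sd reproduces identical replicates).
    """
    values: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        n_c = series.n_kept(cond)
        if n_c == 0:
            continue
        mu = float(fit.draw(1, rng)[0])
        sd = summary.sd.get(cond, np.nan)
        if not np.isfinite(sd):
            sd = 0.0
        values[cond] = rng.normal(mu, sd, size=n_c)
    return ReplicateSeries(series.molecule_id, series.molecule_class,
                           series.genotype, values)


@dataclass
class SimulationSpec:
    mode: SimulationMode
    seed: int

    def __post_init__(self) -> None:
        self.mode = SimulationMode(self.mode)


def simulate_dataset(dataset: StudyDataset,
                     summaries: dict[str, dict[str, ConditionSummary]],
                     spec: SimulationSpec) -> StudyDataset:
    """Replace the randomized class(es) by surrogates; pass others through."""
    rng = np.random.default_rng(spec.seed)
    mode = SimulationMode(spec.mode)

    def randomized(block: dict[str, ReplicateSeries], cls: str) -> dict[str, ReplicateSeries]:
        out = {}
        for mid, series in block.items():
            summary = summaries[cls].get(mid)
            if summary is None:
                continue
            fit = fit_condition_mean_distribution(summary)
            out[mid] = simulate_molecule(series, summary, fit, rng)
        return out

    mets = dataset.metabolites
    phos = dataset.phosphopeptides
    if mode in (SimulationMode.randomize_metabolites, SimulationMode.randomize_both):
        mets = randomized(dataset.metabolites, "metabolite")
    if mode in (SimulationMode.randomize_phosphopeptides, SimulationMode.randomize_both):
        phos = randomized(dataset.phosphopeptides, "phosphopeptide")
    sim = StudyDataset(dataset.genotype, mets, phos,
                       provenance={"mode": mode.value, "seed": spec.seed})
    logger.info("simulated dataset (%s, seed=%d) for genotype %s",
                mode.value, spec.seed, dataset.genotype)
    return sim


# ---------------------------------------------------------------------------
# False-positive-rate curves


def default_ic_grid() -> np.ndarray:
    """Quarter-integer thresholds spanning the theoretical I_C range."""
    return np.arange(-24.0, 24.0 + 0.25, 0.25)


def default_rho_grid() -> np.ndarray:
    """100 equal classes on [-1, 1]."""
    return np.linspace(-1.0, 1.0, 101)


@dataclass
class FprCurve:
    measure: str
    thresholds: np.ndarray
    share_experimental: np.ndarray
    share_simulated: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "measure": self.measure,
            "threshold": self.thresholds,
            "share_experimental": self.share_experimental,
            "share_simulated": self.share_simulated,
        })


def tail_share(values: np.ndarray, threshold: float) -> float:
    """Fraction of pairs at or beyond a threshold, on its sign branch.

    Positive (and zero) thresholds count values >= t, negative thresholds
    count values <= t, so each branch is monotone in |t|.
    """
    values = np.asarray(values, dtype=float)
    if threshold >= 0:
        return float(np.mean(values >= threshold))
    return float(np.mean(values <= threshold))


def fpr_curve(exp_pairs: pd.DataFrame, sim_pairs: pd.DataFrame,
              measure: str = "ic", thresholds: np.ndarray | None = None) -> FprCurve:
    """Experimental vs simulated tail shares over a threshold grid."""
    if exp_pairs.empty or sim_pairs.empty:
        raise ValueError("pair tables must be non-empty")
    if thresholds is None:
        thresholds = default_ic_grid() if measure == "ic" else default_rho_grid()
    ev = exp_pairs[measure].to_numpy(dtype=float)
    sv = sim_pairs[measure].to_numpy(dtype=float)
    if measure == "rho":
        ev = ev[np.isfinite(ev)]
        sv = sv[np.isfinite(sv)]
    share_exp = np.array([tail_share(ev, t) for t in thresholds])
    share_sim = np.array([tail_share(sv, t) for t in thresholds])
    return FprCurve(measure, np.asarray(thresholds, dtype=float), share_exp, share_sim)
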