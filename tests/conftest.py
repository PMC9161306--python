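import numpy as np
import pytest

from concoex.conditions import CONDITIONS
from concoex.dataset import ReplicateSeries
from concoex.preprocessing import ConditionSummary, pattern_zscores


def make_summary(molecule_id, means, sds, n=5, molecule_class="metabolite",
                 genotype="wild_type", is_flat=False, kw_p=0.01):
    """ConditionSummary straight from chosen condition means and sds."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    return ConditionSummary(
        molecule_id=molecule_id,
        molecule_class=molecule_class,
        genotype=genotype,
        mean={c: float(m) for c, m in zip(CONDITIONS, means)},
        sd={c: float(s) for c, s in zip(CONDITIONS, sds)},
        n={c: n for c in CONDITIONS},
        variance_ratio=1.0,
        kw_p=kw_p,
        is_flat=is_flat,
        zscores=pattern_zscores(means),
    )


def make_series(molecule_id, condition_values, molecule_class="metabolite",
                genotype="wild_type"):
    """ReplicateSeries from a {condition: list-of-values} mapping."""
    return ReplicateSeries(molecule_id, molecule_class, genotype,
                           {c: np.asarray(v, dtype=float)
                            for c, v in condition_values.items()})


@pytest.fixture(scope="session")
def small_study():
    """Small planted synthetic study shared across tests (seeded)."""
    from concoex.synthetic import generate_dataset
    return generate_dataset(n_metabolites=8, n_phospho=15,
                            genotypes=("wild_type", "pgm"), seed=11)
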