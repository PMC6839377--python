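import numpy as np
import pytest

import doseagree as da

#: criteria pairs where one is componentwise looser than the other
COMPARABLE_CRITERIA = [
    ((1.0, 1.0), (2.0, 2.0)),
    ((2.0, 2.0), (2.0, 3.0)),
    ((2.0, 2.0), (3.0, 2.0)),
    ((2.0, 3.0), (3.0, 3.0)),
    ((3.0, 2.0), (3.0, 3.0)),
    ((3.0, 3.0), (5.0, 3.0)),
]


def random_grid_pair(rng, ref_n=12, ev_n=2, ref_spacing=1.0):
    """A random fine reference grid with a coarse evaluated grid inside it."""
    ref = da.DoseGrid(rng.uniform(0.0, 2.0, (ref_n, ref_n)), (ref_spacing, ref_spacing))
    step = (ref_n - 1) * ref_spacing / (ev_n + 1)
    ev = da.DoseGrid(
        rng.uniform(0.0, 2.0, (ev_n, ev_n)),
        (step, step),
        (step / 2, step / 2),
    )
    return ref, ev


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic QA cohort: 100 plans, 12% with delivery errors."""
    return da.cohort_pairs(n=100, errored_fraction=0.12, seed=17)


@pytest.fixture(scope="session")
def gamma_sweep(default_cohort):
    """Global and local gamma %GP for the full criteria x LDT sweep."""
    return da.batch_indices(default_cohort, techniques=("gamma_global", "gamma_local"))


@pytest.fixture(scope="session")
def madd_sweep(default_cohort):
    """Box and quadrature MADD %GP for the full criteria x LDT sweep."""
    return da.batch_indices(default_cohort, techniques=("madd_b", "madd_gamma"))
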