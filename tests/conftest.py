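import random

import pytest

from ighrep.locus_model import build_toy_locus
from ighrep.repertoire_sim import JunctionParams, SelectionParams, simulate_cohort


@pytest.fixture(scope="session")
def locus30():
    """The default study locus: 30 V, 4 D, 4 J, 80% of V with a cRSS."""
    return build_toy_locus(30, 4, 4, 0.8, seed=1)


@pytest.fixture(scope="session")
def locus_small():
    """A small all-cRSS locus for replacement-focused tests."""
    return build_toy_locus(10, 2, 4, 1.0, seed=2)


@pytest.fixture(scope="session")
def wt_sim(locus30):
    """A modest wild-type cohort reused across read-level tests."""
    sp = SelectionParams.default_for(locus30)
    return simulate_cohort(locus30, JunctionParams(), sp, n_cells=3000, seed=7)


@pytest.fixture()
def rng():
    return random.Random(123)
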