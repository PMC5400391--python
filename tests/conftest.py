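import numpy as np
import pytest

from famturn import calibrate, fixtures, species_tree_from_newick

#: one seed for every stochastic test input in the suite
SUITE_SEED = 1


@pytest.fixture(scope="session")
def dipteran_tree():
    return fixtures.dipteran_tree()


@pytest.fixture(scope="session")
def abc_tree():
    """Minimal 3-taxon ultrametric tree used by the reconciliation examples."""
    return species_tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def desk_cfg():
    return calibrate.desk_profile(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def desk_grid(dipteran_tree, desk_cfg):
    """The desk-profile simulation grid (12 rates x 200 families), shared by
    the calibration tests; ~20 s to build once."""
    return calibrate.simulate_grid(dipteran_tree, desk_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
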