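import numpy as np
import pytest

from doubledrive.alleles import Params, STATE


@pytest.fixture(scope="session")
def space():
    return STATE


@pytest.fixture(scope="session")
def idealised():
    """No mutation, no resistance formation, no unintended costs."""
    return Params.idealised()


@pytest.fixture(scope="session")
def baseline_low():
    """Published baseline, low-EJR scenario."""
    return Params()


def make_male(space, *, y=0, x=0, a=(0, 0)):
    """Male genotype index from allele indices."""
    return space.male_index(x, y, int(space.a_pair_index[a[0], a[1]]))


def make_female(space, *, x=(0, 0), a=(0, 0)):
    return space.female_index(
        int(space.x_pair_index[x[0], x[1]]), int(space.a_pair_index[a[0], a[1]])
    )


@pytest.fixture(scope="session")
def intact_dd_male(space):
    """Release genotype: intact YLE, wildtype X, wildtype/intact-ASD."""
    return space.male_genotype(make_male(space, y=1, a=(0, 2)))
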