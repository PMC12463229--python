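import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from ekhom.diagram import LinkDiagram
from ekhom.fixtures import fixture_table, from_braid


@pytest.fixture(scope="session")
def table():
    return fixture_table()


@pytest.fixture(scope="session")
def trefoil(table):
    return table["trefoil_left"].diagram


@pytest.fixture(scope="session")
def hopf_neg(table):
    return table["hopf_negative"].diagram


@pytest.fixture(scope="session")
def example31(table):
    return table["example31"].diagram


@pytest.fixture(scope="session")
def seven_six(table):
    return table["seven_six"].diagram


def random_braid_diagram(rng: np.random.Generator, max_crossings: int = 6,
                         all_negative: bool = False) -> LinkDiagram:
    """A random small diagram: the trace closure of a random braid word.

    ``all_negative`` restricts to left-handed crossings, the case in which
    a smoothing tower is a genuine filtration.
    """
    n = int(rng.integers(1, max_crossings + 1))
    gens = (-1, -2) if all_negative else (-2, -1, 1, 2)
    word = [int(rng.choice(gens)) for _ in range(n)]
    return from_braid(word, strands=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240910)
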