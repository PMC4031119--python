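import numpy as np
import pytest

from lngcoding.features import CodingConfig
from lngcoding.graphs import LabeledGraph


@pytest.fixture
def cfg():
    """Default coding configuration (N=2, W=2, t=3, code length 30)."""
    return CodingConfig()


@pytest.fixture
def k2():
    g = LabeledGraph(0, ["A", "B"])
    g.add_edge(0, 1, "x")
    return g


@pytest.fixture
def p3():
    g = LabeledGraph(0, ["A", "B", "C"])
    g.add_edge(0, 1, "x")
    g.add_edge(1, 2, "y")
    return g


@pytest.fixture
def triangle():
    g = LabeledGraph(0, ["A", "B", "C"])
    g.add_edge(0, 1, "x")
    g.add_edge(1, 2, "x")
    g.add_edge(0, 2, "x")
    return g


@pytest.fixture
def star4():
    """Star with center 0 and three leaves."""
    g = LabeledGraph(0, ["C", "L", "L", "L"])
    for leaf in (1, 2, 3):
        g.add_edge(0, leaf, "s")
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
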