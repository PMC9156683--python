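import numpy as np
import pytest

from biogeofit.phylo import parse_newick
from biogeofit.regions import RegionMatrix
from biogeofit.stratigraphy import FossilRanges


@pytest.fixture
def balanced4():
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def crossed4():
    return parse_newick("((A,C),(B,D));")


@pytest.fixture
def ladder4():
    """Pectinate tree with leaves in strict age order under fads4."""
    return parse_newick("(((D,C),B),A);")


@pytest.fixture
def reversed_ladder4():
    return parse_newick("(((A,B),C),D);")


@pytest.fixture
def fads4():
    return FossilRanges.from_ages({"A": 10.0, "B": 8.0, "C": 5.0, "D": 2.0})


@pytest.fixture
def two_cherry_matrix():
    """Rows (1,0),(1,0),(0,1),(0,1): the exhaustive bHER fixture."""
    return RegionMatrix(
        ["A", "B", "C", "D"], ["r1", "r2"],
        np.array([[1, 0], [1, 0], [0, 1], [0, 1]]),
    )
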