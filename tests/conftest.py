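import numpy as np
import pandas as pd
import pytest

from introndyn import DatedTree, IntronMatrix
from introndyn.matrix import IntronPosition


@pytest.fixture
def six_tip_tree() -> DatedTree:
    return DatedTree.from_newick(
        "(((A:5.0,B:5.0)N4:5.0,(C:7.0,D:7.0)N5:3.0)N2:5.0,(E:9.0,F:9.0)N3:6.0)N1:20.0;"
    )


@pytest.fixture
def toy_matrix() -> IntronMatrix:
    """Two species, one with two paralogous copies, three positions."""
    positions = [
        IntronPosition("p1", 3, 0),
        IntronPosition("p2", 7, 1),
        IntronPosition("p3", 7, 2),
    ]
    copies = pd.DataFrame(
        {"species": ["A", "A", "B"]},
        index=pd.Index(["A|c1", "A|c2", "B|c1"], name="copy_id"),
    )
    states = np.array(
        [[1, 1, 0],
         [1, 0, -1],
         [0, 1, 1]],
        dtype=np.int8,
    )
    return IntronMatrix(copies, positions, states)


@pytest.fixture
def toy_tree() -> DatedTree:
    return DatedTree.from_newick("(A:10.0,B:10.0)R:85.0;")
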