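import numpy as np
import pytest

from paleokit.characters import CharacterMatrix, ContinuousColumn, DiscreteColumn
from paleokit.colorcode import ContactMatrix
from paleokit.trees import PhyloTree


@pytest.fixture
def quartet_tree() -> PhyloTree:
    """Unrooted ((A,B),(C,D)) over alphabetic taxa A..D."""
    return PhyloTree.from_newick("((A,B),(C,D));")


@pytest.fixture
def conflicting_quartet() -> PhyloTree:
    return PhyloTree.from_newick("((A,C),(B,D));")


def disc(*states) -> DiscreteColumn:
    """Shorthand: disc(0, 0, 1, None, {0,1}) -> DiscreteColumn."""
    cells = []
    for s in states:
        if s is None:
            cells.append(None)
        elif isinstance(s, (set, frozenset)):
            cells.append(frozenset(s))
        else:
            cells.append(frozenset({s}))
    return DiscreteColumn(tuple(cells))


def cont(*values) -> ContinuousColumn:
    """Shorthand: cont(0.1, (0.2, 0.4), None) -> ContinuousColumn."""
    cells = []
    for v in values:
        if v is None:
            cells.append(None)
        elif isinstance(v, tuple):
            cells.append((float(v[0]), float(v[1])))
        else:
            cells.append((float(v), float(v)))
    return ContinuousColumn(tuple(cells))


def path_graph(names) -> ContactMatrix:
    n = len(names)
    a = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = True
    return ContactMatrix(tuple(names), a)


def complete_graph(names) -> ContactMatrix:
    n = len(names)
    a = ~np.eye(n, dtype=bool)
    return ContactMatrix(tuple(names), a)
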