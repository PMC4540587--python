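import numpy as np
import pytest

from retroils import PresenceAbsenceMatrix, Tree, ladder_tree


@pytest.fixture
def t5():
    """The worked 5-taxon ladder ((((A,B),C),D),E)."""
    return Tree.from_structure((((("A", "B"), "C"), "D"), "E"))


@pytest.fixture
def make_matrix():
    """Build a matrix from {marker_id: {taxon: state}} over a taxon list."""

    def build(taxa, markers, meta=None):
        ids = list(markers)
        rows = [[str(markers[m].get(t, "?")) for t in taxa] for m in ids]
        return PresenceAbsenceMatrix(taxa, ids, np.array(rows, dtype=str), meta)

    return build


@pytest.fixture
def coalescent_ladder():
    def build(n_taxa=5, internode=0.5):
        return ladder_tree([f"t{i + 1}" for i in range(n_taxa)], internode=internode,
                           units="coalescent")

    return build


def random_tree_structure(rng, taxa):
    """Random rooted binary topology by sequential random attachment."""
    taxa = list(taxa)
    struct = (taxa[0], taxa[1])
    for name in taxa[2:]:
        edges = _nodes(struct)
        target = edges[rng.integers(len(edges))]
        struct = _attach(struct, target, name)
    return struct


def _nodes(struct):
    out = [struct]
    if isinstance(struct, tuple):
        for c in struct:
            out.extend(_nodes(c))
    return out


def _attach(struct, target, name):
    if struct is target:
        return (struct, name)
    if not isinstance(struct, tuple):
        return struct
    return tuple(_attach(c, target, name) for c in struct)
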