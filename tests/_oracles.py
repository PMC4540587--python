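"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's DP: the polymorphism-parsimony
oracle enumerates every candidate origin and every connected polymorphic
region explicitly and takes the minimum, which is feasible for trees with
up to ~8 leaves.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

from retroils.tree import Tree, _canonical


@lru_cache(maxsize=None)
def rooted_shapes(n_leaves: int) -> tuple:
    """All unlabeled rooted binary tree shapes with ``n_leaves`` leaves.

    Counts follow the Wedderburn-Etherington numbers: 1, 1, 2, 3, 6, 11, 23
    for 2..8 leaves.  Shapes are nested tuples with ``None`` placeholders.
    """
    if n_leaves == 1:
        return (None,)
    out = set()
    for i in range(1, n_leaves // 2 + 1):
        for left in rooted_shapes(i):
            for right in rooted_shapes(n_leaves - i):
                out.add(_canonical((left, right)))
    return tuple(sorted(out, key=repr))


def label_shape(shape, prefix: str = "L"):
    """Replace placeholder leaves with L0, L1, ... in traversal order."""
    counter = [0]

    def rec(node):
        if node is None:
            name = f"{prefix}{counter[0]}"
            counter[0] += 1
            return name
        return tuple(rec(c) for c in node)

    return rec(shape)


def connected_regions(tree: Tree):
    """All connected branch sets closed upward to a top node.

    A region is represented as (top node, frozenset of member nodes); each
    member's parent branch is polymorphic.  Every non-top member's parent is
    also a member (connectivity through the top).
    """
    regions_below: dict[int, list[frozenset]] = {}
    for v in tree.postorder:
        options: list[frozenset] = [frozenset([v])]
        for c in tree.children(v):
            extended = []
            for base in options:
                extended.append(base)  # child subtree not polymorphic
                for sub in regions_below[c]:
                    extended.append(base | sub)
            options = extended
        regions_below[v] = options
    out = []
    for v in tree.postorder:
        for s in regions_below[v]:
            out.append((v, s))
    return out


def oracle_min_retained(tree: Tree) -> np.ndarray:
    """Minimal retained-P count for every non-empty tip pattern.

    Returns an array indexed by the presence bitmask (tip bit order =
    ``tree.taxa``); entry 0 (all absent) is 0.  For each pattern the
    minimum is taken over a direct 0→1 origin (iff the presence set equals
    some branch's tip set, 0 retained) and every connected polymorphic
    region (|region| retained) whose hanging subtrees are each pure in the
    pattern and whose top subtends all presence tips.
    """
    n = tree.n_leaves
    patterns = np.arange(2 ** n, dtype=np.int64)
    best = np.full(2 ** n, np.iinfo(np.int64).max, dtype=np.int64)
    best[0] = 0
    # direct origins
    for v in tree.postorder:
        best[tree.tipmask(v)] = 0
    # polymorphic regions
    for top, members in connected_regions(tree):
        tm_top = tree.tipmask(top)
        hanging = [
            tree.tipmask(c)
            for m in members
            for c in tree.children(m)
            if c not in members
        ]
        ok = (patterns & ~tm_top) == 0
        ok &= patterns != 0
        for h in hanging:
            sub = patterns & h
            ok &= (sub == 0) | (sub == h)
        cost = len(members)
        best = np.where(ok & (cost < best), cost, best)
    return best


def all_binary_patterns(tree: Tree):
    """Yield (bitmask, pattern dict over {'0','1'}) for every tip assignment."""
    taxa = tree.taxa
    for mask in range(2 ** len(taxa)):
        yield mask, {t: ("1" if (mask >> k) & 1 else "0") for k, t in enumerate(taxa)}


def brute_force_question_resolution(tree: Tree, pattern: dict, no_missing_engine):
    """Best (min retained) over all explicit resolutions of '?' entries."""
    unknown = [t for t, s in pattern.items() if s == "?"]
    fixed = {t: s for t, s in pattern.items() if s != "?"}
    best = None
    for combo in product("01", repeat=len(unknown)):
        full = dict(fixed, **dict(zip(unknown, combo)))
        if all(v == "0" for v in full.values()):
            cost = 0
        else:
            cost = no_missing_engine(tree, full)
        if best is None or cost < best:
            best = cost
    return best
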