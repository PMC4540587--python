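"""Polymorphism parsimony for binary presence/absence characters on rooted trees.

The model is Dollo-like: an insertion arises exactly once (0 → 1 or 0 → P on
one branch, the *origin*), and conflict between a presence/absence pattern
and the tree is explained by retention of the insertion as a transient
polymorphism (state P) along a connected set of branches below the origin,
with each branch leaving the polymorphic region fixing one allele (P → 1 or
P → 0).  No precise excision and no independent second insertion are
allowed — the standard assumption for retrotransposon markers.

For a character with at least one presence tip, the minimal-polymorphism
mapping is unique once ties are broken:

* the origin sits on the branch above the MRCA of all presence tips (the
  lowest feasible branch);
* below the origin a branch is P iff its subtended tips (after resolution of
  ``?``) contain both states, 1 iff all are present, 0 iff all are absent;
* ``?`` tips are resolved by dynamic programming to minimize the number of
  retained-P branches, resolving to 0 (absence) on ties.

Two step-counting conventions are exposed: ``"fixations"`` counts allele
fixation events (transitions to 1 plus transitions to 0), the quantity that
measures how many lineages sorted independently; ``"retentions"`` counts
1 + the number of polymorphism-retaining branches, the convention of classic
polymorphism-parsimony programs.  On strictly bifurcating trees the two
coincide; on polytomies they differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .tree import Tree, TreeError
from .matrix_io import PresenceAbsenceMatrix, ABSENT, PRESENT, MISSING

CONVENTIONS = ("fixations", "retentions")

_INF = float("inf")

#: per-branch states in a mapping
STATE_ABSENT, STATE_PRESENT, STATE_POLY = "0", "1", "P"


class MappingError(ValueError):
    """Pattern cannot be mapped (unknown taxon, no scored entries, ...)."""


@dataclass
class CharacterMapping:
    """Per-branch assignment of {0, 1, P} for one marker on one tree.

    ``origin`` is the node whose parent branch carries the unique 0→1 or 0→P
    transition (``None`` for all-absent patterns).  ``states[v]`` is the
    state of the branch above node ``v``.  ``resolutions`` records how each
    ``?`` tip was resolved.
    """

    marker_id: str | None
    origin: int | None
    states: dict[int, str]
    fixations_to_1: int
    fixations_to_0: int
    retained_p: int
    resolutions: dict[str, str] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        """True for all-absent patterns (no insertion on the tree)."""
        return self.origin is None

    @property
    def n_fixations(self) -> int:
        return self.fixations_to_1 + self.fixations_to_0

    @property
    def is_conflict_free(self) -> bool:
        """Single fixation, no retained polymorphism (ILS across ≤1 event)."""
        return (not self.is_empty) and self.n_fixations == 1 and self.retained_p == 0

    def steps(self, convention: str = "fixations") -> int:
        if convention == "fixations":
            return 0 if self.is_empty else self.n_fixations
        if convention == "retentions":
            return 0 if self.is_empty else 1 + self.retained_p
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")


def _pattern_masks(tree: Tree, pattern: Mapping[str, object]) -> tuple[int, int, list[str]]:
    """Split a pattern into (ones, zeros) bitmasks and the list of '?' taxa."""
    ones = zeros = 0
    unknown: list[str] = []
    if not pattern:
        raise MappingError("empty pattern")
    for name, raw in pattern.items():
        state = str(raw)
        bit = tree.leaf_bit(name)  # raises TreeError for unknown taxon
        if state == "1":
            ones |= bit
        elif state == "0":
            zeros |= bit
        elif state == "?":
            unknown.append(name)
        else:
            raise MappingError(f"bad state {raw!r} for taxon {name!r}")
    if ones == 0 and zeros == 0:
        raise MappingError("pattern has no scored (non-'?') entries")
    return ones, zeros, unknown


def map_character(
    tree: Tree, pattern: Mapping[str, object], marker_id: str | None = None
) -> CharacterMapping:
    """Minimal polymorphism-parsimony mapping of one binary character.

    ``pattern`` maps taxon name → state (``"1"``, ``"0"``, ``"?"``); taxa
    must be a subset of the tree's leaves.  Taxa absent from the pattern are
    treated as ``?``.  Returns the mapping minimizing the number of
    retained-P branches (ties in ``?`` resolution go to absence).
    """
    ones, zeros, unknown = _pattern_masks(tree, pattern)
    resolutions: dict[str, str] = {}
    # taxa not mentioned at all behave like '?'
    mentioned = {n for n in pattern}
    implicit_unknown = [n for n in tree.taxa if n not in mentioned]

    if ones == 0:
        for n in unknown + implicit_unknown:
            resolutions[n] = "0"
        return CharacterMapping(marker_id, None, {}, 0, 0, 0, resolutions)

    m = tree.mrca(ones)
    sub = tree.subtree_nodes(m)
    in_sub = set(sub)
    # '?' outside the presence MRCA subtree resolve to absence
    for n in unknown + implicit_unknown:
        if tree.leaf_node(n) not in in_sub:
            resolutions[n] = "0"

    # DP over subtree(m): cost = (#mixed-subtree nodes, #'?'→1 resolutions),
    # minimized lexicographically.  Node classes: 0 = pure absent,
    # 1 = pure present, 2 = mixed.
    cost: dict[int, list[tuple[float, float]]] = {}
    choice: dict[int, list[tuple[int, ...] | None]] = {}
    for v in sub:
        if tree.is_leaf(v):
            name = tree.label(v)
            bit = tree.tipmask(v)
            if bit & ones:
                c = [(_INF, _INF), (0.0, 0.0), (_INF, _INF)]
            elif bit & zeros:
                c = [(0.0, 0.0), (_INF, _INF), (_INF, _INF)]
            else:  # '?' tip
                c = [(0.0, 0.0), (0.0, 1.0), (_INF, _INF)]
            cost[v] = c
            choice[v] = [None, None, None]
        else:
            kids = tree.children(v)
            c0 = _tuple_sum(cost[k][0] for k in kids)
            c1 = _tuple_sum(cost[k][1] for k in kids)
            # mixed: children pick classes; need >=1 presence-bearing and
            # >=1 absence-bearing child.  Small DP over (has1, has0).
            best: dict[tuple[bool, bool], tuple[tuple[float, float], tuple[int, ...]]] = {
                (False, False): ((0.0, 0.0), ())
            }
            for k in kids:
                nxt: dict[tuple[bool, bool], tuple[tuple[float, float], tuple[int, ...]]] = {}
                for (h1, h0), (acc, picks) in best.items():
                    for cls in (0, 1, 2):
                        ck = cost[k][cls]
                        if ck[0] == _INF:
                            continue
                        key = (h1 or cls in (1, 2), h0 or cls in (0, 2))
                        cand = (acc[0] + ck[0], acc[1] + ck[1])
                        prev = nxt.get(key)
                        if prev is None or cand < prev[0]:
                            nxt[key] = (cand, picks + (cls,))
                best = nxt
            full = best.get((True, True))
            if full is None:
                cmix = (_INF, _INF)
                pick = None
            else:
                cmix = (full[0][0] + 1.0, full[0][1])
                pick = full[1]
            cost[v] = [c0, c1, cmix]
            choice[v] = [None, None, pick]

    top1, topm = cost[m][1], cost[m][2]
    top_cls = 1 if top1 <= topm else 2

    states: dict[int, str] = {}
    f1 = f0 = retained = 0

    def assign(v: int, cls: int) -> None:
        nonlocal f1, f0, retained
        if cls == 0:
            for u in tree.subtree_nodes(v):
                states[u] = STATE_ABSENT
                if tree.is_leaf(u) and not (tree.tipmask(u) & (ones | zeros)):
                    resolutions[tree.label(u)] = "0"
        elif cls == 1:
            for u in tree.subtree_nodes(v):
                states[u] = STATE_PRESENT
                if tree.is_leaf(u) and not (tree.tipmask(u) & (ones | zeros)):
                    resolutions[tree.label(u)] = "1"
        else:
            states[v] = STATE_POLY
            retained += 1
            for k, cls_k in zip(tree.children(v), choice[v][2]):
                assign(k, cls_k)
                if cls_k == 1:
                    f1 += 1
                elif cls_k == 0:
                    f0 += 1

    if top_cls == 1:
        assign(m, 1)
        f1 = 1  # direct 0 -> 1 origin
    else:
        assign(m, 2)

    return CharacterMapping(marker_id, m, states, f1, f0, retained, resolutions)


def _tuple_sum(tuples) -> tuple[float, float]:
    a = b = 0.0
    for t in tuples:
        a += t[0]
        b += t[1]
    return (a, b)


# -- tree scoring ----------------------------------------------------------


@dataclass
class TreeScore:
    """Parsimony score of a matrix on one tree under one step convention."""

    convention: str
    total_steps: int
    per_character_steps: np.ndarray
    n_incongruent: int
    n_conflict_free: int
    n_uninformative: int
    ci: float | None
    ri: float | None

    @property
    def n_characters(self) -> int:
        return int(self.per_character_steps.size)


def _classify_pattern_row(row: np.ndarray) -> str:
    scored = row != MISSING
    n_scored = int(scored.sum())
    n_present = int((row == PRESENT).sum())
    if n_scored == 0 or n_present == 0 or n_present == n_scored:
        return "uninformative"
    return "informative"


def score_tree(
    tree: Tree,
    matrix: PresenceAbsenceMatrix,
    convention: str = "fixations",
    mappings: Sequence[CharacterMapping] | None = None,
) -> TreeScore:
    """Score a presence/absence matrix on a rooted tree.

    Characters that are constant after ``?`` resolution (all-absent or
    all-present) are uninformative and contribute zero steps.  CI and RI are
    computed over informative characters only (per-character minimum 1 step;
    maximum = number of observed presence tips).
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    missing_taxa = [t for t in matrix.taxa if t not in set(tree.taxa)]
    if missing_taxa:
        raise MappingError(f"matrix taxa not on tree: {', '.join(missing_taxa[:5])}")

    steps = np.zeros(matrix.n_markers, dtype=int)
    n_incon = n_free = n_unin = 0
    g_sum = s_sum = m_sum = 0  # RI accumulators over informative characters
    for i in range(matrix.n_markers):
        row = matrix.states[i]
        if _classify_pattern_row(row) == "uninformative":
            n_unin += 1
            continue
        mp = mappings[i] if mappings is not None else map_character(
            tree, matrix.pattern(i), matrix.marker_ids[i]
        )
        s = mp.steps(convention)
        steps[i] = s
        if s > 1:
            n_incon += 1
        else:
            n_free += 1
        n_ones = int((row == PRESENT).sum())
        g_sum += n_ones
        s_sum += s
        m_sum += 1
    total = int(steps.sum())
    n_informative = matrix.n_markers - n_unin
    ci = (n_informative / total) if total > 0 else None
    ri = ((g_sum - s_sum) / (g_sum - m_sum)) if (g_sum - m_sum) > 0 else None
    return TreeScore(convention, total, steps, n_incon, n_free, n_unin, ci, ri)


def dollo_score(tree: Tree, matrix: PresenceAbsenceMatrix) -> TreeScore:
    """Plain Dollo scoring: one origin plus the minimal number of 1→0 losses.

    A comparison baseline: conflicts are explained by secondary losses
    instead of polymorphism retention.  ``?`` resolution minimizes losses,
    resolving to absence on ties.
    """
    missing_taxa = [t for t in matrix.taxa if t not in set(tree.taxa)]
    if missing_taxa:
        raise MappingError(f"matrix taxa not on tree: {', '.join(missing_taxa[:5])}")
    steps = np.zeros(matrix.n_markers, dtype=int)
    n_incon = n_free = n_unin = 0
    g_sum = s_sum = m_sum = 0
    for i in range(matrix.n_markers):
        row = matrix.states[i]
        if _classify_pattern_row(row) == "uninformative":
            n_unin += 1
            continue
        s = _dollo_steps(tree, matrix.pattern(i))
        steps[i] = s
        if s > 1:
            n_incon += 1
        else:
            n_free += 1
        n_ones = int((row == PRESENT).sum())
        g_sum += n_ones
        s_sum += s
        m_sum += 1
    total = int(steps.sum())
    n_informative = matrix.n_markers - n_unin
    ci = (n_informative / total) if total > 0 else None
    ri = ((g_sum - s_sum) / (g_sum - m_sum)) if (g_sum - m_sum) > 0 else None
    return TreeScore("dollo", total, steps, n_incon, n_free, n_unin, ci, ri)


def _dollo_steps(tree: Tree, pattern: Mapping[str, object]) -> int:
    ones, zeros, _ = _pattern_masks(tree, pattern)
    if ones == 0:
        return 0
    m = tree.mrca(ones)
    # c1[v]: min losses in subtree(v) with v labelled presence-bearing;
    # c0[v]: v's subtree entirely absent (0 losses inside; the loss is
    # charged on the edge into it).
    c1: dict[int, float] = {}
    c0: dict[int, float] = {}
    for v in tree.subtree_nodes(m):
        if tree.is_leaf(v):
            bit = tree.tipmask(v)
            if bit & ones:
                c1[v], c0[v] = 0.0, _INF
            elif bit & zeros:
                c1[v], c0[v] = _INF, 0.0
            else:
                c1[v], c0[v] = 0.0, 0.0
        else:
            kids = tree.children(v)
            c0[v] = sum(c0[k] for k in kids) if all(c0[k] < _INF for k in kids) else _INF
            # v labelled 1: each child either stays presence-bearing (c1) or
            # its whole subtree is lost (c0 + 1 for the loss on its stem);
            # at least one child must stay.
            total = sum(min(c1[k], c0[k] + 1.0) for k in kids)
            finite_stays = [k for k in kids if c1[k] < _INF]
            if total == _INF or not finite_stays:
                c1[v] = _INF
            elif any(c1[k] <= c0[k] + 1.0 for k in finite_stays):
                c1[v] = total
            else:
                c1[v] = total + min(c1[k] - (c0[k] + 1.0) for k in finite_stays)
    return int(1 + c1[m])


# -- heuristic tree search -------------------------------------------------


def search_mpre(
    matrix: PresenceAbsenceMatrix,
    n_jumbles: int = 7,
    seed: int = 11111,
    convention: str = "fixations",
) -> tuple[Tree, TreeScore]:
    """Heuristic search for the most-parsimonious presence/absence tree.

    One stepwise-addition start tree per jumbled taxon input order, each
    refined by nearest-neighbor-interchange hill climbing on total steps;
    the best-scoring result is returned.  Deterministic given ``seed``.
    """
    if matrix.n_taxa < 3:
        raise MappingError("tree search needs at least 3 taxa")
    if n_jumbles < 1:
        raise ValueError("n_jumbles must be >= 1")
    rng = np.random.default_rng(seed)
    best_struct = None
    best_total = None
    for _ in range(n_jumbles):
        order = [matrix.taxa[i] for i in rng.permutation(matrix.n_taxa)]
        struct = _stepwise_addition(matrix, order, convention)
        struct, total = _nni_hill_climb(matrix, struct, convention)
        if best_total is None or total < best_total:
            best_total, best_struct = total, struct
    tree = Tree.from_structure(best_struct)
    return tree, score_tree(tree, matrix, convention)


def _total_steps(matrix: PresenceAbsenceMatrix, struct, convention: str) -> int:
    """Total steps of the matrix restricted to the taxa on a (partial) tree."""
    tree = Tree.from_structure(struct)
    on_tree = [j for j, t in enumerate(matrix.taxa) if t in set(tree.taxa)]
    names = [matrix.taxa[j] for j in on_tree]
    total = 0
    for i in range(matrix.n_markers):
        row = matrix.states[i, on_tree]
        scored = row != MISSING
        n_present = int((row == PRESENT).sum())
        if n_present == 0 or n_present == int(scored.sum()):
            continue  # uninformative on this leaf subset
        pattern = {
            n: ("1" if s == PRESENT else "0" if s == ABSENT else "?")
            for n, s in zip(names, row)
        }
        total += map_character(tree, pattern).steps(convention)
    return total


def _attachments(struct, leaf: str):
    """All structures obtained by attaching ``leaf`` on each branch.

    Every node (tip or internal, root included) has a stem branch, so a
    rooted tree with n leaves offers 2n - 1 attachment positions.
    """

    def rec(node):
        variants = [(node, leaf)]  # attach on the stem of this node
        if isinstance(node, tuple):
            for i, child in enumerate(node):
                for alt in rec(child):
                    variants.append(tuple(alt if j == i else c for j, c in enumerate(node)))
        return variants

    return rec(struct)


def _stepwise_addition(matrix: PresenceAbsenceMatrix, order: Sequence[str], convention: str):
    struct = (order[0], order[1])
    for leaf in order[2:]:
        candidates = _attachments(struct, leaf)
        scored = [(_total_steps(matrix, c, convention), k) for k, c in enumerate(candidates)]
        _, k = min(scored)
        struct = candidates[k]
    return struct


def _nni_neighbors(struct):
    """All structures one rooted NNI away (swap a grandchild with its uncle)."""
    results = []

    def rec(node, path):
        if not isinstance(node, tuple):
            return
        for i, child in enumerate(node):
            if isinstance(child, tuple):
                sibs = [c for j, c in enumerate(node) if j != i]
                for gi in range(len(child)):
                    for si, sib in enumerate(sibs):
                        new_child = tuple(sib if g == gi else gc for g, gc in enumerate(child))
                        moved = child[gi]
                        new_sibs = list(sibs)
                        new_sibs[si] = moved
                        new_node_children = []
                        si_seen = 0
                        for j, c in enumerate(node):
                            if j == i:
                                new_node_children.append(new_child)
                            else:
                                new_node_children.append(new_sibs[si_seen])
                                si_seen += 1
                        results.append(_rebuild(path, tuple(new_node_children)))
            rec(child, path + [(node, i)])

    rec(struct, [])
    return results


def _rebuild(path, new_node):
    for parent, idx in reversed(path):
        new_node = tuple(new_node if j == idx else c for j, c in enumerate(parent))
    return new_node


def _nni_hill_climb(matrix: PresenceAbsenceMatrix, struct, convention: str):
    current = struct
    current_score = _total_steps(matrix, current, convention)
    improved = True
    while improved:
        improved = False
        for neigh in _nni_neighbors(current):
            s = _total_steps(matrix, neigh, convention)
            if s < current_score:
                current, current_score = neigh, s
                improved = True
                break
    return current, current_score
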