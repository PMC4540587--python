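"""Rooted phylogenies used as mapping and simulation substrates.

A :class:`Tree` is a rooted phylogeny with uniquely labelled leaves and
optional nonnegative branch lengths in million years (``"my"``), coalescent
units (``"coalescent"``), or no stated units (``None``).  Presence/absence
mapping is polarity-dependent (0 = ancestral absence), so every tree here is
rooted; a Newick string whose outermost node is a multifurcation is treated
as unrooted and rejected unless explicitly allowed.

Newick reading and writing are delegated to dendropy; the class itself keeps
flat parent/children arrays plus per-node tip bitmasks, which is what the
parsimony engine operates on.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import dendropy


class TreeError(ValueError):
    """Malformed tree input (parse failure, duplicate leaves, bad lengths)."""


_UNITS = ("my", "coalescent", None)


class Tree:
    """Rooted tree over uniquely named leaves.

    Nodes are integer ids ``0 .. n_nodes-1`` in postorder (children before
    parents, root last).  The *branch* of a node is the edge above it; the
    root's branch is the root stem.
    """

    __slots__ = (
        "_parent",
        "_children",
        "_length",
        "_label",
        "units",
        "_postorder",
        "_leaves",
        "_taxa",
        "_leaf_bit",
        "_tipmask",
        "_node_of_leaf",
    )

    def __init__(
        self,
        parent: Sequence[int | None],
        children: Sequence[Sequence[int]],
        length: Sequence[float | None],
        label: Sequence[str | None],
        units: str | None = None,
    ) -> None:
        if units not in _UNITS:
            raise TreeError(f"unknown branch-length units {units!r}")
        self._parent = list(parent)
        self._children = [list(c) for c in children]
        self._length = list(length)
        self._label = list(label)
        self.units = units
        self._index()
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        newick: str,
        units: str | None = None,
        allow_basal_polytomy: bool = False,
    ) -> "Tree":
        try:
            dt = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"could not parse Newick: {exc}") from exc
        return cls.from_dendropy(dt, units=units, allow_basal_polytomy=allow_basal_polytomy)

    @classmethod
    def from_dendropy(
        cls,
        dtree: "dendropy.Tree",
        units: str | None = None,
        allow_basal_polytomy: bool = False,
    ) -> "Tree":
        parent: list[int | None] = []
        children: list[list[int]] = []
        length: list[float | None] = []
        label: list[str | None] = []
        index: dict[int, int] = {}
        for nd in dtree.postorder_node_iter():
            i = len(parent)
            index[id(nd)] = i
            parent.append(None)
            children.append([index[id(c)] for c in nd.child_nodes()])
            for c in nd.child_nodes():
                parent[index[id(c)]] = i
            length.append(nd.edge.length)
            if nd.is_leaf():
                name = None
                if nd.taxon is not None:
                    name = nd.taxon.label
                elif nd.label:
                    name = nd.label
                if name is None or not str(name).strip():
                    raise TreeError("leaf without a label")
                label.append(str(name).strip())
            else:
                label.append(None)
        tree = cls(parent, children, length, label, units=units)
        root_degree = len(tree.children(tree.root))
        if root_degree > 2 and not allow_basal_polytomy:
            raise TreeError(
                f"basal multifurcation of degree {root_degree}: tree appears "
                "unrooted; reroot it (or pass allow_basal_polytomy=True)"
            )
        return tree

    @classmethod
    def from_structure(
        cls,
        structure,
        lengths: Mapping[str, float] | None = None,
        units: str | None = None,
    ) -> "Tree":
        """Build a tree from nested tuples of leaf names.

        ``("E", (("A", "B"), "C"))`` gives the rooted shape ((A,B),C) with E
        as the first root child.  ``lengths`` optionally assigns leaf branch
        lengths by name (internal branches are left unset).
        """
        parent: list[int | None] = []
        children: list[list[int]] = []
        length: list[float | None] = []
        label: list[str | None] = []

        def build(node) -> int:
            if isinstance(node, (tuple, list)):
                kids = [build(k) for k in node]
                i = len(parent)
                parent.append(None)
                children.append(kids)
                for k in kids:
                    parent[k] = i
                length.append(None)
                label.append(None)
                return i
            i = len(parent)
            parent.append(None)
            children.append([])
            length.append(None if lengths is None else lengths.get(str(node)))
            label.append(str(node))
            return i

        build(structure)
        return cls(parent, children, length, label, units=units)

    @classmethod
    def read(cls, path, units: str | None = None, allow_basal_polytomy: bool = False) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), units=units, allow_basal_polytomy=allow_basal_polytomy)

    # -- indexing / validation --------------------------------------------

    def _index(self) -> None:
        roots = [i for i, p in enumerate(self._parent) if p is None]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        order: list[int] = []
        seen: set[int] = set()

        def walk(v: int) -> None:
            if v in seen:
                raise TreeError("cycle detected in tree")
            seen.add(v)
            for c in self._children[v]:
                walk(c)
            order.append(v)

        walk(roots[0])
        if len(order) != len(self._parent):
            raise TreeError("disconnected nodes in tree")
        self._postorder = order
        self._leaves = [v for v in order if not self._children[v]]
        self._taxa = [self._label[v] for v in self._leaves]
        self._leaf_bit = {name: 1 << k for k, name in enumerate(self._taxa)}
        self._node_of_leaf = {self._label[v]: v for v in self._leaves}
        tipmask = [0] * len(self._parent)
        for v in order:
            if not self._children[v]:
                tipmask[v] = self._leaf_bit[self._label[v]]
            else:
                m = 0
                for c in self._children[v]:
                    m |= tipmask[c]
                tipmask[v] = m
        self._tipmask = tipmask

    def _validate(self) -> None:
        names = [n for n in self._taxa]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf label(s): {', '.join(dupes)}")
        if any(not n for n in names):
            raise TreeError("empty leaf label")
        if self.units is not None:
            for v, ln in enumerate(self._length):
                if ln is not None and ln < 0:
                    raise TreeError(f"negative branch length on node {v}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._parent)

    @property
    def root(self) -> int:
        return self._postorder[-1]

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def taxa(self) -> list[str]:
        """Leaf names in postorder appearance."""
        return list(self._taxa)

    @property
    def leaves(self) -> list[int]:
        return list(self._leaves)

    @property
    def postorder(self) -> list[int]:
        return list(self._postorder)

    def children(self, v: int) -> list[int]:
        return list(self._children[v])

    def parent(self, v: int) -> int | None:
        return self._parent[v]

    def is_leaf(self, v: int) -> bool:
        return not self._children[v]

    def label(self, v: int) -> str | None:
        return self._label[v]

    def length(self, v: int) -> float | None:
        """Length of the branch above node ``v`` (None for the root stem if unset)."""
        return self._length[v]

    def tipmask(self, v: int) -> int:
        return self._tipmask[v]

    def leaf_bit(self, name: str) -> int:
        try:
            return self._leaf_bit[name]
        except KeyError:
            raise TreeError(f"taxon {name!r} not on tree") from None

    def leaf_node(self, name: str) -> int:
        try:
            return self._node_of_leaf[name]
        except KeyError:
            raise TreeError(f"taxon {name!r} not on tree") from None

    def mask_of(self, names: Iterable[str]) -> int:
        m = 0
        for n in names:
            m |= self.leaf_bit(n)
        return m

    def names_of(self, mask: int) -> list[str]:
        return [n for n in self._taxa if self._leaf_bit[n] & mask]

    def mrca(self, mask: int) -> int:
        """Most recent common ancestor of the leaves in ``mask`` (a bitmask)."""
        if mask == 0:
            raise TreeError("mrca of empty leaf set")
        for v in self._postorder:  # postorder -> smallest superset first
            if mask & ~self._tipmask[v] == 0:
                return v
        raise TreeError("mask references leaves not on this tree")

    def clade(self, v: int) -> frozenset[str]:
        return frozenset(self.names_of(self._tipmask[v]))

    def clades(self) -> set[frozenset[str]]:
        """Tip sets of all branches (leaves included)."""
        return {self.clade(v) for v in self._postorder}

    def subtree_nodes(self, v: int) -> list[int]:
        """Nodes of the subtree rooted at ``v``, in postorder."""
        out: list[int] = []

        def walk(u: int) -> None:
            for c in self._children[u]:
                walk(c)
            out.append(u)

        walk(v)
        return out

    # -- ages (for coalescent simulation) ----------------------------------

    def node_ages(self, rtol: float = 1e-6) -> list[float]:
        """Ages (time before present) of all nodes, requiring ultrametricity.

        Leaf ages are 0; an internal node's age must agree across its
        children within ``rtol`` of tree depth.  Branch lengths must be set
        for all non-root branches.
        """
        ages = [0.0] * self.n_nodes
        for v in self._postorder:
            if self.is_leaf(v):
                continue
            cand = []
            for c in self._children[v]:
                ln = self._length[c]
                if ln is None:
                    raise TreeError("node_ages requires branch lengths on all non-root branches")
                cand.append(ages[c] + ln)
            depth = max(cand)
            if depth > 0 and (max(cand) - min(cand)) > rtol * max(depth, 1.0):
                raise TreeError("tree is not ultrametric; cannot assign node ages")
            ages[v] = depth
        return ages

    # -- structure / newick ------------------------------------------------

    def structure(self, v: int | None = None):
        """Nested-tuple topology (leaf names at the tips)."""
        if v is None:
            v = self.root
        if self.is_leaf(v):
            return self._label[v]
        return tuple(self.structure(c) for c in self._children[v])

    def to_newick(self, include_lengths: bool = True) -> str:
        def quote(name: str) -> str:
            if any(ch in name for ch in " (),:;[]'"):
                return "'" + name.replace("'", "''") + "'"
            return name

        def fmt(v: int) -> str:
            if self.is_leaf(v):
                s = quote(self._label[v])
            else:
                s = "(" + ",".join(fmt(c) for c in self._children[v]) + ")"
            ln = self._length[v]
            if include_lengths and ln is not None and self._parent[v] is not None:
                s += f":{ln!r}"
            return s

        return fmt(self.root) + ";"

    def write(self, path, include_lengths: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(include_lengths=include_lengths) + "\n")

    # -- misc --------------------------------------------------------------

    def branch_name(self, v: int) -> str:
        """Stable human-readable branch identifier (sorted tip names)."""
        if self.is_leaf(v):
            return self._label[v]
        return "{" + "|".join(sorted(self.names_of(self._tipmask[v]))) + "}"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {self.n_leaves} leaves, units={self.units!r}>"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return (
            _canonical(self.structure()) == _canonical(other.structure())
            and self.units == other.units
        )

    def __hash__(self):
        return hash(_canonical(self.structure()))


def _canonical(structure):
    """Order-independent canonical form of a nested-tuple topology."""
    if isinstance(structure, tuple):
        return tuple(sorted((_canonical(s) for s in structure), key=repr))
    return structure


def ladder_tree(taxa: Sequence[str], internode: float | None = None, units: str | None = None) -> Tree:
    """Pectinate (caterpillar) tree ((((t1,t2),t3),...),tn).

    ``taxa[0]`` and ``taxa[1]`` form the innermost cherry; ``taxa[-1]`` is the
    earliest-diverging lineage.  With ``internode`` set, every internal edge
    gets that length and tip branches are extended to make the tree
    ultrametric (tip age 0), which is the form the coalescent simulator
    expects when ``units="coalescent"``.
    """
    if len(taxa) < 2:
        raise TreeError("ladder_tree needs at least two taxa")
    struct = (str(taxa[0]), str(taxa[1]))
    for name in taxa[2:]:
        struct = (struct, str(name))
    tree = Tree.from_structure(struct, units=units)
    if internode is not None:
        # internal nodes in postorder appear cherry-first; assign ages
        ages = {}
        for v in tree.postorder:
            if tree.is_leaf(v):
                ages[v] = 0.0
        height = internode
        for v in tree.postorder:
            if not tree.is_leaf(v):
                ages[v] = height
                height += internode
        for v in tree.postorder:
            p = tree.parent(v)
            if p is not None:
                tree._length[v] = ages[p] - ages[v]
    return tree
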