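"""Marker support for alternative placements of a focal taxon or clade.

Under ILS alone, the markers that conflict with the species tree around a
contentious node are expected to distribute near-symmetrically over the
alternative local topologies; ancient hybridization instead predicts an
over-represented alternative.  This module enumerates the candidate
placements of a focal clade on a backbone tree, counts the markers that are
*diagnostic* conflict-free support for each candidate, and tests the
non-best candidates for departure from a uniform multinomial.

Diagnostic support (this package's formalization): attaching the focal
clade F on a branch subtending clade e creates the attachment-path clades
``F ∪ e`` and ``e``; a candidate's *diagnostic clades* are its path clades
that are not clades of every candidate (shared clades, like the region
itself or the focal clade, discriminate nothing).  A marker is credited to
a candidate iff it is conflict-free on that candidate's tree, its origin
branch subtends a diagnostic clade, and it could not — under any resolution
of its ``?`` entries — support a diagnostic clade of a different candidate;
a marker ambiguous between two placements counts for neither, so support
sets are disjoint by construction.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .tree import Tree, TreeError
from .matrix_io import PresenceAbsenceMatrix, PRESENT, ABSENT
from .parsimony import map_character, _classify_pattern_row

#: largest non-best total for which the exact multinomial test is attempted
EXACT_TEST_MAX_TOTAL = 200
#: enumeration guard (compositions bound; the partition enumeration is smaller)
EXACT_TEST_MAX_COMPOSITIONS = 2_000_000


@dataclass
class PlacementCandidate:
    name: str
    tree: Tree
    #: clades created by this attachment (focal ∪ e and e)
    path_clades: frozenset = frozenset()
    #: path clades not present in every candidate (what the marker must pin)
    diagnostic_clades: frozenset = frozenset()


@dataclass
class SupportProfile:
    candidates: list[PlacementCandidate]
    counts: dict[str, int]
    supporting_markers: dict[str, list[str]]
    n_ambiguous: int = 0

    @property
    def best(self) -> str:
        return max(self.counts, key=lambda k: (self.counts[k], k))

    def descending(self) -> list[tuple[str, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def placement_candidates(
    backbone: Tree,
    focal: str | Iterable[str],
    region: Iterable[str] | None = None,
    include_stem: bool = True,
    extra_placements: Sequence[Tree] = (),
) -> list[PlacementCandidate]:
    """One candidate tree per attachment branch of the focal clade.

    The focal taxon (or clade) is pruned from the backbone and re-attached
    on every branch whose subtended clade lies within ``region`` (a taxon
    set naming a clade of the pruned tree; default: the whole tree).  With
    ``include_stem`` the region's own stem branch is included (focal as
    sister to the entire region).  A rooted binary region with k leaves
    offers 2k - 1 attachment positions.  ``extra_placements`` appends
    user-supplied whole trees (e.g. a placement outside the region).
    """
    focal_names = {focal} if isinstance(focal, str) else set(map(str, focal))
    tips = set(backbone.taxa)
    missing = focal_names - tips
    if missing:
        raise TreeError(f"focal taxa not on backbone: {', '.join(sorted(missing))}")
    focal_mask = backbone.mask_of(focal_names)
    focal_node = backbone.mrca(focal_mask)
    if frozenset(backbone.clade(focal_node)) != frozenset(focal_names):
        raise TreeError("focal taxa are not a clade of the backbone")
    focal_struct = backbone.structure(focal_node)
    focal_set = frozenset(focal_names)

    pruned = _prune(backbone.structure(), focal_names)
    if pruned is None or not isinstance(pruned, tuple):
        raise TreeError("backbone must retain at least two taxa after pruning the focal clade")
    pruned_tree = Tree.from_structure(pruned)
    if region is None:
        region_set = frozenset(pruned_tree.taxa)
    else:
        region_set = frozenset(map(str, region)) - focal_names
    if region_set not in pruned_tree.clades():
        raise TreeError(f"region {sorted(region_set)} is not a clade of the pruned backbone")

    candidates: list[PlacementCandidate] = []
    for label, struct, attached in _attach_in_region(pruned, focal_struct, region_set, include_stem):
        path = frozenset({attached | focal_set, attached})
        candidates.append(
            PlacementCandidate(f"sister_to_{label}", Tree.from_structure(struct), path)
        )
    for k, t in enumerate(extra_placements):
        if set(t.taxa) != tips:
            raise TreeError("extra placement trees must share the backbone leaf set")
        candidates.append(PlacementCandidate(f"extra_{k + 1}", t, frozenset()))

    # drop duplicate topologies, keeping first occurrence
    seen: set = set()
    unique: list[PlacementCandidate] = []
    for c in candidates:
        if c.tree not in seen:
            seen.add(c.tree)
            unique.append(c)
    _assign_diagnostic_clades(unique, focal_set)
    return unique


def _prune(structure, names: set[str]):
    if not isinstance(structure, tuple):
        return None if structure in names else structure
    kids = [k for k in (_prune(c, names) for c in structure) if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return tuple(kids)


def _leafset(structure) -> frozenset[str]:
    if not isinstance(structure, tuple):
        return frozenset([structure])
    out: set[str] = set()
    for c in structure:
        out |= _leafset(c)
    return frozenset(out)


def _attach_in_region(pruned, focal_struct, region_set: frozenset[str], include_stem: bool):
    """Yield (label, full structure, attached clade) per attachment branch."""
    out = []

    def label_of(node_set) -> str:
        ls = sorted(node_set)
        return ls[0] if len(ls) == 1 else "+".join(ls)

    def rec(node, in_region: bool):
        variants = []
        node_set = _leafset(node)
        here = in_region or node_set == region_set
        if here and (include_stem or node_set != region_set):
            variants.append((label_of(node_set), (focal_struct, node), node_set))
        if isinstance(node, tuple):
            for i, child in enumerate(node):
                for label, alt, att in rec(child, here):
                    variants.append(
                        (label, tuple(alt if j == i else c for j, c in enumerate(node)), att)
                    )
        return variants

    return rec(pruned, False)


def _assign_diagnostic_clades(candidates: list[PlacementCandidate], focal_set: frozenset) -> None:
    all_clades = [c.tree.clades() for c in candidates]
    universal = set.intersection(*all_clades) if all_clades else set()
    for i, cand in enumerate(candidates):
        if cand.path_clades:
            diag = set(cand.path_clades)
        else:  # extra placement: clades unique to this candidate
            others: set = set()
            for j, cl in enumerate(all_clades):
                if j != i:
                    others |= cl
            diag = all_clades[i] - others
        diag -= universal
        diag.discard(focal_set)
        diag = {d for d in diag if len(d) > 0}
        cand.diagnostic_clades = frozenset(diag)


def support_counts(
    matrix: PresenceAbsenceMatrix, candidates: Sequence[PlacementCandidate]
) -> SupportProfile:
    """Diagnostic conflict-free marker counts per placement candidate.

    See the module docstring for the support definition.  Markers that
    could support diagnostic clades of more than one candidate (including
    via ``?`` resolution) are tallied as ambiguous and counted for none.
    """
    if not candidates:
        raise ValueError("no candidates")
    leafset = set(candidates[0].tree.taxa)
    for c in candidates:
        if set(c.tree.taxa) != leafset:
            raise TreeError("candidates do not share a leaf set")
    bad = [t for t in matrix.taxa if t not in leafset]
    if bad:
        raise TreeError(f"matrix taxa not on candidate trees: {', '.join(bad[:5])}")

    counts = {c.name: 0 for c in candidates}
    supporting: dict[str, list[str]] = {c.name: [] for c in candidates}
    n_ambiguous = 0
    taxa = matrix.taxa
    for i, mid in enumerate(matrix.marker_ids):
        row = matrix.states[i]
        if _classify_pattern_row(row) == "uninformative":
            continue
        ones = {taxa[j] for j in range(len(taxa)) if row[j] == PRESENT}
        zeros = {taxa[j] for j in range(len(taxa)) if row[j] == ABSENT}
        # candidates whose diagnostic set this marker could pin under some
        # '?' resolution: a clade C with ones ⊆ C and zeros ∩ C = ∅
        compatible = [
            c
            for c in candidates
            if any(ones <= set(cl) and not (zeros & set(cl)) for cl in c.diagnostic_clades)
        ]
        if len(compatible) > 1:
            n_ambiguous += 1
            continue
        if not compatible:
            continue
        cand = compatible[0]
        mp = map_character(cand.tree, matrix.pattern(i), mid)
        if not mp.is_conflict_free:
            continue
        origin_clade = frozenset(cand.tree.clade(mp.origin))
        if origin_clade in cand.diagnostic_clades:
            counts[cand.name] += 1
            supporting[cand.name].append(mid)
    return SupportProfile(list(candidates), counts, supporting, n_ambiguous)


# -- symmetry test ---------------------------------------------------------


@dataclass
class HybridizationCheck:
    flag: bool
    p_value: float
    method: str
    best: str
    non_best_counts: dict[str, int]
    alpha: float


def hybridization_check(
    profile: SupportProfile | Sequence[int], alpha: float = 0.05
) -> HybridizationCheck:
    """Test the non-best placement counts against the symmetric-ILS expectation.

    Under ILS alone, markers conflicting with the best-supported placement
    should scatter near-uniformly over the remaining candidates; a
    hybridization-like signature is one alternative absorbing an excess.
    Uses an exact multinomial goodness-of-fit test when the non-best total
    is small enough to enumerate, otherwise the chi-square approximation.
    The flag is raised iff uniformity is rejected at ``alpha`` and some
    non-best candidate sits above its expected count.
    """
    if isinstance(profile, SupportProfile):
        ordered = profile.descending()
        if len(ordered) < 3:
            raise ValueError("need at least 3 candidates")
        best_name = ordered[0][0]
        non_best = {k: v for k, v in ordered[1:]}
    else:
        counts = [int(v) for v in profile]
        if len(counts) < 3:
            raise ValueError("need at least 3 candidates")
        order = np.argsort(counts)[::-1]
        best_name = f"candidate_{order[0] + 1}"
        non_best = {f"candidate_{i + 1}": counts[i] for i in order[1:]}
    obs = np.array(list(non_best.values()), dtype=int)
    n, k = int(obs.sum()), obs.size
    if n == 0:
        raise ValueError("all non-best counts are zero; symmetry test undefined")
    expected = n / k
    if n <= EXACT_TEST_MAX_TOTAL and math.comb(n + k - 1, k - 1) <= EXACT_TEST_MAX_COMPOSITIONS:
        p = _exact_multinomial_p(obs)
        method = "exact-multinomial"
    else:
        p = float(stats.chisquare(obs).pvalue)
        method = "chi-square"
    residual_excess = bool((obs > expected).any())
    return HybridizationCheck(
        bool(p < alpha and residual_excess), float(p), method, best_name, non_best, alpha
    )


def _exact_multinomial_p(obs: np.ndarray) -> float:
    """Exact multinomial GOF p-value against the uniform null.

    p = total probability of all outcomes no more probable than the
    observed one (the standard exact multinomial test ordering).
    Enumeration is over count multisets (partitions of n into k
    nonnegative parts), each weighted by its number of category orderings.
    """
    n, k = int(obs.sum()), obs.size
    log_unif = -n * math.log(k)
    lgamma = math.lgamma

    def log_pmf(counts) -> float:
        return lgamma(n + 1) - sum(lgamma(c + 1) for c in counts) + log_unif

    obs_lp = log_pmf(obs.tolist())
    total = 0.0
    for comp in _partitions(n, k):
        lp = log_pmf(comp)
        if lp <= obs_lp + 1e-9:
            total += math.exp(lp) * _n_orderings(comp)
    return min(total, 1.0)


def _partitions(n: int, k: int):
    """Non-increasing tuples of k nonnegative integers summing to n."""

    def rec(remaining, parts_left, max_part):
        if parts_left == 1:
            if remaining <= max_part:
                yield (remaining,)
            return
        lo = -(-remaining // parts_left)  # ceil keeps non-increasing order feasible
        for first in range(min(remaining, max_part), lo - 1, -1):
            for rest in rec(remaining - first, parts_left - 1, first):
                yield (first,) + rest

    yield from rec(n, k, n)


def _n_orderings(comp) -> int:
    """Distinct category assignments for a count multiset."""
    out = math.factorial(len(comp))
    for mult in Counter(comp).values():
        out //= math.factorial(mult)
    return out
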