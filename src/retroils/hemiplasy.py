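"""Hemiplasy combinatorics: allelic fates of a polymorphism under ILS.

A biallelic insertion polymorphism that persists across ``n`` speciation
events on a maximally pectinate (caterpillar) species tree leaves
``L = n + 1`` lineages that each independently fix either the presence or
the absence allele: ``2**L`` equally weighted fixation vectors.

A fixation vector is *species-tree congruent* iff it could equally have
arisen with the polymorphism persisting across at most one speciation
event — that is, iff the set of presence lineages is a clade of the
caterpillar (a leading block ``l1..lk`` of the ladder, a single lineage, or
the full set) or is empty.  A caterpillar over ``L`` lineages has
``2L - 1`` clades (L leading blocks including the full set, plus ``L - 1``
non-initial singletons), so with the empty vector there are exactly ``2L``
congruent fates and ``2**L - 2L`` hemiplasious ones; the hemiplasy
probability under uniformly random fixation is ``(2**L - 2L) / 2**L``.

Lineage order: index 0 of a fixation vector is the innermost cherry lineage
and the last index is the earliest-diverging lineage, i.e. the caterpillar
is ``((((l1,l2),l3),...),lL)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

from .tree import Tree, ladder_tree

ENUMERATION_MAX_EVENTS = 20
CLOSED_FORM_MAX_EVENTS = 63


@dataclass(frozen=True)
class HemiplasyTable:
    """Counts of congruent vs hemiplasious fixation fates for one ILS duration."""

    n_events: int          # speciation events the polymorphism persists across
    n_lineages: int        # L = n_events + 1 independently sorting lineages
    n_total: int           # 2**L possible fixation vectors
    n_congruent: int       # 2 * L
    n_hemiplasious: int    # 2**L - 2*L
    p_hemiplasy: float     # n_hemiplasious / n_total


def hemiplasy_table(n_events_max: int = 17) -> list[HemiplasyTable]:
    """Closed-form hemiplasy counts for ILS across 1..n_events_max events."""
    if not 1 <= n_events_max <= CLOSED_FORM_MAX_EVENTS:
        raise ValueError(f"n_events_max must be in 1..{CLOSED_FORM_MAX_EVENTS}")
    rows = []
    for n in range(1, n_events_max + 1):
        L = n + 1
        total = 2 ** L
        congruent = 2 * L
        hemi = total - congruent
        rows.append(HemiplasyTable(n, L, total, congruent, hemi, hemi / total))
    return rows


def classify_pattern(
    fixation_vector: Sequence[int], ladder_order: Sequence[str] | None = None
) -> str:
    """Classify one fixation vector as ``"congruent"`` or ``"hemiplasious"``.

    ``fixation_vector`` holds 0/1 fates for the ladder lineages, innermost
    cherry first.  A vector is congruent iff its presence set is empty or is
    a clade of the caterpillar: a leading block, a singleton, or all
    lineages.  (``ladder_order`` optionally names the lineages; only its
    length is checked.)
    """
    vec = [int(v) for v in fixation_vector]
    if any(v not in (0, 1) for v in vec):
        raise ValueError("fixation vector entries must be 0 or 1")
    if ladder_order is not None and len(ladder_order) != len(vec):
        raise ValueError(
            f"vector length {len(vec)} does not match ladder of {len(ladder_order)} lineages"
        )
    ones = [i for i, v in enumerate(vec) if v]
    if not ones or len(ones) == len(vec) or len(ones) == 1:
        return "congruent"
    if ones == list(range(len(ones))):  # leading block l1..lk
        return "congruent"
    return "hemiplasious"


def enumerate_fates(n_events: int) -> list[tuple[tuple[int, ...], str]]:
    """All ``2**(n_events+1)`` fixation vectors with their classification."""
    if not 1 <= n_events <= ENUMERATION_MAX_EVENTS:
        raise ValueError(f"n_events must be in 1..{ENUMERATION_MAX_EVENTS}")
    L = n_events + 1
    return [(vec, classify_pattern(vec)) for vec in product((0, 1), repeat=L)]


def caterpillar(n_lineages: int) -> Tree:
    """The pectinate species tree the classification refers to.

    Lineage ``l1`` is the innermost cherry member, ``l{L}`` the
    earliest-diverging lineage, matching the vector index convention.
    """
    if n_lineages < 2:
        raise ValueError("need at least 2 lineages")
    return ladder_tree([f"l{i + 1}" for i in range(n_lineages)])
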