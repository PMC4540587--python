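"""Quantify incomplete lineage sorting per marker, branch, partition, radiation.

The ILS duration of a marker is the minimum number of speciation events its
insertion polymorphism must have persisted across: with ``k`` independently
fixing lineages (fixations to presence plus fixations to absence in the
minimal polymorphism-parsimony mapping), the duration is ``k - 1``.
Conflict-free markers (a single fixation) correspond to ILS across one or
fewer speciation events and are reported as duration class ``"<=1"``; the
conflict classes ``2`` (weak), ``3`` (moderate) and ``">=4"`` (strong)
mirror the doughnut-plot convention of per-internode ILS summaries.

Each marker is attributed to its parsimony-inferred origin branch; branch
summaries count conflict-free vs ILS-affected insertions per internode and,
when a dated tree (branch lengths in MY) is supplied, the insertion rate
per million years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tree import Tree
from .matrix_io import PresenceAbsenceMatrix
from .parsimony import (
    CharacterMapping,
    MappingError,
    map_character,
    search_mpre,
    _classify_pattern_row,
)

DURATION_CLASSES = ("<=1", "2", "3", ">=4")


class UndefinedDurationError(ValueError):
    """ILS duration is undefined for all-absent (empty) mappings."""


def ils_duration(mapping: CharacterMapping) -> int:
    """Minimal number of speciation events the polymorphism persisted across.

    ``fixations_to_1 + fixations_to_0 - 1``; conflict-free markers return 0
    (class ``"<=1"``: one or fewer events is indistinguishable from none).
    """
    if mapping.is_empty:
        raise UndefinedDurationError(
            f"marker {mapping.marker_id!r}: all-absent pattern has no ILS duration"
        )
    return mapping.n_fixations - 1


def duration_class(duration: int) -> str:
    if duration <= 1:
        return "<=1"
    if duration >= 4:
        return ">=4"
    return str(duration)


@dataclass
class BranchILSSummary:
    """Per-internode marker counts (conflict-free vs ILS duration classes)."""

    branch: int                       # node id on the analyzed tree
    branch_name: str                  # sorted tip names of the subtended clade
    conflict_free: int = 0
    ils_counts: dict[str, int] = field(default_factory=lambda: {"2": 0, "3": 0, ">=4": 0})
    branch_length_my: float | None = None

    @property
    def n_ils(self) -> int:
        return sum(self.ils_counts.values())

    @property
    def total_markers(self) -> int:
        return self.conflict_free + self.n_ils

    @property
    def pct_ils(self) -> float | None:
        """Percent ILS-affected; None (undefined) for empty internodes."""
        if self.total_markers == 0:
            return None
        return 100.0 * self.n_ils / self.total_markers

    @property
    def insertion_rate(self) -> float | None:
        """Insertions per million years (requires a dated branch length)."""
        if self.branch_length_my is None or self.branch_length_my <= 0:
            return None
        return self.total_markers / self.branch_length_my


@dataclass
class MarkerILSRecord:
    marker_id: str
    origin: int | None
    origin_name: str | None
    duration: int | None
    duration_class: str | None
    conflict_free: bool | None


def marker_table(
    tree: Tree, matrix: PresenceAbsenceMatrix
) -> tuple[list[MarkerILSRecord], list[CharacterMapping | None]]:
    """Map every marker and tabulate origin branch + ILS duration.

    Uninformative markers (all-absent or constant-presence after ``?``)
    yield records with ``None`` fields and are excluded from branch
    summaries.
    """
    records: list[MarkerILSRecord] = []
    mappings: list[CharacterMapping | None] = []
    for i, mid in enumerate(matrix.marker_ids):
        row = matrix.states[i]
        if _classify_pattern_row(row) == "uninformative":
            records.append(MarkerILSRecord(mid, None, None, None, None, None))
            mappings.append(None)
            continue
        mp = map_character(tree, matrix.pattern(i), mid)
        d = ils_duration(mp)
        records.append(
            MarkerILSRecord(
                mid, mp.origin, tree.branch_name(mp.origin), d, duration_class(d), d <= 1
            )
        )
        mappings.append(mp)
    return records, mappings


def branch_summary(
    tree: Tree,
    matrix: PresenceAbsenceMatrix,
    dated_tree: Tree | None = None,
) -> list[BranchILSSummary]:
    """Per-branch conflict-free/ILS counts with optional insertion rates.

    Markers are attributed to their parsimony origin branch on ``tree``.
    ``dated_tree`` (same topology, branch lengths in MY) supplies the
    denominators for insertion rates; without it rates are undefined.
    """
    if dated_tree is not None:
        if dated_tree.units != "my":
            raise ValueError("dated_tree must carry branch lengths in MY (units='my')")
        date_of = {frozenset(dated_tree.clade(v)): dated_tree.length(v) for v in dated_tree.postorder}
    records, _ = marker_table(tree, matrix)
    summaries: dict[int, BranchILSSummary] = {}
    for v in tree.postorder:
        length = None
        if dated_tree is not None:
            length = date_of.get(tree.clade(v))
        summaries[v] = BranchILSSummary(v, tree.branch_name(v), branch_length_my=length)
    for rec in records:
        if rec.origin is None:
            continue
        s = summaries[rec.origin]
        if rec.conflict_free:
            s.conflict_free += 1
        else:
            s.ils_counts[duration_class(rec.duration)] += 1
    return [summaries[v] for v in tree.postorder]


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "t", n_perm: int = 9999, seed: int = 0
) -> CorrelationResult:
    """Spearman rank correlation between two per-branch vectors.

    Ties get average ranks.  ``method="t"`` uses the large-sample t
    approximation for the two-sided p-value; ``method="permutation"`` uses
    an exact-by-resampling permutation p-value (seeded).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    if method == "t":
        res = stats.spearmanr(x, y)
        return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))
    if method == "permutation":
        rho = float(stats.spearmanr(x, y).statistic)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            r = float(stats.spearmanr(x, rng.permutation(y)).statistic)
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return CorrelationResult(rho, (count + 1) / (n_perm + 1), int(x.size))
    raise ValueError(f"unknown method {method!r}")


# -- genomic partitions ----------------------------------------------------


def z_vs_autosome(chromosome: str | None, z_names: Iterable[str] = ("Z", "chrZ")) -> str:
    if chromosome is None or (isinstance(chromosome, float) and np.isnan(chromosome)):
        return "unknown"
    chrom = str(chromosome).strip()
    if not chrom or chrom.lower() in ("nan", "na", "un", "unknown"):
        return "unknown"
    if chrom in set(z_names):
        return "Z"
    return "autosome"


def micro_vs_macro(
    chromosome: str | None,
    sizes: Mapping[str, float],
    threshold: float = 20e6,
) -> str:
    """Micro/macrochromosome split at the conventional 20-Mb size cutoff."""
    if chromosome is None:
        return "unknown"
    chrom = str(chromosome).strip()
    if chrom not in sizes:
        return "unknown"
    return "micro" if sizes[chrom] < threshold else "macro"


@dataclass
class PartitionSummary:
    partition: str
    n_markers: int
    n_informative: int
    n_ils: int

    @property
    def pct_ils(self) -> float | None:
        if self.n_informative == 0:
            return None
        return 100.0 * self.n_ils / self.n_informative


def partition_summary(
    matrix: PresenceAbsenceMatrix,
    tree: Tree,
    partition_rule: Callable[[str | None], str] | Mapping[str, str] = z_vs_autosome,
) -> list[PartitionSummary]:
    """ILS-affected marker fraction per genomic partition.

    ``partition_rule`` is either a callable on the chromosome name or a
    mapping marker_id → partition name.  Markers whose chromosome is
    unassignable land in an explicit ``"unknown"`` partition rather than
    being dropped.
    """
    if not callable(partition_rule):
        lookup = dict(partition_rule)
        assign = lambda mid, chrom: lookup.get(mid, "unknown")  # noqa: E731
    else:
        assign = lambda mid, chrom: partition_rule(chrom)  # noqa: E731
    chroms: dict[str, str | None] = {}
    if matrix.meta is not None and "chromosome" in matrix.meta.columns:
        chroms = matrix.meta["chromosome"].to_dict()
    records, _ = marker_table(tree, matrix)
    out: dict[str, PartitionSummary] = {}
    for rec in records:
        part = assign(rec.marker_id, chroms.get(rec.marker_id))
        s = out.setdefault(part, PartitionSummary(part, 0, 0, 0))
        s.n_markers += 1
        if rec.duration is None:
            continue
        s.n_informative += 1
        if not rec.conflict_free:
            s.n_ils += 1
    return sorted(out.values(), key=lambda s: s.partition)


# -- radiations (clade subsets of internodes) ------------------------------


@dataclass
class RadiationSummary:
    radiation: str
    n_markers: int
    n_ils: int
    duration_spectrum: dict[int, int]

    @property
    def pct_ils(self) -> float | None:
        if self.n_markers == 0:
            return None
        return 100.0 * self.n_ils / self.n_markers


def radiation_summary(
    tree: Tree,
    matrix: PresenceAbsenceMatrix,
    radiations: Mapping[str, Iterable[frozenset | set | tuple | list]],
) -> list[RadiationSummary]:
    """Duration-class frequency spectra for named internode sets.

    ``radiations`` names each radiation and lists the clades (taxon sets)
    whose stem branches belong to it; markers originating on those branches
    are pooled and their full integer duration spectrum reported.
    """
    clade_node = {tree.clade(v): v for v in tree.postorder}
    memberships: dict[str, set[int]] = {}
    for name, clades in radiations.items():
        nodes = set()
        for c in clades:
            key = frozenset(str(t) for t in c)
            if key not in clade_node:
                raise ValueError(f"radiation {name!r}: {sorted(key)} is not a clade of the tree")
            nodes.add(clade_node[key])
        memberships[name] = nodes
    records, _ = marker_table(tree, matrix)
    out = {name: RadiationSummary(name, 0, 0, {}) for name in radiations}
    for rec in records:
        if rec.origin is None:
            continue
        for name, nodes in memberships.items():
            if rec.origin in nodes:
                s = out[name]
                s.n_markers += 1
                if not rec.conflict_free:
                    s.n_ils += 1
                s.duration_spectrum[rec.duration] = s.duration_spectrum.get(rec.duration, 0) + 1
    return [out[name] for name in radiations]


def subtree_tree(
    matrix: PresenceAbsenceMatrix,
    marker_ids: Iterable[str],
    n_jumbles: int = 7,
    seed: int = 11111,
):
    """Most-parsimonious tree from a marker subset (e.g. Z-linked markers).

    Delegates to the heuristic search; warns (but still runs) when fewer
    than 3 informative markers remain.
    """
    import logging

    sub = matrix.subset(marker_ids)
    n_informative = sum(
        1 for i in range(sub.n_markers) if _classify_pattern_row(sub.states[i]) == "informative"
    )
    if n_informative < 3:
        logging.getLogger(__name__).warning(
            "marker subset has only %d informative markers; tree will be poorly resolved",
            n_informative,
        )
    return search_mpre(sub, n_jumbles=n_jumbles, seed=seed)


def pct_ils_overall(tree: Tree, matrix: PresenceAbsenceMatrix) -> float | None:
    """Percent ILS-affected among informative markers (genome-wide average)."""
    records, _ = marker_table(tree, matrix)
    informative = [r for r in records if r.duration is not None]
    if not informative:
        return None
    return 100.0 * sum(1 for r in informative if not r.conflict_free) / len(informative)


def records_frame(records: Sequence[MarkerILSRecord]) -> pd.DataFrame:
    """Per-marker table (marker id, origin branch, duration, class) as a DataFrame."""
    return pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in records],
            "origin_branch": [r.origin_name for r in records],
            "duration": [r.duration for r in records],
            "duration_class": [r.duration_class for r in records],
            "conflict_free": [r.conflict_free for r in records],
        }
    )


def branch_frame(summaries: Sequence[BranchILSSummary]) -> pd.DataFrame:
    """Per-branch table mirroring published per-internode ILS/rate tables."""
    return pd.DataFrame(
        {
            "branch": [s.branch_name for s in summaries],
            "conflict_free": [s.conflict_free for s in summaries],
            "ils_2": [s.ils_counts["2"] for s in summaries],
            "ils_3": [s.ils_counts["3"] for s in summaries],
            "ils_ge4": [s.ils_counts[">=4"] for s in summaries],
            "total": [s.total_markers for s in summaries],
            "pct_ils": [s.pct_ils for s in summaries],
            "branch_length_my": [s.branch_length_my for s in summaries],
            "insertion_rate_per_my": [s.insertion_rate for s in summaries],
        }
    )
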