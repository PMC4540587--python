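"""Coalescent simulator for retrotransposon presence/absence markers.

The generator stands in for a genome-screening pipeline: it produces marker
matrices whose conflicts arise from incomplete lineage sorting alone, under
the exact assumptions the mapping method makes — a single haploid lineage
per species, one insertion per locus (infinite sites), no independent
insertion and no precise excision.

Per locus: a gene tree is drawn under the multispecies coalescent on the
species tree (branch lengths in coalescent units; within a branch, k
lineages coalesce at rate k(k-1)/2 and survivors pass to the parent
branch); an insertion is placed uniformly along the gene tree (optionally
weighted by per-species-branch rate multipliers); the presence pattern is
the insertion edge's descendant tips.  Missing-data masking and the usual
ascertainment filters (min scored taxa, no plesiomorphies, no
autapomorphies, no all-absent) are applied by rejection sampling, so the
requested number of retained loci is exact.

Each retained locus carries two ground truths:

* ``duration_pattern`` — the minimal ILS duration implied by the complete,
  unmasked presence/absence pattern (polymorphism parsimony on the
  generating species tree): the estimand of pattern-based inference;
* ``duration_true`` — the genealogical persistence: the number of
  speciation events more recent than the insertion at which the splitting
  population contained both carrier and non-carrier sampled lineages.  This
  can exceed ``duration_pattern`` when deep coalescence leaves no trace in
  the pattern (e.g. a clean clade pattern fixed only after the polymorphism
  crossed a speciation), which is exactly the component of ILS that no
  presence/absence method can recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tree import Tree, TreeError, ladder_tree, _canonical
from .matrix_io import PresenceAbsenceMatrix, MISSING, PRESENT, ABSENT
from .parsimony import map_character, _classify_pattern_row
from .ils import ils_duration, marker_table, duration_class


class SimulationError(RuntimeError):
    pass


# -- gene trees ------------------------------------------------------------


@dataclass
class GeneTree:
    """Coalescent gene tree: node times, children, descendant-tip bitmasks."""

    times: list[float]
    children: list[tuple[int, ...]]
    tipmask: list[int]
    taxa: list[str]                      # bit order matches the species tree
    #: residency segments (gene node, species node, t0, t1): the time span a
    #: gene lineage spends inside a species-tree branch
    segments: list[tuple[int, int, float, float]]
    #: per internal species node: tipmasks of lineages entering its parent branch
    entering: dict[int, list[int]]

    @property
    def root(self) -> int:
        return len(self.times) - 1

    def parent_map(self) -> list[int | None]:
        parent: list[int | None] = [None] * len(self.times)
        for i, kids in enumerate(self.children):
            for k in kids:
                parent[k] = i
        return parent

    def structure(self, v: int | None = None):
        if v is None:
            v = self.root
        if not self.children[v]:
            bit = self.tipmask[v]
            return self.taxa[bit.bit_length() - 1]
        return tuple(self.structure(c) for c in self.children[v])

    def topology_matches(self, species_tree: Tree) -> bool:
        return _canonical(self.structure()) == _canonical(species_tree.structure())

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if not self.children[v]:
                s = self.taxa[self.tipmask[v].bit_length() - 1]
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            p = self._parent[v]
            if p is not None:
                s += f":{self.times[p] - self.times[v]:g}"
            return s

        self._parent = self.parent_map()
        return fmt(self.root) + ";"


def simulate_gene_tree(species_tree: Tree, rng: np.random.Generator) -> GeneTree:
    """One multispecies-coalescent gene tree, one haploid sample per species.

    ``species_tree`` must be ultrametric with branch lengths in coalescent
    units (``units="coalescent"`` recommended).  Within each species branch
    the standard n-coalescent runs; lineages remaining at the top pass to
    the parent branch, and above the root coalescence continues to a single
    lineage.
    """
    if species_tree.units not in ("coalescent", None):
        raise SimulationError("species tree branch lengths must be in coalescent units")
    ages = species_tree.node_ages()
    taxa = species_tree.taxa

    times: list[float] = []
    children: list[tuple[int, ...]] = []
    tipmask: list[int] = []
    segments: list[tuple[int, int, float, float]] = []
    entering: dict[int, list[int]] = {}
    # lineages surviving the branch above each species node
    surviving: dict[int, list[int]] = {}

    def new_node(t: float, kids: tuple[int, ...], mask: int) -> int:
        times.append(t)
        children.append(kids)
        tipmask.append(mask)
        return len(times) - 1

    for v in species_tree.postorder:
        if species_tree.is_leaf(v):
            g = new_node(0.0, (), species_tree.tipmask(v))
            active = [g]
        else:
            active = []
            for c in species_tree.children(v):
                active.extend(surviving[c])
            entering[v] = [tipmask[g] for g in active]
        t = ages[v]
        p = species_tree.parent(v)
        t_top = ages[p] if p is not None else np.inf
        starts = {g: t for g in active}
        while len(active) > 1:
            k = len(active)
            wait = rng.exponential(1.0 / (k * (k - 1) / 2.0))
            if t + wait >= t_top:
                break
            t += wait
            i, j = sorted(rng.choice(k, size=2, replace=False))
            gi, gj = active[j], active[i]  # pop higher index first
            active.pop(j)
            active.pop(i)
            segments.append((gi, v, starts.pop(gi), t))
            segments.append((gj, v, starts.pop(gj), t))
            merged = new_node(t, (gi, gj), tipmask[gi] | tipmask[gj])
            active.append(merged)
            starts[merged] = t
        if p is None and len(active) == 1:
            g = active[0]
            segments.append((g, v, starts.pop(g), t))  # zero-length stub for the root lineage
        else:
            for g in active:
                segments.append((g, v, starts.pop(g), t_top))
        surviving[v] = active

    return GeneTree(times, children, tipmask, taxa, segments, entering)


def _draw_insertion(
    gene: GeneTree,
    species_tree: Tree,
    rng: np.random.Generator,
    rate_multipliers: Mapping[int, float] | None = None,
) -> tuple[int, int, float]:
    """(gene node below the insertion, species branch, insertion time)."""
    root = gene.root
    segs = [s for s in gene.segments if s[0] != root and s[3] > s[2]]
    if not segs:
        raise SimulationError("degenerate gene tree with no branch length")
    weights = np.array(
        [
            (t1 - t0) * (1.0 if rate_multipliers is None else rate_multipliers.get(sp, 1.0))
            for (_, sp, t0, t1) in segs
        ]
    )
    total = weights.sum()
    if total <= 0:
        raise SimulationError("all insertion weights are zero")
    idx = int(rng.choice(len(segs), p=weights / total))
    g, sp, t0, t1 = segs[idx]
    t_ins = t0 + rng.uniform(0.0, t1 - t0)
    return g, sp, t_ins


def genealogical_duration(gene: GeneTree, species_tree: Tree, carriers: int, t_ins: float) -> int:
    """Speciation events with a witnessed presence/absence polymorphism.

    Counts internal species nodes more recent than the insertion whose
    splitting population contained at least one carrier lineage (tipmask a
    subset of ``carriers``) and one non-carrier lineage.
    """
    ages = species_tree.node_ages()
    n = 0
    for v, masks in gene.entering.items():
        if ages[v] >= t_ins:
            continue
        has_carrier = any(m & ~carriers == 0 for m in masks)
        has_other = any(m & carriers == 0 for m in masks)
        if has_carrier and has_other:
            n += 1
    return n


# -- matrix simulation -----------------------------------------------------


def default_chromosome_scheme() -> dict[str, float]:
    """A rough avian-like chromosome assignment: macros, Z, many micros."""
    scheme = {f"chr{i}": w for i, w in zip(range(1, 11), (0.13, 0.11, 0.10, 0.07, 0.06, 0.05, 0.04, 0.035, 0.03, 0.025))}
    scheme["chrZ"] = 0.07
    micro_total = 1.0 - sum(scheme.values())
    for i in range(11, 31):
        scheme[f"chr{i}"] = micro_total / 20.0
    return scheme


@dataclass
class SimulationConfig:
    """Study-condition knobs for the marker generator.

    Defaults mirror a genome-screening study design: thousands of candidate
    loci, a fifth of entries unscorable, and ascertainment that discards
    plesiomorphic, autapomorphic, under-scored and empty patterns (markers
    must be scorable in ≥10 taxa, capped at the taxon count for small
    validation trees).
    """

    species_tree: Tree
    n_loci: int = 2000
    missing_rate: float = 0.2
    min_scored_taxa: int = 10
    drop_plesiomorphic: bool = True
    drop_autapomorphic: bool = True
    drop_all_absent: bool = True
    chromosomes: Mapping[str, float] | None = None
    z_names: tuple[str, ...] = ("chrZ", "Z")
    micro_names: tuple[str, ...] = tuple(f"chr{i}" for i in range(11, 31))
    rate_multipliers: Mapping[int, float] | None = None
    p_genic: float = 0.45
    seed: int = 0
    keep_gene_trees: bool = False
    max_attempts_per_locus: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.chromosomes is not None:
            w = sum(self.chromosomes.values())
            if w <= 0:
                raise ValueError("chromosome proportions must sum to a positive value")


def simulate_matrix(config: SimulationConfig) -> tuple[PresenceAbsenceMatrix, pd.DataFrame]:
    """Simulate a marker matrix plus its per-locus truth table.

    Returns ``(matrix, truth)`` where ``truth`` has one row per retained
    locus: carriers, insertion branch and time, genealogical duration
    (``duration_true``), pattern-implied duration (``duration_pattern``),
    and the attempt count.  Deterministic given the config seed.
    """
    tree = config.species_tree
    rng = np.random.default_rng(config.seed)
    taxa = tree.taxa
    n_taxa = len(taxa)
    min_scored = min(config.min_scored_taxa, n_taxa)
    chrom_names = list(config.chromosomes) if config.chromosomes else None
    chrom_probs = None
    if chrom_names:
        w = np.array([config.chromosomes[c] for c in chrom_names], dtype=float)
        chrom_probs = w / w.sum()

    rows: list[np.ndarray] = []
    truth_rows: list[dict] = []
    meta_rows: list[dict] = []
    attempts_total = 0
    for locus in range(config.n_loci):
        for attempt in range(1, config.max_attempts_per_locus + 1):
            attempts_total += 1
            gene = simulate_gene_tree(tree, rng)
            g, sp, t_ins = _draw_insertion(gene, tree, rng, config.rate_multipliers)
            carriers = gene.tipmask[g]
            full = np.array(
                [PRESENT if (tree.leaf_bit(t) & carriers) else ABSENT for t in taxa],
                dtype=np.int8,
            )
            observed = full.copy()
            if config.missing_rate > 0:
                mask = rng.random(n_taxa) < config.missing_rate
                observed[mask] = MISSING
            scored = observed != MISSING
            n_scored = int(scored.sum())
            n_present = int((observed == PRESENT).sum())
            if n_scored < min_scored:
                continue
            if config.drop_all_absent and n_present == 0:
                continue
            if config.drop_plesiomorphic and n_scored > 0 and n_present == n_scored:
                continue
            if config.drop_autapomorphic and n_present == 1:
                continue
            break
        else:
            raise SimulationError(
                f"locus {locus}: no pattern passed ascertainment within "
                f"{config.max_attempts_per_locus} attempts (filters too strict "
                f"for this tree/missing-rate combination)"
            )
        locus_id = f"locus_{locus + 1:05d}"
        rows.append(observed)
        full_pattern = {t: str(int(s)) for t, s in zip(taxa, full)}
        mp = map_character(tree, full_pattern, locus_id)
        d_pattern = ils_duration(mp)
        d_true = genealogical_duration(gene, tree, carriers, t_ins)
        rec = {
            "locus_id": locus_id,
            "carriers": "|".join(tree.names_of(carriers)),
            "insertion_branch": tree.branch_name(sp),
            "t_insertion": t_ins,
            "origin_branch_pattern": tree.branch_name(mp.origin),
            "duration_pattern": d_pattern,
            "duration_true": d_true,
            "attempts": attempt,
        }
        if config.keep_gene_trees:
            rec["gene_tree"] = gene.to_newick()
        truth_rows.append(rec)
        meta = {}
        if chrom_names:
            meta["chromosome"] = chrom_names[int(rng.choice(len(chrom_names), p=chrom_probs))]
        else:
            meta["chromosome"] = "chr1"
        start = int(rng.integers(1, 150_000_000))
        meta["start"] = start
        meta["end"] = start + int(rng.integers(300, 8000))
        meta["genic"] = bool(rng.random() < config.p_genic)
        meta["tsd_motif"] = "".join(rng.choice(list("ACGT"), size=5))
        meta_rows.append(meta)

    marker_ids = [r["locus_id"] for r in truth_rows]
    meta_df = pd.DataFrame(meta_rows, index=pd.Index(marker_ids, name="marker_id"))
    matrix = PresenceAbsenceMatrix(taxa, marker_ids, np.vstack(rows), meta_df)
    truth = pd.DataFrame(truth_rows).set_index("locus_id")
    truth.attrs["attempts_total"] = attempts_total
    return matrix, truth


# -- validation harness ----------------------------------------------------


@dataclass
class RecoveryReport:
    """Estimated vs true per-locus ILS durations and per-branch rates."""

    per_locus: pd.DataFrame
    agreement_pattern: float     # vs duration implied by the full pattern
    agreement_genealogy: float   # vs genealogical persistence
    pct_ils_estimated: float | None
    pct_ils_pattern_truth: float | None


def _clamp_class(d: int) -> str:
    # conflict-free = "ILS across one or fewer events": 0 and 1 are one class
    return "<=1" if d <= 1 else str(d)


def recover_parameters(
    matrix: PresenceAbsenceMatrix, species_tree: Tree, truth: pd.DataFrame
) -> RecoveryReport:
    """Run the mapping pipeline on simulated data and compare to truth.

    Per-locus parsimony durations (from the observed, possibly masked
    matrix) are compared class-wise (``<=1``, 2, 3, ...) against both the
    pattern-implied truth and the genealogical truth.
    """
    records, _ = marker_table(species_tree, matrix)
    est = {r.marker_id: r.duration for r in records}
    rows = []
    for locus_id, t in truth.iterrows():
        e = est.get(locus_id)
        if e is None:
            continue  # uninformative after masking; excluded from agreement
        rows.append(
            {
                "locus_id": locus_id,
                "duration_estimated": e,
                "duration_pattern": int(t["duration_pattern"]),
                "duration_true": int(t["duration_true"]),
                "match_pattern": _clamp_class(e) == _clamp_class(int(t["duration_pattern"])),
                "match_genealogy": _clamp_class(e) == _clamp_class(int(t["duration_true"])),
            }
        )
    per_locus = pd.DataFrame(rows)
    if len(per_locus) == 0:
        raise SimulationError("no informative loci to compare")
    informative = [r for r in records if r.duration is not None]
    pct_est = (
        100.0 * sum(1 for r in informative if not r.conflict_free) / len(informative)
        if informative
        else None
    )
    pattern_truth = truth.loc[per_locus["locus_id"], "duration_pattern"]
    pct_truth = 100.0 * float((pattern_truth >= 2).mean()) if len(pattern_truth) else None
    return RecoveryReport(
        per_locus,
        float(per_locus["match_pattern"].mean()),
        float(per_locus["match_genealogy"].mean()),
        pct_est,
        pct_truth,
    )


def to_coalescent_units(
    time_my: float, n_e: float, generation_time_years: float, ploidy: int = 2
) -> float:
    """Convert a span in MY to coalescent units (the only home of N_e here).

    ``time_my * 1e6 / generation_time_years`` generations divided by
    ``ploidy * n_e`` (2N_e generations per unit for diploids).
    """
    if n_e <= 0 or generation_time_years <= 0:
        raise ValueError("n_e and generation_time_years must be positive")
    return time_my * 1e6 / generation_time_years / (ploidy * n_e)
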