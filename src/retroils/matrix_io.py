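"""Presence/absence matrices of retrotransposon markers: I/O, validation, filtering.

The central data object is :class:`PresenceAbsenceMatrix`: markers × taxa over
the states ``1`` (orthologous insertion present), ``0`` (absent: intact,
non-duplicated target site), and ``?`` (missing / unscorable).  Polarity is
fixed — 0 is the ancestral state, established upstream with non-ingroup
outgroups — and is never inferred here.

Three on-disk dialects are supported:

* wide CSV (rows = markers, metadata columns then one column per taxon) —
  the package's canonical form;
* PHYLIP discrete (``ntax nchar`` header, rows = taxa, symbols ``0 1 ?``);
* NEXUS with a standard-datatype DATA block (``symbols="01" missing=?``),
  via dendropy.

Marker metadata columns (``chromosome``, ``start``, ``end``, ``genic``,
``tsd_motif``) ride along in the CSV dialect.  Coordinates are 1-based
inclusive, matching the spreadsheet presentation of typical deposited marker
tables.  On input, the missing symbols ``N`` and ``-`` are tolerated and
mapped to ``?`` with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import dendropy

log = logging.getLogger(__name__)

#: integer codes used in the states array
ABSENT, PRESENT, MISSING = 0, 1, -1

_CODE_OF = {"0": ABSENT, "1": PRESENT, "?": MISSING}
_CHAR_OF = {ABSENT: "0", PRESENT: "1", MISSING: "?"}
_TOLERATED_MISSING = {"N", "n", "-"}

#: metadata columns recognized in the wide-CSV dialect, in canonical order
META_COLUMNS = ("chromosome", "start", "end", "genic", "tsd_motif")

FORMATS = ("csv-wide", "phylip-discrete", "nexus-standard")


class MatrixFormatError(ValueError):
    """Malformed matrix input; the message names the offending record."""


class PresenceAbsenceMatrix:
    """Binary presence/absence marker matrix with optional per-marker metadata.

    Parameters
    ----------
    taxa : ordered taxon names (whitespace-trimmed, case-sensitive).
    marker_ids : unique marker identifiers.
    states : array (n_markers, n_taxa) with codes 1/0/-1 (present/absent/missing),
        or an iterable of strings over ``{"0","1","?"}``.
    meta : optional DataFrame indexed like ``marker_ids`` carrying marker
        metadata (chromosome, 1-based inclusive start/end, genic flag,
        5-bp TSD motif).
    """

    def __init__(
        self,
        taxa: Sequence[str],
        marker_ids: Sequence[str],
        states,
        meta: pd.DataFrame | None = None,
    ) -> None:
        self.taxa = [str(t).strip() for t in taxa]
        self.marker_ids = [str(m) for m in marker_ids]
        arr = np.asarray(states)
        if arr.dtype.kind in "US":
            coded = np.empty(arr.shape, dtype=np.int8)
            for sym, code in _CODE_OF.items():
                coded[arr == sym] = code
            bad = ~np.isin(arr, list(_CODE_OF))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise MatrixFormatError(
                    f"non-binary symbol {arr[i, j]!r} at marker "
                    f"{self.marker_ids[i]!r}, taxon {self.taxa[j]!r}"
                )
            arr = coded
        self.states = arr.astype(np.int8)
        if self.states.ndim != 2 or self.states.shape != (len(self.marker_ids), len(self.taxa)):
            raise MatrixFormatError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.taxa)} taxa"
            )
        if not np.isin(self.states, [ABSENT, PRESENT, MISSING]).all():
            raise MatrixFormatError("state codes must be 1, 0 or -1 ('?')")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixFormatError(f"duplicate taxon name(s): {', '.join(dupes)}")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            dupes = sorted({m for m in self.marker_ids if self.marker_ids.count(m) > 1})
            raise MatrixFormatError(f"duplicate marker id(s): {', '.join(dupes)}")
        if meta is not None:
            meta = meta.copy()
            meta.index = pd.Index(self.marker_ids, name="marker_id")
            _validate_meta(meta)
        self.meta = meta

    # -- container basics --------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.states, other.states)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PresenceAbsenceMatrix {self.n_markers} markers x {self.n_taxa} taxa>"

    def pattern(self, marker) -> dict[str, str]:
        """Per-taxon states ``{'1','0','?'}`` for one marker (id or index)."""
        i = marker if isinstance(marker, (int, np.integer)) else self.marker_ids.index(marker)
        row = self.states[i]
        return {t: _CHAR_OF[int(s)] for t, s in zip(self.taxa, row)}

    def subset(self, marker_ids: Iterable[str]) -> "PresenceAbsenceMatrix":
        wanted = list(marker_ids)
        pos = {m: i for i, m in enumerate(self.marker_ids)}
        missing = [m for m in wanted if m not in pos]
        if missing:
            raise MatrixFormatError(f"unknown marker id(s): {', '.join(missing[:5])}")
        idx = [pos[m] for m in wanted]
        meta = self.meta.iloc[idx] if self.meta is not None else None
        return PresenceAbsenceMatrix(self.taxa, wanted, self.states[idx], meta)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: metadata columns (if any) then one column per taxon."""
        sym = np.vectorize(_CHAR_OF.get)(self.states) if self.n_markers else np.empty((0, self.n_taxa), dtype=object)
        df = pd.DataFrame(sym, index=pd.Index(self.marker_ids, name="marker_id"), columns=self.taxa)
        if self.meta is not None:
            df = pd.concat([self.meta, df], axis=1)
        return df


def _validate_meta(meta: pd.DataFrame) -> None:
    if {"start", "end"}.issubset(meta.columns):
        se = meta[["start", "end"]].dropna()
        bad = se[se["start"].astype(float) > se["end"].astype(float)]
        if len(bad):
            raise MatrixFormatError(f"start > end for marker {bad.index[0]!r}")
    if "tsd_motif" in meta.columns:
        motifs = meta["tsd_motif"].dropna()
        for mid, motif in motifs.items():
            m = str(motif)
            if len(m) != 5 or any(ch not in "ACGTN" for ch in m.upper()):
                raise MatrixFormatError(f"marker {mid!r}: TSD motif must be 5 letters over ACGTN, got {motif!r}")


def _clean_symbols(raw: np.ndarray, where: str) -> np.ndarray:
    """Map tolerated missing symbols to '?', reject anything non-binary."""
    arr = raw.astype(str)
    arr = np.char.strip(arr)
    tolerated = np.isin(arr, list(_TOLERATED_MISSING))
    if tolerated.any():
        log.warning("%s: mapped %d '%s'-style entries to '?'", where, int(tolerated.sum()),
                    "/".join(sorted({a for a in arr[tolerated]})))
        arr = np.where(tolerated, "?", arr)
    return arr


# -- readers ---------------------------------------------------------------


def read_matrix(path, format: str = "csv-wide") -> PresenceAbsenceMatrix:
    """Read a presence/absence matrix in one of the supported dialects."""
    if format == "csv-wide":
        return _read_csv(path)
    if format == "phylip-discrete":
        return _read_phylip(path)
    if format == "nexus-standard":
        return _read_nexus(path)
    raise MatrixFormatError(f"unknown matrix format {format!r}; expected one of {FORMATS}")


def _read_csv(path) -> PresenceAbsenceMatrix:
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise MatrixFormatError(f"could not parse CSV {path}: {exc}") from exc
    if "marker_id" not in df.columns:
        raise MatrixFormatError(f"{path}: wide CSV must have a 'marker_id' column")
    df = df.set_index("marker_id")
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    taxa = [c for c in df.columns if c not in META_COLUMNS]
    if not taxa:
        raise MatrixFormatError(f"{path}: no taxon columns found")
    meta = df[meta_cols] if meta_cols else None
    if meta is not None:
        meta = meta.copy()
        for col in ("start", "end"):
            if col in meta.columns:
                meta[col] = pd.to_numeric(meta[col], errors="coerce").astype("Int64")
    sym = _clean_symbols(df[taxa].fillna("?").to_numpy(), where=str(path))
    return PresenceAbsenceMatrix(taxa, df.index.tolist(), sym, meta)


def _read_phylip(path) -> PresenceAbsenceMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty PHYLIP file")
    head = lines[0].split()
    if len(head) != 2 or not all(tok.isdigit() for tok in head):
        raise MatrixFormatError(f"{path}, line 1: malformed PHYLIP header {lines[0]!r}")
    ntax, nchar = int(head[0]), int(head[1])
    if len(lines) - 1 != ntax:
        raise MatrixFormatError(f"{path}: header promises {ntax} taxa, found {len(lines) - 1} rows")
    taxa: list[str] = []
    rows: list[list[str]] = []
    for k, ln in enumerate(lines[1:], start=2):
        parts = ln.split(None, 1)
        if len(parts) == 1 and nchar == 0:
            parts.append("")
        if len(parts) != 2:
            raise MatrixFormatError(f"{path}, line {k}: expected 'name states'")
        name = parts[0].strip()
        states = parts[1].replace(" ", "").replace("\t", "")
        if len(states) != nchar:
            raise MatrixFormatError(
                f"{path}, line {k} ({name}): {len(states)} characters, header promises {nchar}"
            )
        taxa.append(name)
        rows.append(list(states))
    sym = _clean_symbols(np.array(rows, dtype=str) if rows else np.empty((0, 0), dtype=str), where=str(path))
    # PHYLIP rows are taxa; transpose to markers x taxa
    sym = sym.T if sym.size else sym.reshape(nchar, ntax)
    marker_ids = [f"char_{i + 1}" for i in range(nchar)]
    try:
        return PresenceAbsenceMatrix(taxa, marker_ids, sym)
    except MatrixFormatError as exc:
        raise MatrixFormatError(f"{path}: {exc}") from exc


def _read_nexus(path) -> PresenceAbsenceMatrix:
    try:
        cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:
        raise MatrixFormatError(f"could not parse NEXUS {path}: {exc}") from exc
    taxa = [t.label for t in cm.taxon_namespace]
    rows = []
    for t in cm.taxon_namespace:
        seq = cm[t]
        rows.append([str(ch) for ch in seq.symbols_as_list()])
    nchar = len(rows[0]) if rows else 0
    sym = _clean_symbols(np.array(rows, dtype=str) if rows else np.empty((0, 0), dtype=str), where=str(path))
    sym = sym.T if sym.size else sym.reshape(nchar, len(taxa))
    marker_ids = [f"char_{i + 1}" for i in range(nchar)]
    try:
        return PresenceAbsenceMatrix(taxa, marker_ids, sym)
    except MatrixFormatError as exc:
        raise MatrixFormatError(f"{path}: {exc}") from exc


# -- writers ---------------------------------------------------------------


def write_matrix(matrix: PresenceAbsenceMatrix, path, format: str = "csv-wide") -> None:
    """Write a matrix so that ``read_matrix(write_matrix(m)) == m``."""
    if format == "csv-wide":
        matrix.to_frame().to_csv(path)
        return
    if format == "phylip-discrete":
        with open(path, "w") as fh:
            fh.write(f"{matrix.n_taxa} {matrix.n_markers}\n")
            for j, name in enumerate(matrix.taxa):
                # classic PHYLIP pads/truncates names to 10 characters
                padded = (name[:10]).ljust(10)
                row = "".join(_CHAR_OF[int(s)] for s in matrix.states[:, j])
                fh.write(f"{padded} {row}\n")
        return
    if format == "nexus-standard":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_markers};\n")
            fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n')
            fh.write("    MATRIX\n")
            width = max((len(t) for t in matrix.taxa), default=8) + 2
            for j, name in enumerate(matrix.taxa):
                safe = name if " " not in name else f"'{name}'"
                row = "".join(_CHAR_OF[int(s)] for s in matrix.states[:, j])
                fh.write(f"        {safe.ljust(width)}{row}\n")
            fh.write("    ;\nEND;\n")
        return
    raise MatrixFormatError(f"unknown matrix format {format!r}; expected one of {FORMATS}")


# -- filtering -------------------------------------------------------------


@dataclass
class FilterReport:
    """Outcome of :func:`filter_informative`, marker ids listed per removal reason."""

    too_few_scored: list[str] = field(default_factory=list)
    plesiomorphic: list[str] = field(default_factory=list)
    autapomorphic: list[str] = field(default_factory=list)
    no_presence: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return (
            len(self.too_few_scored)
            + len(self.plesiomorphic)
            + len(self.autapomorphic)
            + len(self.no_presence)
        )

    def summary(self) -> dict[str, int]:
        return {
            "too_few_scored": len(self.too_few_scored),
            "plesiomorphic": len(self.plesiomorphic),
            "autapomorphic": len(self.autapomorphic),
            "no_presence": len(self.no_presence),
            "retained": len(self.retained),
        }


def filter_informative(
    matrix: PresenceAbsenceMatrix, min_taxa: int = 10
) -> tuple[PresenceAbsenceMatrix, FilterReport]:
    """Apply the standard marker ascertainment filters.

    Removes markers that are (in this order of reporting): scored in fewer
    than ``min_taxa`` taxa; plesiomorphic (all scored states 1 — the
    insertion predates the ingroup radiation); autapomorphic (present in
    exactly one scored taxon); or without any presence state.  Filtering is
    idempotent.
    """
    if min_taxa < 2:
        raise ValueError("min_taxa must be >= 2")
    scored = matrix.states != MISSING
    n_scored = scored.sum(axis=1)
    n_present = (matrix.states == PRESENT).sum(axis=1)
    report = FilterReport()
    keep_idx: list[int] = []
    for i, mid in enumerate(matrix.marker_ids):
        if n_scored[i] < min_taxa:
            report.too_few_scored.append(mid)
        elif n_scored[i] > 0 and n_present[i] == n_scored[i]:
            report.plesiomorphic.append(mid)
        elif n_present[i] == 1:
            report.autapomorphic.append(mid)
        elif n_present[i] == 0:
            report.no_presence.append(mid)
        else:
            report.retained.append(mid)
            keep_idx.append(i)
    meta = matrix.meta.iloc[keep_idx] if matrix.meta is not None else None
    filtered = PresenceAbsenceMatrix(
        matrix.taxa,
        [matrix.marker_ids[i] for i in keep_idx],
        matrix.states[keep_idx] if keep_idx else np.empty((0, matrix.n_taxa), dtype=np.int8),
        meta,
    )
    return filtered, report


# -- tree convenience re-exports ------------------------------------------

from .tree import Tree, TreeError  # noqa: E402  (public via this module too)


def read_tree(path, units: str | None = None, allow_basal_polytomy: bool = False) -> Tree:
    """Read a rooted Newick tree (see :class:`retroils.tree.Tree`)."""
    return Tree.read(path, units=units, allow_basal_polytomy=allow_basal_polytomy)


def write_tree(tree: Tree, path, include_lengths: bool = True) -> None:
    tree.write(path, include_lengths=include_lengths)
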