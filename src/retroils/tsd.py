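"""Target-site-duplication motif statistics.

LTR retrotransposon insertions are flanked by a 5-bp target site duplication
(TSD).  If the element had a target-site preference, independent insertion
into the same site — one of the two routes to homoplasy — would be more
likely.  This module summarizes the per-position nucleotide composition of
the recorded 5-bp motifs as a sequence-logo matrix (counts, frequencies,
information content in bits) and tests each position against the uniform
(no-preference) expectation.

Information content per position is ``IC_j = 2 - H_j`` where ``H_j`` is the
Shannon entropy (log base 2) of the position's nucleotide frequencies; no
small-sample correction is applied.  ``N`` letters are dropped from the
affected position's counts only, not the whole motif.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

NUCLEOTIDES = ("A", "C", "G", "T")
MOTIF_LENGTH = 5


class MotifError(ValueError):
    """A motif record is malformed; the message names it."""


@dataclass
class MotifMatrix:
    """Position weight statistics of a motif collection (4 × 5)."""

    counts: np.ndarray           # int, shape (4, 5), rows A/C/G/T
    frequencies: np.ndarray      # float, columns sum to 1 (where counted)
    information_bits: np.ndarray # shape (5,), 0..2 bits
    chi2: np.ndarray             # per-position GOF statistic vs uniform
    n_motifs: int

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def motif_matrix(motifs, ids=None) -> MotifMatrix:
    """Tabulate 5-bp motifs into counts/frequencies/IC per position.

    ``motifs`` is an iterable of 5-letter strings over ``ACGTN`` (case
    insensitive); a wrong-length or out-of-alphabet motif raises
    :class:`MotifError` naming the record.
    """
    counts = np.zeros((4, MOTIF_LENGTH), dtype=int)
    row = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    n = 0
    for k, motif in enumerate(motifs):
        label = ids[k] if ids is not None else f"record {k + 1}"
        m = str(motif).upper().strip()
        if len(m) != MOTIF_LENGTH:
            raise MotifError(f"{label}: motif {motif!r} is not {MOTIF_LENGTH} letters")
        for j, ch in enumerate(m):
            if ch == "N":
                continue
            if ch not in row:
                raise MotifError(f"{label}: motif letter {ch!r} not in ACGTN")
            counts[row[ch], j] += 1
        n += 1
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), np.nan)
        logf = np.where(freq > 0, np.log2(np.where(freq > 0, freq, 1.0)), 0.0)
    entropy = -(np.where(np.isnan(freq), 0.0, freq) * logf).sum(axis=0)
    ic = np.where(totals > 0, 2.0 - entropy, np.nan)
    chi2 = np.where(
        totals > 0,
        ((counts - totals / 4.0) ** 2 / np.where(totals > 0, totals / 4.0, 1)).sum(axis=0),
        np.nan,
    )
    return MotifMatrix(counts, freq, ic, chi2, n)


@dataclass
class PreferenceTest:
    chi2: np.ndarray           # per-position statistic (df 3)
    p_per_position: np.ndarray
    p_global: float            # Fisher's combination over the 5 positions
    n_per_position: np.ndarray


def preference_test(matrix: MotifMatrix, min_count: int = 20) -> PreferenceTest:
    """Chi-square test of per-position uniformity (no target-site preference).

    Each position is tested against equal 1/4 nucleotide frequencies (df 3);
    the five positions are combined with Fisher's method into a global
    p-value.  Positions must each carry at least ``min_count`` counted
    letters.
    """
    totals = matrix.column_totals
    if (totals < min_count).any():
        j = int(np.argmin(totals))
        raise MotifError(
            f"position {j + 1} has only {int(totals[j])} counted letters "
            f"(minimum {min_count}) — too few for the uniformity test"
        )
    p_pos = np.array([float(stats.chisquare(matrix.counts[:, j]).pvalue) for j in range(MOTIF_LENGTH)])
    combined = stats.combine_pvalues(p_pos, method="fisher")
    return PreferenceTest(matrix.chi2.copy(), p_pos, float(combined.pvalue), totals.copy())
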