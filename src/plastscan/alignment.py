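"""Pairwise whole-genome alignment of near-identical plastomes.

Two ingestion routes produce the same :class:`PairwiseAlignment` container:

* :func:`align_pair` — a built-in anchor-and-chain aligner for genome pairs of
  low divergence (p-distance up to roughly 1%): maximal unique shared k-mers
  are chained collinearly and the short inter-anchor segments are closed with
  an affine-gap global alignment (match +1, mismatch -1, gap open -4,
  gap extend -1).
* :func:`load_alignment` — a precomputed 2-record gapped FASTA alignment, as
  produced by alignment editors.

The container exposes column <-> ungapped-position maps and a consensus with
IUPAC ambiguity codes at substitution columns.
"""
from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .genome_io import AnnotatedGenome, FormatError

__all__ = [
    "PairwiseAlignment",
    "ConsensusSequence",
    "LowIdentityError",
    "align_pair",
    "load_alignment",
    "consensus",
    "write_alignment_fasta",
    "write_column_map",
]

log = logging.getLogger(__name__)

GAP = "-"

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -4, -1

_IUPAC_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


class LowIdentityError(RuntimeError):
    """The two sequences are too divergent for the built-in aligner."""


@dataclass(eq=False)
class PairwiseAlignment:
    """Two equal-length gapped rows plus coordinate maps.

    Invariants: rows have equal length; no column is a gap in both rows;
    removing the gaps from a row reproduces the input sequence.
    """

    row_a: str
    row_b: str
    id_a: str = "a"
    id_b: str = "b"
    rotation_b: int = 0  # applied to sequence b before aligning (circular input)

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise FormatError(
                f"alignment rows differ in length ({len(self.row_a)} vs {len(self.row_b)})"
            )
        self.row_a = self.row_a.upper()
        self.row_b = self.row_b.upper()

    def __len__(self) -> int:
        return len(self.row_a)

    @cached_property
    def _arr_a(self) -> np.ndarray:
        return np.frombuffer(self.row_a.encode(), dtype=np.uint8)

    @cached_property
    def _arr_b(self) -> np.ndarray:
        return np.frombuffer(self.row_b.encode(), dtype=np.uint8)

    @cached_property
    def gap_a(self) -> np.ndarray:
        """Boolean mask of columns gapped in row a."""
        return self._arr_a == ord(GAP)

    @cached_property
    def gap_b(self) -> np.ndarray:
        return self._arr_b == ord(GAP)

    @cached_property
    def col_to_pos_a(self) -> np.ndarray:
        """Ungapped position of each column in sequence a; -1 at gap columns."""
        return _col_to_pos(self.gap_a)

    @cached_property
    def col_to_pos_b(self) -> np.ndarray:
        return _col_to_pos(self.gap_b)

    @cached_property
    def pos_to_col_a(self) -> np.ndarray:
        """Alignment column of each ungapped position of sequence a."""
        return np.flatnonzero(~self.gap_a)

    @cached_property
    def pos_to_col_b(self) -> np.ndarray:
        return np.flatnonzero(~self.gap_b)

    @property
    def seq_a(self) -> str:
        return self.row_a.replace(GAP, "")

    @property
    def seq_b(self) -> str:
        return self.row_b.replace(GAP, "")

    def validate(self) -> None:
        """Assert the container invariants (no both-gap column)."""
        if bool((self.gap_a & self.gap_b).any()):
            raise FormatError("alignment contains a column gapped in both rows")

    def slice(self, col_start: int, col_end: int) -> "PairwiseAlignment":
        """Sub-alignment over columns ``[col_start, col_end)``."""
        if not (0 <= col_start <= col_end <= len(self)):
            raise IndexError(f"column slice ({col_start}, {col_end}) out of bounds")
        return PairwiseAlignment(
            row_a=self.row_a[col_start:col_end],
            row_b=self.row_b[col_start:col_end],
            id_a=self.id_a, id_b=self.id_b,
        )


def _col_to_pos(gap_mask: np.ndarray) -> np.ndarray:
    pos = np.cumsum(~gap_mask) - 1
    pos[gap_mask] = -1
    return pos


@dataclass
class ConsensusSequence:
    """Column-wise merge of a pairwise alignment: IUPAC code at substitution
    columns, the present base at indel columns; no column is dropped."""

    bases: str
    at_content: float
    column_map: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.bases)


# ---------------------------------------------------------------------------
# Built-in aligner
# ---------------------------------------------------------------------------


def align_pair(a: AnnotatedGenome | str, b: AnnotatedGenome | str,
               k: int = 21, band: int = 200) -> PairwiseAlignment:
    """Align two near-identical genomes.

    Maximal unique shared k-mers are collected as anchors, the longest
    collinear anchor subset is chained, and the inter-anchor segments are
    closed with an affine-gap global alignment. Circular genomes are rotated
    to the first chained anchor before aligning so origin differences do not
    surface as terminal indels.

    Raises :class:`LowIdentityError` when chained anchors cover less than half
    of the shorter genome (the pair is then outside the supported divergence
    range and an external aligner should be used).
    """
    sa = a.sequence if isinstance(a, AnnotatedGenome) else str(a).upper()
    sb = b.sequence if isinstance(b, AnnotatedGenome) else str(b).upper()
    id_a = a.id if isinstance(a, AnnotatedGenome) else "a"
    id_b = b.id if isinstance(b, AnnotatedGenome) else "b"
    circular = (
        a.circular if isinstance(a, AnnotatedGenome) else False
    ) and (b.circular if isinstance(b, AnnotatedGenome) else False)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")

    rotation = 0
    anchors = _chain_anchors(sa, sb, k)
    if circular and anchors:
        pa0, pb0 = anchors[0][:2]
        if pa0 != pb0 and abs(pa0 - pb0) > band:
            rotation = (pb0 - pa0) % len(sb)
            sb = sb[rotation:] + sb[:rotation]
            anchors = _chain_anchors(sa, sb, k)
    coverage = sum(length for _, _, length in anchors)
    if coverage < 0.5 * min(len(sa), len(sb)):
        raise LowIdentityError(
            f"anchor coverage {coverage} bp < 50% of the shorter genome; "
            "sequences too divergent for the built-in aligner — supply an "
            "external alignment instead"
        )

    parts_a: list[str] = []
    parts_b: list[str] = []
    cur_a = cur_b = 0
    for pa, pb, length in anchors:
        trim = max(cur_a - pa, cur_b - pb, 0)
        pa, pb, length = pa + trim, pb + trim, length - trim
        if length <= 0:
            continue
        ga, gb = _affine_global(sa[cur_a:pa], sb[cur_b:pb], band)
        parts_a.append(ga)
        parts_b.append(gb)
        parts_a.append(sa[pa : pa + length])
        parts_b.append(sb[pb : pb + length])
        cur_a, cur_b = pa + length, pb + length
    ga, gb = _affine_global(sa[cur_a:], sb[cur_b:], band)
    parts_a.append(ga)
    parts_b.append(gb)

    aln = PairwiseAlignment("".join(parts_a), "".join(parts_b),
                            id_a=id_a, id_b=id_b, rotation_b=rotation)
    # round-trip invariant is an internal correctness assertion
    assert aln.seq_a == sa and aln.seq_b == sb, "aligner round-trip failure"
    aln.validate()
    return aln


def _chain_anchors(sa: str, sb: str, k: int) -> list[tuple[int, int, int]]:
    """Longest collinear chain of unique shared k-mers, merged into maximal
    co-diagonal runs ``(pos_a, pos_b, length)``."""
    def unique_kmers(s: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            counts[kmer] = i if kmer not in counts else -1
        return {kmer: i for kmer, i in counts.items() if i >= 0}

    ka = unique_kmers(sa)
    kb = unique_kmers(sb)
    pairs = sorted((pa, kb[kmer]) for kmer, pa in ka.items() if kmer in kb)
    if not pairs:
        return []
    # longest strictly-increasing subsequence in pos_b (pos_a already sorted)
    tails: list[int] = []
    tail_idx: list[int] = []
    parent = [-1] * len(pairs)
    for i, (_, pb) in enumerate(pairs):
        j = bisect.bisect_left(tails, pb)
        if j == len(tails):
            tails.append(pb)
            tail_idx.append(i)
        else:
            tails[j] = pb
            tail_idx[j] = i
        parent[i] = tail_idx[j - 1] if j > 0 else -1
    chain = []
    i = tail_idx[-1]
    while i >= 0:
        chain.append(pairs[i])
        i = parent[i]
    chain.reverse()
    # merge co-diagonal overlapping/adjacent seeds into maximal runs
    runs: list[list[int]] = []
    for pa, pb in chain:
        if runs and pa - pb == runs[-1][0] - runs[-1][1] and pa <= runs[-1][0] + runs[-1][2]:
            runs[-1][2] = pa + k - runs[-1][0]
        else:
            runs.append([pa, pb, k])
    return [tuple(r) for r in runs]


def _affine_global(x: str, y: str, band: int = 200) -> tuple[str, str]:
    """Global alignment with affine gaps (scores per module constants).

    Returns the two gapped rows. Intended for the short inter-anchor segments
    of near-identical genomes; very large segments (> ~4e6 cells) fall back to
    edit-distance alignment via edlib when available.
    """
    n, m = len(x), len(y)
    if n == 0:
        return GAP * m, y
    if m == 0:
        return x, GAP * n
    if n * m > 4_000_000:
        return _edlib_global(x, y)

    neg = np.int32(-(10 ** 8))
    M = np.full((n + 1, m + 1), neg, dtype=np.int32)
    Ix = np.full((n + 1, m + 1), neg, dtype=np.int32)  # gap in y (consumes x)
    Iy = np.full((n + 1, m + 1), neg, dtype=np.int32)  # gap in x (consumes y)
    M[0, 0] = 0
    Ix[1:, 0] = GAP_OPEN + GAP_EXTEND * np.arange(1, n + 1)
    Iy[0, 1:] = GAP_OPEN + GAP_EXTEND * np.arange(1, m + 1)
    xa = np.frombuffer(x.encode(), dtype=np.uint8)
    ya = np.frombuffer(y.encode(), dtype=np.uint8)
    jj = np.arange(m)
    for i in range(1, n + 1):
        sub = np.where(ya == xa[i - 1], MATCH, MISMATCH).astype(np.int32)
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        Ix[i] = np.maximum(M[i - 1] + GAP_OPEN, Ix[i - 1]) + GAP_EXTEND
        # Iy[i, j] = GE*j + max_{k<j} (best_row_i[k] + GO - GE*k)
        best_row = np.maximum(M[i], Ix[i])
        w = best_row[:-1] + GAP_OPEN - GAP_EXTEND * jj
        Iy[i, 1:] = np.maximum.accumulate(w) + GAP_EXTEND * (jj + 1)
    # traceback
    out_x: list[str] = []
    out_y: list[str] = []
    i, j = n, m
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    while i > 0 or j > 0:
        if state == 0:  # M: consumed x[i-1], y[j-1]
            out_x.append(x[i - 1])
            out_y.append(y[j - 1])
            i, j = i - 1, j - 1
            state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
        elif state == 1:  # Ix: consumed x[i-1]
            out_x.append(x[i - 1])
            out_y.append(GAP)
            came_open = M[i - 1, j] + GAP_OPEN + GAP_EXTEND == Ix[i, j]
            i -= 1
            state = 0 if came_open else 1
            if i == 0 and j > 0:
                state = 2
        else:  # Iy: consumed y[j-1]
            out_x.append(GAP)
            out_y.append(y[j - 1])
            j -= 1
            # re-derive state: extension iff previous Iy explains the score
            if j > 0 and Iy[i, j] + GAP_EXTEND == Iy[i, j + 1]:
                state = 2
            else:
                state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]])) if (i or j) else 0
    return "".join(reversed(out_x)), "".join(reversed(out_y))


def _edlib_global(x: str, y: str) -> tuple[str, str]:
    try:
        import edlib
    except ImportError as exc:  # pragma: no cover
        raise LowIdentityError(
            "inter-anchor segment too large for exact affine alignment and "
            "edlib is unavailable; supply an external alignment"
        ) from exc
    res = edlib.align(x, y, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, x, y)
    return nice["query_aligned"], nice["target_aligned"]


# ---------------------------------------------------------------------------
# Loading external alignments
# ---------------------------------------------------------------------------


def load_alignment(path: str | Path) -> PairwiseAlignment:
    """Load a gapped FASTA alignment with exactly two records.

    Rows are uppercased; columns gapped in both rows carry no pairwise
    information and are removed (the count is logged).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise FormatError(
            f"{path}: expected exactly 2 aligned records, found {len(records)}"
        )
    ra, rb = (str(r.seq).upper() for r in records)
    if len(ra) != len(rb):
        raise FormatError(
            f"{path}: aligned rows differ in length ({len(ra)} vs {len(rb)})"
        )
    arr_a = np.frombuffer(ra.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(rb.encode(), dtype=np.uint8)
    both_gap = (arr_a == ord(GAP)) & (arr_b == ord(GAP))
    n_dropped = int(both_gap.sum())
    if n_dropped:
        log.info("%s: removed %d columns gapped in both rows", path, n_dropped)
        keep = ~both_gap
        ra = arr_a[keep].tobytes().decode()
        rb = arr_b[keep].tobytes().decode()
    aln = PairwiseAlignment(ra, rb, id_a=records[0].id, id_b=records[1].id)
    aln.validate()
    return aln


def write_alignment_fasta(aln: PairwiseAlignment, path: str | Path) -> None:
    """Write the alignment as 2-record gapped FASTA (the dialect
    :func:`load_alignment` reads)."""
    with open(path, "w") as fh:
        for rid, row in ((aln.id_a, aln.row_a), (aln.id_b, aln.row_b)):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i : i + 70] + "\n")


def write_column_map(aln: PairwiseAlignment, path: str | Path) -> None:
    """Write the column map as TSV (column, pos_a, pos_b); -1 marks a gap."""
    pa, pb = aln.col_to_pos_a, aln.col_to_pos_b
    with open(path, "w") as fh:
        fh.write("column\tpos_a\tpos_b\n")
        for c in range(len(aln)):
            fh.write(f"{c}\t{pa[c]}\t{pb[c]}\n")


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def consensus(aln: PairwiseAlignment) -> ConsensusSequence:
    """Column-wise consensus: equal bases pass through, substitutions become
    the IUPAC ambiguity code of the two bases, indel columns keep the present
    base. Length equals the number of alignment columns."""
    out = []
    for ca, cb in zip(aln.row_a, aln.row_b):
        if ca == cb:
            out.append(ca)
        elif ca == GAP:
            out.append(cb)
        elif cb == GAP:
            out.append(ca)
        else:
            out.append(_IUPAC_PAIR.get(frozenset((ca, cb)), "N"))
    bases = "".join(out)
    at = bases.count("A") + bases.count("T")
    acgt = at + bases.count("G") + bases.count("C")
    return ConsensusSequence(
        bases=bases,
        at_content=at / acgt if acgt else float("nan"),
        column_map=np.arange(len(bases)),
    )
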