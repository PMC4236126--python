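"""Variant calling and mutational-context statistics on a pairwise alignment.

SNPs are columns where both rows carry determined, unequal bases; an indel
event is one maximal run of gap characters within one row; inversions are
mismatch blocks whose reverse complement matches the partner at high
identity. Indel events are classified into three mutational classes:

* ``polyN`` — a length-variable homopolymer locus: the indel is a single
  repeated nucleotide and the maximal homopolymer run through the locus
  (indel plus same-base extension into both flanks) reaches at least 7 bases;
* ``SSR_or_inversion`` — the indel equals one adjacent copy of a multi-base
  motif (tandem duplication/deletion) or the reverse complement of an
  adjacent equal-length substring (inverted repeat);
* ``other`` — everything else.

The AT context of variation is summarized two ways: the base composition of
the indel sequences per class, and the AT content of windows of increasing
radius around each SNP on the consensus, both compared with the genome-wide
consensus AT content.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, ConsensusSequence, PairwiseAlignment
from .genome_io import revcomp

__all__ = [
    "SNP",
    "IndelEvent",
    "Inversion",
    "VariantSet",
    "SNPNeighborhoodProfile",
    "POLY_N",
    "SSR_OR_INVERSION",
    "OTHER",
    "call_snps",
    "call_indels",
    "call_variants",
    "indel_pos_a",
    "classify_indel",
    "detect_inversions",
    "column_census",
    "indel_at_profiles",
    "snp_neighborhood_at",
    "seq_at_fraction",
    "DEFAULT_RADII",
]

POLY_N = "polyN"
SSR_OR_INVERSION = "SSR_or_inversion"
OTHER = "other"

DEFAULT_RADII = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 20, 50, 100)


@dataclass(frozen=True)
class SNP:
    column: int
    pos_a: int
    pos_b: int
    base_a: str
    base_b: str


@dataclass
class IndelEvent:
    columns: tuple[int, int]  # half-open column interval of the gap run
    carrier: str  # "a" or "b": the row holding the gap
    indel_seq: str  # the inserted/deleted bases, read from the non-gap row
    length: int
    flank_left: str = ""
    flank_right: str = ""
    klass: str | None = None
    complex: bool = False  # abuts a gap run in the opposite row


@dataclass(frozen=True)
class Inversion:
    interval_a: tuple[int, int]  # ungapped positions on sequence a
    interval_b: tuple[int, int]
    length: int
    palindromic: bool = False


@dataclass
class VariantSet:
    snps: list[SNP] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)
    inversions: list[Inversion] = field(default_factory=list)


@dataclass
class SNPNeighborhoodProfile:
    radii: tuple[int, ...]
    at: np.ndarray  # (n_snps, n_radii); NaN where no unambiguous base in window
    truncated: np.ndarray  # bool (n_snps, n_radii): window hit a sequence end
    genome_at: float

    def mean_by_radius(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.at, axis=0)


def seq_at_fraction(seq: str) -> float:
    """(A+T)/(A+C+G+T) over determined bases; NaN if none."""
    up = seq.upper()
    at = up.count("A") + up.count("T")
    acgt = at + up.count("G") + up.count("C")
    return at / acgt if acgt else float("nan")


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


def _masks(aln: PairwiseAlignment):
    a, b = aln._arr_a, aln._arr_b
    det_a = np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8))
    det_b = np.isin(b, np.frombuffer(b"ACGT", dtype=np.uint8))
    return a, b, det_a, det_b


def call_snps(aln: PairwiseAlignment) -> list[SNP]:
    """One SNP per column where both rows have determined (ACGT), unequal
    bases. Columns with N or IUPAC ambiguity in either row are skipped (see
    :func:`column_census` for their count)."""
    a, b, det_a, det_b = _masks(aln)
    snp_mask = det_a & det_b & (a != b)
    cols = np.flatnonzero(snp_mask)
    pa, pb = aln.col_to_pos_a, aln.col_to_pos_b
    return [
        SNP(column=int(c), pos_a=int(pa[c]), pos_b=int(pb[c]),
            base_a=chr(a[c]), base_b=chr(b[c]))
        for c in cols
    ]


def _gap_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open intervals."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [len(mask)]))
    return list(zip(starts.tolist(), ends.tolist()))


def call_indels(aln: PairwiseAlignment, flank_width: int = 20) -> list[IndelEvent]:
    """One event per maximal run of contiguous gap characters within one row.

    Runs in different rows separated by at least one non-gap column are
    distinct events; abutting runs in opposite rows are both reported with
    the ``complex`` flag set. Flanks are read from the non-gap row's ungapped
    sequence.
    """
    events: list[IndelEvent] = []
    runs_a = _gap_runs(aln.gap_a)
    runs_b = _gap_runs(aln.gap_b)
    seqs = {"a": aln.seq_a, "b": aln.seq_b}
    for carrier, runs, other_pos in (
        ("a", runs_a, aln.col_to_pos_b),
        ("b", runs_b, aln.col_to_pos_a),
    ):
        other = seqs["b"] if carrier == "a" else seqs["a"]
        for start, end in runs:
            p0 = int(other_pos[start])
            length = end - start
            events.append(IndelEvent(
                columns=(int(start), int(end)),
                carrier=carrier,
                indel_seq=other[p0 : p0 + length],
                length=length,
                flank_left=other[max(0, p0 - flank_width) : p0],
                flank_right=other[p0 + length : p0 + length + flank_width],
            ))
    # flag abutting opposite-row runs as complex
    a_edges = set()
    for s, e in runs_a:
        a_edges.update((s, e))
    b_edges = set()
    for s, e in runs_b:
        b_edges.update((s, e))
    for ev in events:
        s, e = ev.columns
        edges = b_edges if ev.carrier == "a" else a_edges
        if s in edges or e in edges:
            ev.complex = True
    events.sort(key=lambda ev: ev.columns)
    return events


def indel_pos_a(aln: PairwiseAlignment, ev: IndelEvent) -> int:
    """Position of an indel event on the ungapped genome-A coordinate system.

    For a deletion (gap in row b) this is the first deleted A base; for an
    insertion (gap in row a) it is the A position before which the B bases
    are inserted.
    """
    c0 = ev.columns[0]
    p = int(aln.col_to_pos_a[c0])
    if p >= 0:
        return p
    prev = aln.col_to_pos_a[:c0]
    nz = prev[prev >= 0]
    return int(nz[-1]) + 1 if nz.size else 0


def column_census(aln: PairwiseAlignment) -> dict[str, int]:
    """Partition of alignment columns: identical, snp, ambiguous, gap.

    The four counts sum to the total number of columns.
    """
    a, b, det_a, det_b = _masks(aln)
    gap = aln.gap_a | aln.gap_b
    both_det = det_a & det_b
    snp = both_det & (a != b)
    identical = both_det & (a == b)
    ambiguous = ~gap & ~both_det
    return {
        "identical": int(identical.sum()),
        "snp": int(snp.sum()),
        "ambiguous": int(ambiguous.sum()),
        "gap": int(gap.sum()),
        "total": len(aln),
    }


def call_variants(aln: PairwiseAlignment, classify: bool = True,
                  with_inversions: bool = True,
                  flank_width: int = 20) -> VariantSet:
    """Call and classify all variant types on one alignment."""
    snps = call_snps(aln)
    indels = call_indels(aln, flank_width=flank_width)
    if classify:
        for ev in indels:
            ev.klass = classify_indel(ev)
    inversions = detect_inversions(aln) if with_inversions else []
    return VariantSet(snps=snps, indels=indels, inversions=inversions)


# ---------------------------------------------------------------------------
# Indel classification
# ---------------------------------------------------------------------------


def classify_indel(ev: IndelEvent) -> str:
    """Assign the mutational class of an indel event.

    Decision order: ``polyN`` before ``SSR_or_inversion`` before ``other``
    (a 7-base homopolymer indel is also a trivial SSR; the homopolymer
    reading wins).
    """
    s = ev.indel_seq.upper()
    if not s:
        raise ValueError("indel event with empty sequence")
    left = ev.flank_left.upper()
    right = ev.flank_right.upper()
    if len(set(s)) == 1:
        base = s[0]
        run = len(s)
        for ch in reversed(left):
            if ch != base:
                break
            run += 1
        for ch in right:
            if ch != base:
                break
            run += 1
        if run >= 7:
            return POLY_N
    if len(s) >= 2:
        rc = revcomp(s)
        if (left.endswith(s) or right.startswith(s)
                or left.endswith(rc) or right.startswith(rc)):
            return SSR_OR_INVERSION
    return OTHER


# ---------------------------------------------------------------------------
# Inversions
# ---------------------------------------------------------------------------


def detect_inversions(aln: PairwiseAlignment, min_inv_len: int = 10,
                      min_identity: float = 0.95) -> list[Inversion]:
    """Find inverted segments: maximal runs of at least ``min_inv_len``
    consecutive mismatch columns whose reverse complement matches the partner
    block at ``>= min_identity``."""
    a, b, det_a, det_b = _masks(aln)
    mismatch = det_a & det_b & (a != b)
    out: list[Inversion] = []
    for start, end in _gap_runs(mismatch):
        if end - start < min_inv_len:
            continue
        seg_a = aln.row_a[start:end]
        seg_b = aln.row_b[start:end]
        rc_b = revcomp(seg_b)
        ident = sum(x == y for x, y in zip(seg_a, rc_b)) / len(seg_a)
        if ident >= min_identity:
            pa, pb = aln.col_to_pos_a, aln.col_to_pos_b
            out.append(Inversion(
                interval_a=(int(pa[start]), int(pa[end - 1]) + 1),
                interval_b=(int(pb[start]), int(pb[end - 1]) + 1),
                length=end - start,
                palindromic=(seg_a == revcomp(seg_a)),
            ))
    return out


# ---------------------------------------------------------------------------
# AT-content context
# ---------------------------------------------------------------------------


def indel_at_profiles(events: list[IndelEvent],
                      genome_at: float | None = None) -> dict[str, dict]:
    """AT content of the indel sequences, grouped by class.

    Returns per class a summary dict (n, min, q1, median, mean, q3, max,
    values); an empty class yields an empty summary.
    """
    groups: dict[str, list[float]] = {POLY_N: [], SSR_OR_INVERSION: [], OTHER: []}
    for ev in events:
        if ev.klass is None:
            raise ValueError("events must be classified before profiling")
        groups.setdefault(ev.klass, []).append(seq_at_fraction(ev.indel_seq))
    out: dict[str, dict] = {}
    for klass, vals in groups.items():
        arr = np.array([v for v in vals if not np.isnan(v)])
        if arr.size == 0:
            out[klass] = {"n": 0, "values": []}
            continue
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        out[klass] = {
            "n": int(arr.size),
            "min": float(arr.min()),
            "q1": float(q1),
            "median": float(med),
            "mean": float(arr.mean()),
            "q3": float(q3),
            "max": float(arr.max()),
            "values": arr.tolist(),
        }
    if genome_at is not None:
        out["genome_at"] = genome_at
    return out


def snp_neighborhood_at(
    consensus: ConsensusSequence,
    snps: list[SNP],
    radii: tuple[int, ...] = DEFAULT_RADII,
) -> SNPNeighborhoodProfile:
    """AT content of the consensus bases flanking each SNP.

    For radius ``r`` the window is the ``r`` bases on each side of the SNP
    column, excluding the SNP site itself. Windows truncated at a sequence
    end are flagged, not padded. Ambiguity codes inside a window are excluded
    from numerator and denominator.
    """
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    bases = consensus.bases
    n = len(bases)
    arr = np.frombuffer(bases.encode(), dtype=np.uint8)
    is_at = np.isin(arr, np.frombuffer(b"AT", dtype=np.uint8))
    is_det = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    cum_at = np.concatenate(([0], np.cumsum(is_at)))
    cum_det = np.concatenate(([0], np.cumsum(is_det)))

    at = np.full((len(snps), len(radii)), np.nan)
    truncated = np.zeros((len(snps), len(radii)), dtype=bool)
    for i, snp in enumerate(snps):
        c = snp.column
        for j, r in enumerate(radii):
            lo, hi = c - r, c + r + 1
            if lo < 0 or hi > n:
                truncated[i, j] = True
                lo, hi = max(lo, 0), min(hi, n)
            det = (cum_det[hi] - cum_det[lo]) - int(is_det[c])
            if det == 0:
                continue
            at_count = (cum_at[hi] - cum_at[lo]) - int(is_at[c])
            at[i, j] = at_count / det
    return SNPNeighborhoodProfile(
        radii=tuple(radii), at=at, truncated=truncated,
        genome_at=consensus.at_content,
    )
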