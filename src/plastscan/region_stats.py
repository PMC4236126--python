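"""Per-region and whole-genome variability statistics.

For each noncoding region the alignment slice is taken on reference (genome A)
coordinates and summarized as:

* SNP, indel-event and inversion counts restricted to the slice;
* PIC (potentially informative characters) = SNPs + indels + inversions;
* p-distance = SNPs / (columns with a determined base in both rows), i.e.
  indel and ambiguity columns are excluded from the denominator.

Regions are ranked by p-distance or PIC count, and whole-consensus tracks
(SNP/indel counts and AT content per 500 bp slot) are produced for
genome-scale inspection.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import ConsensusSequence, PairwiseAlignment
from .genome_io import GenomicRegion
from .variants import (
    VariantSet,
    call_indels,
    call_snps,
    classify_indel,
    detect_inversions,
    seq_at_fraction,
)

__all__ = [
    "RegionStats",
    "GenomePairSummary",
    "region_slice",
    "compute_region_stats",
    "rank_regions",
    "whole_genome_summary",
    "sliding_windows",
    "stats_table",
]


@dataclass
class RegionStats:
    region: GenomicRegion
    aligned_length: int
    snps: int
    indels: int
    inversions: int
    pics: int
    p_distance: float | None  # None when the slice has no comparable columns
    contains_homopolymer: bool = False
    complex_indels: bool = False


@dataclass(frozen=True)
class GenomePairSummary:
    id_a: str
    id_b: str
    p_distance: float
    aligned_length: int
    length_difference: int
    snps: int
    indels: int


def region_slice(aln: PairwiseAlignment, region: GenomicRegion) -> PairwiseAlignment:
    """Columns covering ``region`` (coordinates on genome A).

    The slice spans ``[col(start), col(end))``, so insertion columns of B
    that precede a base inside the region are included while those abutting
    the left boundary are not (left-closed / right-open rule).
    """
    if region.wraps:
        raise ValueError(
            f"region {region.name!r} wraps the origin; rotate the genomes first"
        )
    start, end = region.interval
    n_a = int(aln.pos_to_col_a.size)
    if not (0 <= start < end <= n_a):
        raise IndexError(
            f"region {region.name!r} ({start}, {end}) outside genome of length {n_a}"
        )
    col_start = int(aln.pos_to_col_a[start])
    col_end = int(aln.pos_to_col_a[end]) if end < n_a else len(aln)
    return aln.slice(col_start, col_end)


def compute_region_stats(sub: PairwiseAlignment, region: GenomicRegion,
                         with_inversions: bool = True) -> RegionStats:
    """Variant counts, PICs and p-distance for one region slice."""
    snps = call_snps(sub)
    indels = call_indels(sub)
    for ev in indels:
        ev.klass = classify_indel(ev)
    inversions = detect_inversions(sub) if with_inversions else []
    denom = _comparable_columns(sub)
    p = len(snps) / denom if denom else None
    return RegionStats(
        region=region,
        aligned_length=len(sub),
        snps=len(snps),
        indels=len(indels),
        inversions=len(inversions),
        pics=len(snps) + len(indels) + len(inversions),
        p_distance=p,
        contains_homopolymer=any(ev.klass == "polyN" for ev in indels),
        complex_indels=any(ev.complex for ev in indels),
    )


def _comparable_columns(aln: PairwiseAlignment) -> int:
    """Columns with a determined (ACGT) base in both rows."""
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    return int((np.isin(aln._arr_a, acgt) & np.isin(aln._arr_b, acgt)).sum())


def stats_table(stats: list[RegionStats]) -> pd.DataFrame:
    rows = []
    for st in stats:
        rows.append({
            "region": st.region.name,
            "kind": st.region.kind,
            "start": st.region.interval[0],
            "end": st.region.interval[1],
            "copy_of": st.region.copy_of or "",
            "aligned_length": st.aligned_length,
            "snps": st.snps,
            "indels": st.indels,
            "inversions": st.inversions,
            "pics": st.pics,
            "p_distance": st.p_distance if st.p_distance is not None else np.nan,
        })
    return pd.DataFrame(rows)


def rank_regions(stats: list[RegionStats], key: str = "p_distance",
                 top_n: int = 30, include_ir_copies: bool = False) -> pd.DataFrame:
    """Rank regions by ``key`` (descending).

    Ties break on the other key (descending), then aligned length
    (descending), then name (ascending). IR duplicate regions (``copy_of``
    set) are excluded by default so each region counts once per genome pair.
    """
    if key not in ("p_distance", "pics"):
        raise ValueError("key must be 'p_distance' or 'pics'")
    if not stats:
        raise ValueError("no region statistics to rank")
    keep = stats if include_ir_copies else [s for s in stats if s.region.copy_of is None]
    df = stats_table(keep)
    other = "pics" if key == "p_distance" else "p_distance"
    df = df.sort_values(
        by=[key, other, "aligned_length", "region"],
        ascending=[False, False, False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    # Table-style presentation of p-distance (×10^3, 2 decimals)
    df["p_distance_x1000"] = (df["p_distance"] * 1000).round(2)
    return df.head(top_n)


def whole_genome_summary(aln: PairwiseAlignment) -> GenomePairSummary:
    """Genome-pair statistics over the full alignment."""
    snps = call_snps(aln)
    indels = call_indels(aln)
    denom = _comparable_columns(aln)
    len_a = len(aln.seq_a)
    len_b = len(aln.seq_b)
    return GenomePairSummary(
        id_a=aln.id_a,
        id_b=aln.id_b,
        p_distance=len(snps) / denom if denom else 0.0,
        aligned_length=len(aln),
        length_difference=abs(len_a - len_b),
        snps=len(snps),
        indels=len(indels),
    )


def sliding_windows(consensus: ConsensusSequence, variants: VariantSet,
                    window: int = 500) -> pd.DataFrame:
    """Non-overlapping windows ("slots") of the consensus.

    Each window records its SNP count (assigned by consensus position), indel
    count (an event belongs to the window containing its first column), AT
    content, and AT content relative to the whole consensus. The final short
    window is kept and flagged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(consensus)
    starts = list(range(0, n, window))
    snp_counts = np.zeros(len(starts), dtype=int)
    indel_counts = np.zeros(len(starts), dtype=int)
    for snp in variants.snps:
        snp_counts[snp.column // window] += 1
    for ev in variants.indels:
        indel_counts[ev.columns[0] // window] += 1
    rows = []
    for i, s in enumerate(starts):
        e = min(s + window, n)
        at = seq_at_fraction(consensus.bases[s:e])
        rows.append({
            "start": s,
            "end": e,
            "snp_count": int(snp_counts[i]),
            "indel_count": int(indel_counts[i]),
            "at_content": at,
            "at_relative": at / consensus.at_content if consensus.at_content else np.nan,
            "short": e - s < window,
        })
    return pd.DataFrame(rows)
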