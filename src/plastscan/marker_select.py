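"""Marker-selection heuristic for ranked noncoding regions.

The screening mirrors how Sanger-based resequencing projects pick amplicons:

* amplicons (region length plus a flanking-primer allowance) must fall in a
  size window that one PCR and at most two sequencing reads can cover;
* polyA/T stretches longer than seven bases (microsatellites) cause slippage,
  so a read is reliable only up to the end of the first such stretch it
  crosses. One microsatellite can be bridged by two reads that meet at it;
  several microsatellites in one region leave uncovered sequence between
  them and the region is dismissed.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .region_stats import RegionStats, rank_regions

__all__ = [
    "HomopolymerLocus",
    "MarkerCandidate",
    "find_homopolymers",
    "select_markers",
    "candidates_table",
]


@dataclass(frozen=True)
class HomopolymerLocus:
    base: str
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class MarkerCandidate:
    name: str
    rank_p: int
    rank_pic: int
    length: int
    amplicon: int
    homopolymer_loci: list[HomopolymerLocus]
    reads_required: str  # "1", "2", ">2"
    verdict: str  # recommended | conditional | dismissed
    reason: str


def find_homopolymers(seq: str, min_len: int = 8,
                      bases: tuple[str, ...] = ("A", "T")) -> list[HomopolymerLocus]:
    """Maximal single-base runs of length >= ``min_len`` over ``bases``.

    The default threshold of 8 reads "larger than seven nucleotides"
    literally: a 7-base run is not a microsatellite, an 8-base run is.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    out: list[HomopolymerLocus] = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if seq[i] in bases and j - i >= min_len:
            out.append(HomopolymerLocus(base=seq[i], start=i, length=j - i))
        i = j
    return out


def _two_read_coverage(length: int, loci: list[HomopolymerLocus],
                       read_len: int) -> bool:
    """Can two end-anchored reads cover the amplicon?

    A read is reliable up to (and including) the first microsatellite it
    crosses, or its read length, whichever ends first; reads start at the
    two amplicon ends.
    """
    if not loci:
        return True
    left_cover = min(read_len, loci[0].end)
    right_cover_from = max(length - read_len, loci[-1].start)
    return left_cover >= right_cover_from


def select_markers(
    stats: list[RegionStats],
    sequences: dict[str, str],
    size_min: int = 900,
    size_max: int = 1300,
    pad: int = 150,
    read_len: int = 1000,
    hp_min_len: int = 8,
) -> list[MarkerCandidate]:
    """Screen ranked regions for sequencing-efficient markers.

    ``sequences`` maps region name to its reference sequence. ``pad`` models
    the primer-to-region distance, so the amplicon is ``length + pad``;
    candidates are regions whose amplicon falls within
    ``[size_min, size_max]``. ``read_len`` is the reliable Sanger read length
    (stated premise: 800-1000 bases; the conservative end is not used so a
    single read may cover a 1000 bp amplicon).

    Verdicts: ``recommended`` (no microsatellite), ``conditional`` (one
    microsatellite, coverable by two reads meeting at it), ``dismissed``
    (two reads cannot cover all inter-microsatellite intervals; this greedy
    two-read check is our formalization of the qualitative rule).
    """
    rank_p = {r.region: int(r["rank"]) for _, r in
              rank_regions(stats, key="p_distance", top_n=len(stats)).iterrows()}
    rank_pic = {r.region: int(r["rank"]) for _, r in
                rank_regions(stats, key="pics", top_n=len(stats)).iterrows()}
    out: list[MarkerCandidate] = []
    for st in stats:
        name = st.region.name
        if st.region.copy_of is not None or name not in sequences:
            continue
        length = st.region.length
        amplicon = length + pad
        if not (size_min <= amplicon <= size_max):
            continue
        loci = find_homopolymers(sequences[name], min_len=hp_min_len)
        covered = _two_read_coverage(amplicon, _pad_loci(loci, pad), read_len)
        if not loci:
            reads = "1" if amplicon <= read_len else "2"
            verdict = "recommended"
            reason = (
                "no polyA/T microsatellite; one read covers the amplicon"
                if reads == "1"
                else "no polyA/T microsatellite; two reads cover the amplicon"
            )
        elif len(loci) == 1 and covered:
            reads = "2"
            verdict = "conditional"
            reason = "one polyA/T microsatellite; two reads meet at it"
        elif covered:
            reads = "2"
            verdict = "conditional"
            reason = f"{len(loci)} microsatellites but two reads still cover all intervals"
        else:
            reads = ">2"
            verdict = "dismissed"
            reason = (
                f"{len(loci)} polyA/T microsatellites; two reads cannot cover "
                "the intervals between them"
            )
        out.append(MarkerCandidate(
            name=name,
            rank_p=rank_p.get(name, 0),
            rank_pic=rank_pic.get(name, 0),
            length=length,
            amplicon=amplicon,
            homopolymer_loci=loci,
            reads_required=reads,
            verdict=verdict,
            reason=reason,
        ))
    out.sort(key=lambda c: (c.rank_p or 10 ** 6))
    return out


def _pad_loci(loci: list[HomopolymerLocus], pad: int) -> list[HomopolymerLocus]:
    # region sequence coordinates -> amplicon coordinates (primer pad split
    # evenly on both sides)
    half = pad // 2
    return [HomopolymerLocus(l.base, l.start + half, l.length) for l in loci]


def candidates_table(candidates: list[MarkerCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append({
            "region": c.name,
            "rank_p": c.rank_p,
            "rank_pic": c.rank_pic,
            "length": c.length,
            "amplicon": c.amplicon,
            "n_microsatellites": len(c.homopolymer_loci),
            "microsatellites": ";".join(
                f"{l.base}x{l.length}@{l.start}" for l in c.homopolymer_loci
            ),
            "reads_required": c.reads_required,
            "verdict": c.verdict,
            "reason": c.reason,
        })
    return pd.DataFrame(rows)
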