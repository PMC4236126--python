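"""Annotated plastome I/O, quadripartite structure, and noncoding-region extraction.

A plastid genome is modelled as a circular DNA sequence with a feature
annotation (genes, tRNAs, rRNAs, multi-exon genes) and, usually, the canonical
quadripartite layout: a large single-copy region (LSC), a small single-copy
region (SSC), and two inverted-repeat copies (IRa/IRb) that are reverse
complements of each other. The noncoding regions of interest for marker
screening are the intergenic spacers between consecutive annotated features
and the introns between consecutive exons of one gene.

All coordinates are 0-based half-open internally; GenBank's 1-based inclusive
convention is converted at the I/O boundary.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Feature",
    "AnnotatedGenome",
    "QuadripartiteStructure",
    "GenomicRegion",
    "FormatError",
    "ValidationError",
    "StructureNotFoundError",
    "read_annotated_genome",
    "write_genbank",
    "write_feature_table",
    "read_feature_table",
    "write_regions_bed",
    "detect_quadripartite",
    "extract_noncoding_regions",
    "gc_content",
    "at_content",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

FEATURE_KINDS = ("gene", "tRNA", "rRNA", "exon", "intron", "IR")


class FormatError(ValueError):
    """Input file does not conform to the expected format."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


class StructureNotFoundError(RuntimeError):
    """No inverted-repeat pair satisfying the search constraints exists."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """One annotated feature: a gene, tRNA, rRNA or inverted-repeat copy.

    ``intervals`` is an ordered list of 0-based half-open ``(start, end)``
    pairs; multi-exon genes carry one interval per exon.
    """

    name: str
    kind: str
    strand: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValidationError(f"feature {self.name!r}: strand must be '+' or '-'")
        if not self.intervals:
            raise ValidationError(f"feature {self.name!r}: no intervals")
        for s, e in self.intervals:
            if s >= e:
                raise ValidationError(f"feature {self.name!r}: empty interval ({s}, {e})")

    @property
    def footprint(self) -> tuple[int, int]:
        """Smallest interval covering all exons (span of the feature)."""
        return (min(s for s, _ in self.intervals), max(e for _, e in self.intervals))


@dataclass
class AnnotatedGenome:
    """A circular annotated genome record."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"genome {self.id!r}: empty sequence")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < e <= n):
                    raise ValidationError(
                        f"feature {f.name!r} interval ({s}, {e}) outside genome "
                        f"{self.id!r} of length {n}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Sequence of ``[start, end)``; ``end`` may wrap past the origin."""
        if end <= len(self.sequence):
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - len(self.sequence)]


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC/SSC/IRa/IRb layout of a plastome.

    Intervals are 0-based half-open on the linearized sequence; an interval
    whose end is ``<= start`` wraps through the origin. ``ir_equal`` is False
    when the two annotated IR copies differ in length (their per-copy lengths
    are then ``ira``/``irb`` widths, and ``ir_length`` is the IRa length).
    """

    lsc: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    irb: tuple[int, int]
    ir_length: int
    genome_length: int
    ir_equal: bool = True

    def seg_length(self, iv: tuple[int, int]) -> int:
        return (iv[1] - iv[0]) % self.genome_length or (
            self.genome_length if iv[1] == iv[0] else 0
        )

    @property
    def lsc_length(self) -> int:
        return self.seg_length(self.lsc)

    @property
    def ssc_length(self) -> int:
        return self.seg_length(self.ssc)


@dataclass
class GenomicRegion:
    """A noncoding region (intergenic spacer or intron) on the reference genome."""

    name: str
    kind: str  # "spacer" | "intron"
    interval: tuple[int, int]
    copy_of: str | None = None
    wraps: bool = False

    @property
    def length(self) -> int:
        s, e = self.interval
        return e - s

    def sequence(self, genome: AnnotatedGenome) -> str:
        s, e = self.interval
        if self.wraps:
            return genome.sequence[s:] + genome.sequence[: e - len(genome)]
        return genome.sequence[s:e]


# ---------------------------------------------------------------------------
# Reading and writing annotated records
# ---------------------------------------------------------------------------

_GB_KIND = {"gene": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "repeat_region": "IR"}
_KIND_GB = {"gene": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "IR": "repeat_region"}


def _infer_kind(name: str, gb_type: str) -> str:
    kind = _GB_KIND[gb_type]
    if kind == "gene":
        low = name.lower()
        if low.startswith("trn"):
            return "tRNA"
        if low.startswith("rrn"):
            return "rRNA"
    return kind


def _dedupe_names(features: list[Feature]) -> list[Feature]:
    seen: dict[str, int] = {}
    out = []
    for f in features:
        n = seen.get(f.name, 0) + 1
        seen[f.name] = n
        out.append(f if n == 1 else replace(f, name=f"{f.name}_{n}"))
    return out


def read_annotated_genome(path: str | Path, format: str = "genbank") -> AnnotatedGenome:
    """Read one annotated genome record from a GenBank flat file or a
    FASTA + feature-table pair.

    For ``format="fasta+table"``, ``path`` is the FASTA file and the table is
    expected at ``path`` with suffix replaced by ``.features.tsv`` (see
    :func:`write_feature_table`).

    All locations are converted to 0-based half-open intervals;
    join/complement locations become multi-interval features.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "genbank":
        return _read_genbank(path)
    if format == "fasta+table":
        return _read_fasta_table(path)
    raise ValueError(f"unknown format {format!r}")


def _read_genbank(path: Path) -> AnnotatedGenome:
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise FormatError(f"{path}: no GenBank record found") from None
    seq = str(record.seq).upper()
    if not seq:
        raise FormatError(f"{path}: record without sequence")
    circular = record.annotations.get("topology", "circular") != "linear"

    features: list[Feature] = []
    seen_spans: set[tuple[str, tuple[int, int]]] = set()
    for gb_type in ("gene", "tRNA", "rRNA", "repeat_region"):
        for feat in record.features:
            if feat.type != gb_type:
                continue
            name = (
                feat.qualifiers.get("gene", [None])[0]
                or feat.qualifiers.get("locus_tag", [None])[0]
                or feat.qualifiers.get("note", [gb_type])[0]
            )
            parts = sorted(
                ((int(p.start), int(p.end)) for p in feat.location.parts),
                key=lambda iv: iv[0],
            )
            span = (parts[0][0], parts[-1][1])
            # tRNA/rRNA features usually duplicate an identically named gene
            # feature; keep one copy of each (name, span).
            if (name, span) in seen_spans:
                continue
            seen_spans.add((name, span))
            strand = "-" if feat.location.strand == -1 else "+"
            features.append(
                Feature(name=name, kind=_infer_kind(name, gb_type), strand=strand,
                        intervals=tuple(parts))
            )
    if not features:
        raise FormatError(f"{path}: GenBank record has no usable features")
    features.sort(key=lambda f: f.footprint)
    return AnnotatedGenome(
        id=record.id or record.name,
        sequence=seq,
        circular=circular,
        features=_dedupe_names(features),
        source=str(path),
    )


def _read_fasta_table(path: Path) -> AnnotatedGenome:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    table = path.with_suffix(".features.tsv")
    if not table.exists():
        raise IOError(f"feature table not found: {table}")
    features = read_feature_table(table)
    return AnnotatedGenome(
        id=records[0].id,
        sequence=str(records[0].seq),
        circular=True,
        features=features,
        source=str(path),
    )


def read_feature_table(path: str | Path) -> list[Feature]:
    """Read the TSV feature table (name, kind, strand, start, end, parent).

    Rows of kind ``exon`` with a non-empty ``parent`` are folded into the
    parent feature as additional intervals.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    by_name: dict[str, dict] = {}
    order: list[str] = []
    for r in rows:
        if r["kind"] == "exon" and r.get("parent"):
            parent = by_name.get(r["parent"])
            if parent is None:
                raise FormatError(f"exon row references unknown parent {r['parent']!r}")
            parent["intervals"].append((int(r["start"]), int(r["end"])))
        else:
            if r["name"] in by_name:
                raise FormatError(f"duplicate feature name {r['name']!r}")
            by_name[r["name"]] = {
                "name": r["name"],
                "kind": r["kind"],
                "strand": r["strand"],
                "intervals": [(int(r["start"]), int(r["end"]))],
            }
            order.append(r["name"])
    feats = []
    for name in order:
        d = by_name[name]
        d["intervals"] = tuple(sorted(d["intervals"]))
        feats.append(Feature(**d))
    return feats


def write_feature_table(features: list[Feature], path: str | Path) -> None:
    """Write features as TSV (name, kind, strand, start, end, parent);
    multi-interval features emit one parent row plus exon rows."""
    with open(path, "w") as fh:
        fh.write("name\tkind\tstrand\tstart\tend\tparent\n")
        for f in features:
            s, e = f.footprint
            fh.write(f"{f.name}\t{f.kind}\t{f.strand}\t{s}\t{e}\t\n")
            if len(f.intervals) > 1:
                for i, (xs, xe) in enumerate(f.intervals, 1):
                    fh.write(f"{f.name}.exon{i}\texon\t{f.strand}\t{xs}\t{xe}\t{f.name}\n")


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write the genome as a GenBank flat file readable by
    :func:`read_annotated_genome` (coordinate round trip holds)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_"),
        description="synthetic plastome" if not genome.source else genome.id,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand) for s, e in f.intervals]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        record.features.append(
            SeqFeature(location, type=_KIND_GB.get(f.kind, "misc_feature"),
                       qualifiers={"gene": [f.name]})
        )
    SeqIO.write([record], str(path), "genbank")


def write_regions_bed(regions: list[GenomicRegion], genome_id: str,
                      path: str | Path) -> None:
    """Write regions as BED (0-based half-open; name column = region name)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{genome_id}\t{r.interval[0]}\t{r.interval[1]}\t{r.name}\n")


# ---------------------------------------------------------------------------
# Quadripartite structure
# ---------------------------------------------------------------------------


def detect_quadripartite(
    genome: AnnotatedGenome,
    min_ir_len: int = 10_000,
    max_mismatch_frac: float = 0.001,
) -> QuadripartiteStructure:
    """Resolve the LSC/SSC/IRa/IRb layout.

    Explicit IR annotations (kind ``IR``) take precedence; otherwise the
    maximal pair of disjoint reverse-complement repeats of length
    ``>= min_ir_len`` is found by seed k-mer matching against the reverse
    complement, extended with a mismatch budget of
    ``max_mismatch_frac * length``.

    Raises :class:`StructureNotFoundError` when no qualifying repeat exists.
    """
    annotated = [f.footprint for f in genome.features if f.kind == "IR"]
    if len(annotated) == 2:
        ira, irb = sorted(annotated)
        return _assemble_structure(genome, ira, irb)
    ira, irb = _find_ir_pair(genome.sequence, min_ir_len, max_mismatch_frac)
    return _assemble_structure(genome, ira, irb)


def _find_ir_pair(seq: str, min_ir_len: int, max_mismatch_frac: float,
                  k: int = 31) -> tuple[tuple[int, int], tuple[int, int]]:
    n = len(seq)
    rc = revcomp(seq)
    # Seed: shared k-mers between seq and its reverse complement. A common
    # substring seq[ps:ps+L] == rc[pr:pr+L] maps back to the reverse-complement
    # repeat pair (ps, ps+L) vs (n-pr-L, n-pr); extension keeps ps-pr constant.
    index: dict[str, list[int]] = {}
    for i in range(0, n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    diagonals: dict[int, list[tuple[int, int]]] = {}
    step = max(1, k // 2)
    for j in range(0, n - k + 1, step):
        kmer = rc[j : j + k]
        hits = index.get(kmer)
        if hits and len(hits) <= 4:
            for ps in hits:
                diagonals.setdefault(ps - j, []).append((ps, j))
    best: tuple[int, tuple[int, int], tuple[int, int]] | None = None
    for seeds in diagonals.values():
        seeds.sort()
        # split seed runs separated by big jumps
        runs: list[list[tuple[int, int]]] = [[seeds[0]]]
        for sd in seeds[1:]:
            if sd[0] - runs[-1][-1][0] > 2 * k:
                runs.append([sd])
            else:
                runs[-1].append(sd)
        for run in runs:
            ps0, pr0 = run[0]
            ps1 = run[-1][0] + k
            length = ps1 - ps0
            # map rc coordinates back to seq
            pr1 = run[-1][1] + k
            a = (ps0, ps1)
            b = (n - pr1, n - pr0)
            if a[0] >= b[0]:  # symmetric duplicate or self-overlap
                continue
            if a[1] > b[0]:
                continue
            budget = int(max_mismatch_frac * n)
            a, b = _extend_pair(seq, a, b, budget)
            length = a[1] - a[0]
            if length >= min_ir_len and (best is None or length > best[0]):
                best = (length, a, b)
    if best is None:
        raise StructureNotFoundError(
            f"no disjoint reverse-complement repeat pair >= {min_ir_len} bp found"
        )
    return best[1], best[2]


def _extend_pair(seq: str, a: tuple[int, int], b: tuple[int, int],
                 budget: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Extend a reverse-complement repeat pair outward, allowing up to
    ``budget`` mismatches in total."""
    comp = _COMPLEMENT
    n = len(seq)
    a0, a1 = a
    b0, b1 = b
    miss = 0
    look = 12  # a tolerated interior mismatch must be followed by this many matches

    def _ok(i: int, j: int) -> bool:
        return seq[i] == seq[j].translate(comp)

    # extend left end of a / right end of b
    while a0 > 0 and b1 < n and a1 <= b0:
        if not _ok(a0 - 1, b1):
            ahead = all(
                _ok(a0 - 1 - d, b1 + d)
                for d in range(1, look + 1)
                if a0 - 1 - d >= 0 and b1 + d < n
            )
            if miss >= budget or not ahead:
                break
            miss += 1
        a0 -= 1
        b1 += 1
    # extend right end of a / left end of b
    while a1 < b0:
        if not _ok(a1, b0 - 1):
            ahead = all(
                _ok(a1 + d, b0 - 1 - d)
                for d in range(1, look + 1)
                if a1 + d < b0 - 1 - d
            )
            if miss >= budget or not ahead:
                break
            miss += 1
        a1 += 1
        b0 -= 1
    return (a0, a1), (b0, b1)


def _assemble_structure(genome: AnnotatedGenome, ira: tuple[int, int],
                        irb: tuple[int, int]) -> QuadripartiteStructure:
    n = len(genome)
    len_a = ira[1] - ira[0]
    len_b = irb[1] - irb[0]
    if len_a != len_b:
        warnings.warn(
            f"IR copies differ in length ({len_a} vs {len_b} bp)", stacklevel=2
        )
    inner = (ira[1], irb[0])
    outer = (irb[1] % n, ira[0])
    inner_len = (inner[1] - inner[0]) % n
    outer_len = (outer[1] - outer[0]) % n
    if inner_len >= outer_len:
        lsc, ssc = inner, outer
    else:
        lsc, ssc = outer, inner
    return QuadripartiteStructure(
        lsc=lsc, ssc=ssc, ira=ira, irb=irb, ir_length=len_a,
        genome_length=n, ir_equal=(len_a == len_b),
    )


# ---------------------------------------------------------------------------
# Noncoding region extraction
# ---------------------------------------------------------------------------


def extract_noncoding_regions(
    genome: AnnotatedGenome,
    min_len: int = 100,
    split_trnK: bool = True,
    dedupe_ir: bool = True,
    structure: QuadripartiteStructure | None = None,
) -> list[GenomicRegion]:
    """Derive intergenic spacers and introns from the annotation.

    Spacers are the gaps between consecutive feature footprints around the
    circle (footprints of overlapping features, e.g. trnK containing matK,
    are merged so no negative spacer arises). Introns are the gaps between
    consecutive exons of one gene; the trnK intron is split at the embedded
    matK boundaries into 5' and 3' parts when ``split_trnK``. Regions shorter
    than ``min_len`` (ungapped reference length) are dropped. With
    ``dedupe_ir``, the IRb copy of a region carries ``copy_of`` naming its
    IRa counterpart so downstream statistics count it once.
    """
    n = len(genome)
    feats = [f for f in genome.features if f.kind in ("gene", "tRNA", "rRNA")]
    feats.sort(key=lambda f: f.footprint)
    regions: list[GenomicRegion] = []

    # --- spacers between merged footprint blocks
    if feats:
        blocks: list[dict] = []
        for f in feats:
            s, e = f.footprint
            if blocks and s < blocks[-1]["end"]:
                if e > blocks[-1]["end"]:
                    blocks[-1]["end"] = e
                    blocks[-1]["right"] = f.name
                continue
            blocks.append({"start": s, "end": e, "left": f.name, "right": f.name})
        for prev, nxt in zip(blocks, blocks[1:]):
            gap = nxt["start"] - prev["end"]
            if gap < 0:
                warnings.warn(
                    f"overlapping features {prev['right']!r}/{nxt['left']!r} "
                    "produce a negative spacer; skipped", stacklevel=2,
                )
                continue
            if gap >= min_len:
                regions.append(GenomicRegion(
                    name=f"{prev['right']}-{nxt['left']}", kind="spacer",
                    interval=(prev["end"], nxt["start"]),
                ))
        if genome.circular and len(blocks) > 1:
            last, first = blocks[-1], blocks[0]
            gap = (first["start"] - last["end"]) % n
            if 0 < gap < n and gap >= min_len:
                wraps = first["start"] != 0 and last["end"] + gap > n
                end = first["start"] if wraps else last["end"] + gap
                regions.append(GenomicRegion(
                    name=f"{last['right']}-{first['left']}", kind="spacer",
                    interval=(last["end"], end), wraps=wraps,
                ))

    # --- introns between consecutive exons
    by_name = {f.name: f for f in feats}
    for f in feats:
        if len(f.intervals) < 2:
            continue
        gaps = [
            (a[1], b[0]) for a, b in zip(f.intervals, f.intervals[1:]) if b[0] > a[1]
        ]
        if f.name.startswith("trnK") and split_trnK and len(gaps) == 1:
            matk = next((g for g in feats if g.name.startswith("matK")), None)
            gap = gaps[0]
            if matk is not None and gap[0] <= matk.footprint[0] and matk.footprint[1] <= gap[1]:
                ms, me = matk.footprint
                lower = (gap[0], ms)
                upper = (me, gap[1])
                # the 5' part of the intron abuts the 5' exon
                if f.strand == "+":
                    parts = [("trnK intron 5'", lower), ("trnK intron 3'", upper)]
                else:
                    parts = [("trnK intron 3'", lower), ("trnK intron 5'", upper)]
                for nm, iv in parts:
                    if iv[1] - iv[0] >= min_len:
                        regions.append(GenomicRegion(name=nm, kind="intron", interval=iv))
                continue
            warnings.warn("trnK present without embedded matK; split skipped",
                          stacklevel=2)
        for i, iv in enumerate(gaps, 1):
            if iv[1] - iv[0] < min_len:
                continue
            nm = f"{f.name} intron" if len(gaps) == 1 else f"{f.name} intron {i}"
            regions.append(GenomicRegion(name=nm, kind="intron", interval=iv))

    regions.sort(key=lambda r: r.interval)

    if dedupe_ir:
        if structure is None:
            try:
                structure = detect_quadripartite(genome)
            except StructureNotFoundError:
                structure = None
        if structure is not None:
            _mark_ir_duplicates(regions, structure)
    return regions


def _mark_ir_duplicates(regions: list[GenomicRegion],
                        qs: QuadripartiteStructure) -> None:
    """Set ``copy_of`` on regions inside IRb whose mirror exists inside IRa."""
    a0, a1 = qs.ira
    b0, b1 = qs.irb
    in_a = [r for r in regions if not r.wraps and a0 <= r.interval[0] and r.interval[1] <= a1]
    for r in regions:
        if r.wraps or not (b0 <= r.interval[0] and r.interval[1] <= b1):
            continue
        s, e = r.interval
        # position p in IRb mirrors to a0 + (b1 - p) on the IRa copy
        mirror = (a0 + (b1 - e), a0 + (b1 - s))
        best, best_ovl = None, 0
        for cand in in_a:
            cs, ce = cand.interval
            ovl = min(ce, mirror[1]) - max(cs, mirror[0])
            if ovl > best_ovl:
                best, best_ovl = cand, ovl
        if best is not None and best_ovl >= 0.8 * (e - s):
            r.copy_of = best.name


# ---------------------------------------------------------------------------
# Base composition
# ---------------------------------------------------------------------------


def gc_content(seq: str) -> float:
    """Fraction (G+C)/(A+C+G+T); ambiguity codes and N are excluded from both
    numerator and denominator."""
    if not seq:
        raise ValueError("gc_content of empty sequence is undefined")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / acgt


def at_content(seq: str) -> float:
    """Fraction (A+T)/(A+C+G+T); complements :func:`gc_content`."""
    return 1.0 - gc_content(seq)
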