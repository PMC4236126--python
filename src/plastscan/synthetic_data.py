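"""Synthetic quadripartite plastome pairs with a known edit script.

The generator emulates the statistical structure the comparative analysis
assumes: a circular genome of ~160 kb with GC around 36-37%, a quadripartite
layout with two exact inverted-repeat copies, gene/tRNA/rRNA features with
occasional introns and one trnK/matK nesting, and a mutated partner genome at
low divergence (p around 0.0015) with AT-biased SNP placement and indels of
the three mutational classes (homopolymer length variants, SSR copy-number
changes, and unclassified indels).

Because every mutation is planted at most once per site (rejection sampling
with a small exclusion margin), the edit script is unambiguous and the true
pairwise alignment can be emitted directly; calling variants on it must
recover the planted sets exactly, which is the basis of the recovery tests.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .alignment import PairwiseAlignment, write_alignment_fasta
from .genome_io import AnnotatedGenome, Feature, revcomp, write_genbank

__all__ = [
    "SimConfig",
    "PlantedSNP",
    "PlantedIndel",
    "PlantedInversion",
    "GroundTruth",
    "simulate_genome",
    "mutate_genome",
    "simulate_pair",
    "write_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of one simulated genome pair.

    Rates are per-site (``snp_rate``) or per-kb per class (``indel_rate_*``);
    defaults emulate a low-divergence rosid plastome pair (~160 kb, GC 36.6%,
    p ~ 0.0015, ~1.1 indel events per kb aggregate with the unclassified
    class most frequent).
    """

    genome_length: int = 160_000
    gc: float = 0.366
    n_genes: int = 60
    n_trnas: int = 25
    ir_length: int = 26_000
    ssc_fraction: float = 0.12
    snp_rate: float = 0.0015
    at_bias: float = 0.7  # probability a SNP is placed inside a high-AT window
    indel_rate_polyn: float = 0.3  # events per kb
    indel_rate_ssr: float = 0.25
    indel_rate_other: float = 0.55
    indel_mean_len: float = 3.0  # geometric length law
    inversion_count: int = 0
    inversion_length: int = 30
    homopolymer_every: int = 2_000  # planted tract spacing (substrate for polyN)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        for r in (self.snp_rate, self.indel_rate_polyn, self.indel_rate_ssr,
                  self.indel_rate_other):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if 2 * self.ir_length >= self.genome_length:
            raise ValueError("IR pair does not fit twice within the genome")
        if self.genome_length - 2 * self.ir_length - int(
            self.ssc_fraction * self.genome_length
        ) < 5_000:
            raise ValueError("layout infeasible: LSC would be shorter than 5 kb")


@dataclass(frozen=True)
class PlantedSNP:
    pos: int  # position on genome A
    base_from: str
    base_to: str


@dataclass(frozen=True)
class PlantedIndel:
    pos: int  # position on genome A (insertion point / deletion start)
    kind: str  # "ins" (extra bases in B) | "del" (bases missing from B)
    klass: str  # intended mutational class
    seq: str


@dataclass(frozen=True)
class PlantedInversion:
    pos: int
    length: int


@dataclass
class GroundTruth:
    """The planted edit script of a simulated genome pair plus the true
    alignment built directly from it."""

    snps: list[PlantedSNP] = field(default_factory=list)
    indels: list[PlantedIndel] = field(default_factory=list)
    inversions: list[PlantedInversion] = field(default_factory=list)
    alignment: PairwiseAlignment | None = None


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Genome synthesis
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def simulate_genome(cfg: SimConfig) -> AnnotatedGenome:
    """Generate one annotated genome (genome A of a pair).

    Deterministic for a given config. Homopolymer tracts of length 7-15 are
    planted in spacers roughly every ``homopolymer_every`` bases to give the
    polyN mutation process substrate; tandem motif pairs are planted for the
    SSR-deletion process; when inversions are requested, complement-free
    tracts (alphabet {A,C}) are planted so a flipped block mismatches at
    every column.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.genome_length
    ssc_len = int(cfg.ssc_fraction * n)
    lsc_len = n - 2 * cfg.ir_length - ssc_len

    n_lsc_genes = max(1, int(cfg.n_genes * 0.75))
    n_ssc_genes = max(1, cfg.n_genes - n_lsc_genes)
    lsc_seq, lsc_feats = _fill_segment(
        rng, cfg, lsc_len, offset=0, prefix="lsc",
        n_genes=n_lsc_genes, n_trnas=cfg.n_trnas, include_trnk=True,
    )
    ira_start = lsc_len
    ira_seq, ira_feats = _fill_ir(rng, cfg, ira_start)
    ssc_start = ira_start + cfg.ir_length
    ssc_seq, ssc_feats = _fill_segment(
        rng, cfg, ssc_len, offset=ssc_start, prefix="ssc",
        n_genes=n_ssc_genes, n_trnas=2, include_trnk=False,
    )
    irb_start = ssc_start + ssc_len
    irb_seq = revcomp(ira_seq)
    irb_feats = []
    for f in ira_feats:
        mirrored = tuple(sorted(
            (irb_start + (cfg.ir_length - (e - ira_start)),
             irb_start + (cfg.ir_length - (s - ira_start)))
            for s, e in f.intervals
        ))
        irb_feats.append(Feature(
            name=f.name + "_ir", kind=f.kind,
            strand="-" if f.strand == "+" else "+", intervals=mirrored,
        ))

    sequence = lsc_seq + ira_seq + ssc_seq + irb_seq
    assert len(sequence) == n
    features = lsc_feats + ira_feats + ssc_feats + irb_feats
    features.sort(key=lambda f: f.footprint)
    return AnnotatedGenome(
        id=f"sim{cfg.seed:04d}", sequence=sequence, circular=True,
        features=features, source="",
    )


def _fill_segment(rng, cfg: SimConfig, length: int, offset: int, prefix: str,
                  n_genes: int, n_trnas: int, include_trnk: bool):
    """Alternate features and spacer gaps until the budget is spent."""
    parts: list[str] = []
    feats: list[Feature] = []
    pos = offset
    end = offset + length
    gene_i = trna_i = 0
    trnk_done = not include_trnk
    plant_countdown = int(rng.integers(200, cfg.homopolymer_every))

    def gap(max_len: int) -> str:
        nonlocal plant_countdown
        glen = int(rng.integers(60, 900))
        glen = min(glen, max_len)
        if glen <= 0:
            return ""
        seq = _random_seq(rng, glen, cfg.gc)
        # planted substrate, centered away from the gap edges
        if glen > 40:
            plant_countdown -= glen
            if plant_countdown <= 0:
                plant_countdown = cfg.homopolymer_every
                base = rng.choice(np.frombuffer(b"AT", dtype=np.uint8))
                tract = int(rng.integers(7, 16))
                at = int(rng.integers(10, glen - tract - 10)) if glen - tract > 20 else 10
                seq[at : at + tract] = base
            if rng.random() < 0.3 and glen > 40:
                m = int(rng.integers(2, 7))
                at = int(rng.integers(10, glen - 2 * m - 10))
                motif = _random_seq(rng, m, cfg.gc)
                if len(set(motif.tolist())) > 1:
                    seq[at : at + m] = motif
                    seq[at + m : at + 2 * m] = motif
            if cfg.inversion_count and rng.random() < 0.25 and glen > cfg.inversion_length + 24:
                ln = cfg.inversion_length + 4
                at = int(rng.integers(10, glen - ln - 10))
                seq[at : at + ln] = rng.choice(
                    np.frombuffer(b"AC", dtype=np.uint8), size=ln
                )
        return _to_str(seq)

    while pos < end - 120:
        g = gap(end - pos - 100)
        parts.append(g)
        pos += len(g)
        remaining = end - pos
        if not trnk_done and remaining > 2_400:
            # trnK with embedded matK: exon1 - intron5' - matK - intron3' - exon2
            e1, i5, mk, i3, e2 = 37, 260, 1_500, 230, 35
            total = e1 + i5 + mk + i3 + e2
            seq = _random_seq(rng, total, cfg.gc)
            parts.append(_to_str(seq))
            feats.append(Feature(
                name="trnK", kind="tRNA", strand="+",
                intervals=((pos, pos + e1), (pos + total - e2, pos + total)),
            ))
            feats.append(Feature(
                name="matK", kind="gene", strand="+",
                intervals=((pos + e1 + i5, pos + e1 + i5 + mk),),
            ))
            pos += total
            trnk_done = True
            continue
        make_trna = trna_i < n_trnas and (gene_i >= n_genes or rng.random() < 0.35)
        if make_trna:
            flen = int(rng.integers(72, 90))
            if flen > remaining - 10:
                break
            parts.append(_to_str(_random_seq(rng, flen, cfg.gc)))
            trna_i += 1
            feats.append(Feature(
                name=f"trn{chr(65 + trna_i % 26)}{prefix[0]}{trna_i}", kind="tRNA",
                strand="+" if rng.random() < 0.5 else "-",
                intervals=((pos, pos + flen),),
            ))
            pos += flen
        else:
            if gene_i >= n_genes:
                break
            flen = int(rng.integers(250, 1_800))
            two_exon = rng.random() < 0.15
            intron = int(rng.integers(300, 800)) if two_exon else 0
            if flen + intron > remaining - 10:
                break
            gene_i += 1
            name = f"{prefix}g{gene_i:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            if two_exon:
                x1 = int(rng.integers(80, max(100, flen // 2)))
                seq = _random_seq(rng, flen + intron, cfg.gc)
                parts.append(_to_str(seq))
                feats.append(Feature(
                    name=name, kind="gene", strand=strand,
                    intervals=((pos, pos + x1),
                               (pos + x1 + intron, pos + flen + intron)),
                ))
                pos += flen + intron
            else:
                parts.append(_to_str(_random_seq(rng, flen, cfg.gc)))
                feats.append(Feature(
                    name=name, kind="gene", strand=strand,
                    intervals=((pos, pos + flen),),
                ))
                pos += flen
    if pos < end:
        parts.append(_to_str(_random_seq(rng, end - pos, cfg.gc)))
    return "".join(parts), feats


def _fill_ir(rng, cfg: SimConfig, offset: int):
    """One IR copy: an rRNA operon-like block inside random sequence."""
    n = cfg.ir_length
    seq = _random_seq(rng, n, cfg.gc)
    feats = []
    blocks = [("rrn16", "rRNA", 1_490), ("trnIr", "tRNA", 74),
              ("rrn23", "rRNA", 2_810), ("rrn5", "rRNA", 121)]
    pos = 500
    for name, kind, ln in blocks:
        if pos + ln > n - 200:
            break
        feats.append(Feature(
            name=name, kind=kind, strand="+",
            intervals=((offset + pos, offset + pos + ln),),
        ))
        pos += ln + int(rng.integers(150, 400))
    return _to_str(seq), feats


# ---------------------------------------------------------------------------
# Mutation with ground truth
# ---------------------------------------------------------------------------


def _homopolymer_runs(seq: str, min_len: int = 7) -> list[tuple[int, int, str]]:
    """All maximal single-base runs >= min_len as (start, length, base)."""
    out = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            out.append((i, j - i, seq[i]))
        i = j
    return out


def _tandem_sites(arr: np.ndarray, m: int) -> np.ndarray:
    """Start positions p with arr[p:p+m] == arr[p+m:p+2m] and a non-homopolymer
    motif (vectorized)."""
    n = len(arr)
    if n < 2 * m:
        return np.empty(0, dtype=int)
    eq = (arr[:-m] == arr[m:]).astype(np.int32)
    ceq = np.concatenate(([0], np.cumsum(eq)))
    limit = n - 2 * m + 1
    full = (ceq[m : m + limit] - ceq[:limit]) == m
    if m > 1:
        neq = (arr[1:] != arr[:-1]).astype(np.int32)
        cneq = np.concatenate(([0], np.cumsum(neq)))
        distinct = (cneq[m - 1 : m - 1 + limit] - cneq[:limit]) > 0
        full &= distinct
    return np.flatnonzero(full)


def _complement_free_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs over the alphabet {A,C} (their complements are {T,G}, so
    a reverse-complemented block mismatches at every column)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mask = (arr == ord("A")) | (arr == ord("C"))
    out = []
    i, n = 0, len(mask)
    idx = np.flatnonzero(np.diff(mask.astype(np.int8)))
    bounds = [0] + (idx + 1).tolist() + [n]
    for s, e in zip(bounds, bounds[1:]):
        if mask[s] and e - s >= min_len:
            out.append((s, e - s))
    return out


def mutate_genome(
    genome: AnnotatedGenome, cfg: SimConfig
) -> tuple[AnnotatedGenome, GroundTruth]:
    """Apply a random edit script to genome A, returning genome B and the
    ground truth (including the true alignment).

    SNP count is Binomial(length, snp_rate); with probability ``at_bias`` a
    SNP lands uniformly among positions whose +-10 bp window has AT >= 0.8,
    else uniformly. polyN indels add/remove one base at homopolymer runs
    >= 7; SSR indels duplicate or delete one copy of a 2-6 bp motif adjacent
    to an existing copy; other indels insert or delete random sequence of
    geometric length. Events never overlap (rejection sampling with a 2 bp
    exclusion margin); more than 1000 consecutive rejections raises
    :class:`ConfigError`.
    """
    cfg.validate()
    rng = np.random.default_rng((cfg.seed + 1) % 2**31)
    seq = genome.sequence
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    blocked = np.zeros(n + 1, dtype=bool)
    margin = 2

    def try_block(lo: int, hi: int) -> bool:
        lo_m, hi_m = max(0, lo - margin), min(n + 1, hi + margin)
        if blocked[lo_m:hi_m].any():
            return False
        blocked[lo_m:hi_m] = True
        return True

    def sample(fn, n_events: int, what: str):
        placed = 0
        rejections = 0
        while placed < n_events:
            if fn():
                placed += 1
                rejections = 0
            else:
                rejections += 1
                if rejections > 1_000:
                    raise ConfigError(
                        f"could not place {what} event after 1000 rejections; "
                        "rates too high for the genome length"
                    )

    truth = GroundTruth()
    kb = n / 1_000

    # --- indels first (they block spans) -----------------------------------
    runs = _homopolymer_runs(seq, min_len=7)
    n_polyn = min(rng.poisson(cfg.indel_rate_polyn * kb), len(runs))
    if runs and n_polyn:
        order = rng.permutation(len(runs))
        placed = 0
        for ri in order:
            if placed >= n_polyn:
                break
            start, ln, base = runs[ri]
            if not try_block(start, start + ln):
                continue
            if rng.random() < 0.5:
                truth.indels.append(PlantedIndel(start, "ins", "polyN", base))
            else:
                truth.indels.append(PlantedIndel(start, "del", "polyN", base))
            placed += 1

    n_ssr = rng.poisson(cfg.indel_rate_ssr * kb)
    tandems = {m: _tandem_sites(arr, m) for m in range(2, 7)}

    def place_ssr() -> bool:
        m = int(rng.integers(2, 7))
        if rng.random() < 0.5:  # duplication: B gains a second copy
            p = int(rng.integers(0, n - 2 * m))
            motif = seq[p : p + m]
            if len(set(motif)) < 2 or "N" in motif:
                return False
            if not try_block(p, p + m):
                return False
            truth.indels.append(PlantedIndel(p + m, "ins", "SSR_or_inversion", motif))
            return True
        sites = tandems[m]
        if sites.size == 0:
            return False
        p = int(sites[rng.integers(0, sites.size)])
        if not try_block(p, p + 2 * m):
            return False
        truth.indels.append(
            PlantedIndel(p + m, "del", "SSR_or_inversion", seq[p + m : p + 2 * m])
        )
        return True

    sample(place_ssr, n_ssr, "SSR indel")

    n_other = rng.poisson(cfg.indel_rate_other * kb)

    def place_other() -> bool:
        ln = int(rng.geometric(1 / cfg.indel_mean_len))
        if rng.random() < 0.5:
            p = int(rng.integers(0, n))
            if not try_block(p, p + 1):
                return False
            ins = _to_str(_random_seq(rng, ln, cfg.gc))
            truth.indels.append(PlantedIndel(p, "ins", "other", ins))
            return True
        p = int(rng.integers(0, n - ln))
        if not try_block(p, p + ln):
            return False
        truth.indels.append(PlantedIndel(p, "del", "other", seq[p : p + ln]))
        return True

    sample(place_other, n_other, "other indel")

    # --- inversions ---------------------------------------------------------
    if cfg.inversion_count:
        cf_runs = [r for r in _complement_free_runs(seq, cfg.inversion_length + 2)]
        placed = 0
        for start, ln in cf_runs:
            if placed >= cfg.inversion_count:
                break
            p = start + 1
            if not try_block(p, p + cfg.inversion_length):
                continue
            truth.inversions.append(PlantedInversion(p, cfg.inversion_length))
            placed += 1
        if placed < cfg.inversion_count:
            raise ConfigError(
                "not enough complement-free substrate for requested inversions"
            )

    # --- SNPs ---------------------------------------------------------------
    is_at = ((arr == ord("A")) | (arr == ord("T"))).astype(np.int32)
    win = 10
    cum = np.concatenate(([0], np.cumsum(is_at)))
    lo = np.maximum(np.arange(n) - win, 0)
    hi = np.minimum(np.arange(n) + win + 1, n)
    at_frac = (cum[hi] - cum[lo]) / (hi - lo)
    rich = np.flatnonzero(at_frac >= 0.8)
    n_snps = rng.binomial(n, cfg.snp_rate)

    def place_snp() -> bool:
        if rich.size and rng.random() < cfg.at_bias:
            p = int(rich[rng.integers(0, rich.size)])
        else:
            p = int(rng.integers(0, n))
        base = seq[p]
        if base not in "ACGT":
            return False
        if not try_block(p, p + 1):
            return False
        alts = [b for b in "ACGT" if b != base]
        truth.snps.append(PlantedSNP(p, base, alts[int(rng.integers(0, 3))]))
        return True

    sample(place_snp, n_snps, "SNP")

    genome_b, alignment = _apply_edits(genome, truth, cfg)
    truth.alignment = alignment
    return genome_b, truth


def _apply_edits(genome: AnnotatedGenome, truth: GroundTruth,
                 cfg: SimConfig) -> tuple[AnnotatedGenome, PairwiseAlignment]:
    seq = genome.sequence
    events: list[tuple[int, str, object]] = []
    for s in truth.snps:
        events.append((s.pos, "snp", s))
    for ind in truth.indels:
        events.append((ind.pos, ind.kind, ind))
    for inv in truth.inversions:
        events.append((inv.pos, "inv", inv))
    events.sort(key=lambda t: (t[0], 0 if t[1] == "ins" else 1))

    ra: list[str] = []
    rb: list[str] = []
    cur = 0
    for pos, kind, ev in events:
        ra.append(seq[cur:pos])
        rb.append(seq[cur:pos])
        cur = pos
        if kind == "snp":
            ra.append(ev.base_from)
            rb.append(ev.base_to)
            cur = pos + 1
        elif kind == "ins":
            ra.append("-" * len(ev.seq))
            rb.append(ev.seq)
        elif kind == "del":
            ra.append(ev.seq)
            rb.append("-" * len(ev.seq))
            cur = pos + len(ev.seq)
        else:  # inversion
            seg = seq[pos : pos + ev.length]
            ra.append(seg)
            rb.append(revcomp(seg))
            cur = pos + ev.length
    ra.append(seq[cur:])
    rb.append(seq[cur:])
    row_a, row_b = "".join(ra), "".join(rb)

    aln = PairwiseAlignment(row_a, row_b, id_a=genome.id, id_b=genome.id + "m")
    seq_b = aln.seq_b
    # map A feature boundaries onto B through the true alignment
    n_a = len(seq)
    b_before = np.cumsum(~aln.gap_b)  # B bases in columns [0, c]
    feats_b = []
    for f in genome.features:
        ivs = []
        for s, e in f.intervals:
            cs = int(aln.pos_to_col_a[s])
            ce = int(aln.pos_to_col_a[e]) if e < n_a else len(aln)
            bs = int(b_before[cs - 1]) if cs > 0 else 0
            be = int(b_before[ce - 1]) if ce > 0 else 0
            if be > bs:
                ivs.append((bs, be))
        if ivs:
            feats_b.append(Feature(name=f.name, kind=f.kind, strand=f.strand,
                                   intervals=tuple(ivs)))
    genome_b = AnnotatedGenome(
        id=genome.id + "m", sequence=seq_b, circular=True,
        features=feats_b, source="",
    )
    assert aln.seq_a == seq, "edit script does not reproduce genome A"
    return genome_b, aln


def simulate_pair(cfg: SimConfig) -> tuple[AnnotatedGenome, AnnotatedGenome, GroundTruth]:
    """Generate genome A, its mutated partner B, and the ground truth."""
    a = simulate_genome(cfg)
    b, truth = mutate_genome(a, cfg)
    return a, b, truth


def write_truth(truth: GroundTruth, genome_a: AnnotatedGenome,
                genome_b: AnnotatedGenome, out_dir: str | Path) -> dict:
    """Write GenBank files, the true alignment (gapped FASTA) and a JSON
    ground-truth manifest; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genbank(genome_a, out / "genome_a.gb")
    write_genbank(genome_b, out / "genome_b.gb")
    write_alignment_fasta(truth.alignment, out / "true_alignment.fasta")
    manifest = {
        "genome_a": genome_a.id,
        "genome_b": genome_b.id,
        "snps": [asdict(s) for s in truth.snps],
        "indels": [asdict(i) for i in truth.indels],
        "inversions": [asdict(i) for i in truth.inversions],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
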