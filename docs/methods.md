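# Methods

## Scope and model

`plastscan` compares two annotated plastid genomes of very low divergence
(p-distance roughly 0.0005–0.005, the regime of conspecific or congeneric
plastomes) and ranks their noncoding regions — intergenic spacers and introns
— by sequence variability, to support marker choice for species-level
phylogenetic and haplotype studies. The underlying quantities are:

* **p-distance** — the proportion of differing nucleotide sites, computed as
  SNPs divided by the number of alignment columns in which *both* rows carry
  a determined base (A/C/G/T). Gap columns are excluded because an indel is
  one event, not `length` point differences; ambiguity columns are excluded
  because no substitution can be asserted at them.
* **PIC** (potentially informative characters) — the sum of substitutions,
  indel events, and inversions in a region. An indel event is one *maximal
  run of gap characters in one row*, not one gap column; this matches how
  events are counted when alignments are scored by eye and keeps event
  counts far below gap-column counts.
* **Indel classes** — (1) *polyN*: the indel is a single repeated nucleotide
  and the maximal homopolymer run through the locus (the indel plus
  same-base extension into both flanks of the non-gap row) reaches at least
  7 bases; (2) *SSR_or_inversion*: the indel (length ≥ 2) equals one
  immediately adjacent copy of itself (tandem duplication/deletion) or the
  reverse complement of an adjacent equal-length substring; (3) *other*.
  Classification priority is polyN > SSR > other, because a long homopolymer
  indel is also a trivial SSR and the homopolymer reading is the mechanistic
  one (replication slippage on a mononucleotide tract).

## Coordinates and structure

All coordinates are 0-based half-open internally; GenBank's 1-based
inclusive locations are converted at the I/O boundary. The quadripartite
layout (LSC/SSC/IRa/IRb) is taken from explicit inverted-repeat annotations
when present, otherwise detected by seeding unique 31-mers of the sequence
against its reverse complement, grouping seeds by diagonal, and extending
the best candidate pair outward. Extension tolerates a budgeted number of
interior mismatches (default fraction 0.001 of genome length, since
deposited IR copies occasionally differ by a few bases) but a tolerated
mismatch must be followed by 12 matching positions — without that lookahead,
extension would creep past exact IR boundaries into random sequence at a
rate of one position per ~1.3 mismatches. When the two IR copies differ in
length the per-copy lengths are reported and the inequality is flagged
rather than averaged.

Spacers are the gaps between consecutive *merged feature footprints* around
the circle. Merging footprints (e.g. trnK spanning the embedded matK)
prevents negative spacers and names each spacer after the features that
actually bound it. The trnK intron is split at the matK boundaries into 5′
and 3′ parts, assigned by the trnK strand. Regions shorter than 100 bp on
the reference are dropped. Regions inside IRb whose mirrored interval
coincides (≥ 80% reciprocal overlap) with a region in IRa carry a `copy_of`
tag and are counted once in rankings.

## Alignment

The built-in aligner targets pairs below ~1% divergence. Unique shared
21-mers are chained by longest increasing subsequence, co-diagonal seeds are
merged into maximal runs, and the short inter-anchor segments are closed
with an affine-gap global alignment (match +1, mismatch −1, gap open −4,
gap extend −1). Circular inputs whose origins disagree are rotated to the
first chained anchor so origin placement does not surface as terminal
indels. If chained anchors cover less than half of the shorter genome the
aligner refuses and asks for an external alignment: at that divergence gap
placement is editorial and should not be silently invented. Inter-anchor
segments larger than ~4 × 10⁶ DP cells (which do not occur in the supported
divergence regime) fall back to edit-distance alignment via `edlib` if
installed. The round-trip invariant — ungapping each row reproduces its
input sequence — is asserted on every alignment the package produces or
loads; externally supplied alignments may additionally contain columns
gapped in both rows, which carry no pairwise information and are removed
with a logged count.

The consensus keeps every alignment column: equal bases pass through,
substitution columns become the IUPAC code of the two bases, indel columns
keep the present base. Consensus coordinates therefore equal alignment
columns, which makes window tracks and region slices directly comparable.

## Tracks, context statistics, markers

Window tracks use non-overlapping 500 bp slots of the consensus (the final
short window is kept and flagged); SNPs are assigned by consensus position
and an indel belongs to the window containing its first column, so per-
window counts sum exactly to genome totals. SNP neighborhoods are the 2r
consensus bases flanking (and excluding) the SNP column for radii 1–10, 20,
50, 100; windows truncated by a sequence end are flagged, not padded, and
ambiguity codes are excluded from both numerator and denominator of the AT
fraction.

Marker screening models a Sanger workflow: the amplicon is the region plus a
150 bp primer allowance (split evenly across both flanks), candidates are
amplicons of 900–1300 bp, and a sequencing read is taken as reliable up to
the end of the first polyA/T run of ≥ 8 bases it crosses ("larger than
seven") or its read length (default 1000 bases), whichever comes first.
Regions with no such microsatellite are *recommended*; one microsatellite is
*conditional* (two reads meeting at it); when two end-anchored reads cannot
cover the interval between multiple microsatellites the region is
*dismissed*. This two-read coverage check is a deliberate formalization of a
qualitative rule; the emitted reason strings make the decision auditable.

## Synthetic data

The generator emulates the study conditions the analysis assumes, and its
defaults are those conditions: a 160 kb circular genome at GC 0.366 with an
exact 26 kb IR pair and an SSC of 12% of the genome; genes (250–1800 bp,
15% with one intron), tRNAs and an rRNA block in the IR; one trnK/matK
nesting is always present so the intron-split rule is always exercised.
Homopolymer tracts (7–15 bp) are planted in spacers roughly every 2 kb and
tandem motif pairs are planted as substrate so the polyN and SSR mutation
processes have loci to act on; both are re-discovered from the sequence at
mutation time rather than carried as hidden state.

The partner genome is produced by an explicit edit script: SNP count is
Binomial(L, 0.0015); with probability 0.7 a SNP lands uniformly among
positions whose ±10 bp window has AT ≥ 0.8, else uniformly (this mirrors the
empirical concentration of substitutions in AT-rich stretches). Indel rates
are 0.3 (polyN), 0.25 (SSR) and 0.55 (other) events per kb — about 1.1
events/kb aggregate with the unclassified class most frequent, as in
rosid-type pairs — with geometric lengths of mean 3 for the unclassified
class. Events are rejection-sampled with a 2 bp exclusion margin so the
edit script is unambiguous; the true alignment is then written directly
from the script, and feature annotations are projected onto the partner
genome through it. Requested inversions are placed on planted
complement-free tracts (alphabet {A,C}), because flipping such a block
mismatches at every column; a flipped *palindromic* block would be
sequence-invariant and therefore undetectable in principle, which is why
the inversion detector reports nothing for palindromes and keeps a
`palindromic` flag only for near-palindromic detected blocks.

What the simulator does **not** emulate: concerted evolution of the IR
copies (mutations fall independently of the quadripartite structure, so
simulated IRs are slightly more variable than real ones), rate heterogeneity
along the genome beyond the AT bias, codon structure in genes, and
rearrangements other than small inversions. Passing recovery tests
therefore demonstrate the correctness of the calling, slicing and counting
machinery under the stated noise model — not robustness to annotation
errors or to the manual gap-placement conventions of curated alignments.

## Numerical and procedural choices

* Determinism: every stochastic step draws from `numpy` Generators seeded
  from the configuration; identical configurations give byte-identical
  genomes, edit scripts and report files (rankings use stable sorts with a
  full tie-break chain: other key, aligned length, name).
* Rankings exclude IR duplicates by default and treat an undefined
  p-distance (no comparable columns) as missing, sorted last — never as 0.
* Report files print p-distances at 5 decimals in machine output and ×10³
  at 2 decimals in ranking tables; full precision is never rounded away in
  memory.
* Test and acceptance problem sizes: module tests exercise 40–60 kb layouts
  where the property under test is size-independent; recovery, estimator
  and AT-context acceptance checks run at the full default conditions
  (160 kb, 20 replicate seeds for exact recovery).

## Known limitations

* Genomes with rearrangements beyond one origin rotation are out of scope;
  the aligner will refuse them via the anchor-coverage guard.
* Spacers spanning the linearization origin are extracted (by rotation) but
  excluded from alignment slicing; the pipeline logs and skips them.
* The polyN rule applies to any nucleotide, while marker screening counts
  only polyA/T runs — the former describes mutation mechanism, the latter
  Sanger read failure; the two thresholds (7 and 8) differ deliberately
  ("repeated at least sevenfold" vs "larger than seven").
* `select_markers` needs region sequences; regions whose sequence is not
  supplied are skipped silently.
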