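"""SNP/indel/inversion calling, indel classification, AT-context profiles."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastscan.alignment import PairwiseAlignment, consensus
from plastscan.genome_io import revcomp
from plastscan.variants import (
    OTHER,
    POLY_N,
    SSR_OR_INVERSION,
    IndelEvent,
    call_indels,
    call_snps,
    classify_indel,
    column_census,
    detect_inversions,
    indel_at_profiles,
    snp_neighborhood_at,
)


def brute_force_classify(ev: IndelEvent) -> str:
    """Independent classification via exhaustive scans over the event context
    string (flank_left + indel_seq + flank_right)."""
    s, L, R = ev.indel_seq.upper(), ev.flank_left.upper(), ev.flank_right.upper()
    ctx = L + s + R
    lo, hi = len(L), len(L) + len(s)
    if len(set(s)) == 1:
        # longest maximal homopolymer run of ctx overlapping the indel locus
        best = 0
        i = 0
        while i < len(ctx):
            j = i
            while j < len(ctx) and ctx[j] == ctx[i]:
                j += 1
            if ctx[i] == s[0] and i < hi and j > lo:
                best = max(best, j - i)
            i = j
        if best >= 7:
            return POLY_N
    if len(s) >= 2:
        n = len(s)
        for cand in (s, revcomp(s)):
            if lo >= n and ctx[lo - n : lo] == cand:
                return SSR_OR_INVERSION
            if len(ctx) - hi >= n and ctx[hi : hi + n] == cand:
                return SSR_OR_INVERSION
    return OTHER


class TestCalling:
    def test_identical_rows_have_no_variants(self):
        aln = PairwiseAlignment("ACGTACGT", "ACGTACGT")
        assert call_snps(aln) == []
        assert call_indels(aln) == []

    def test_hand_alignment_snp_and_indel(self):
        aln = PairwiseAlignment("AC-GT", "ATAGT")
        snps = call_snps(aln)
        assert len(snps) == 1
        assert (snps[0].column, snps[0].base_a, snps[0].base_b) == (1, "C", "T")
        indels = call_indels(aln)
        assert len(indels) == 1
        ev = indels[0]
        assert ev.carrier == "a"
        assert ev.length == 1
        assert ev.indel_seq == "A"

    def test_gap_runs_are_maximal(self):
        #        0123456789012345
        row_a = "AAAA----------CCCTT--GG"
        row_b = "AAAAGGGGGGGGGGCCCTTAAGG"
        indels = call_indels(PairwiseAlignment(row_a, row_b))
        assert [ev.length for ev in indels] == [10, 2]

    def test_ambiguous_columns_not_called_as_snps(self):
        aln = PairwiseAlignment("ANGT", "ACGT")
        assert call_snps(aln) == []
        census = column_census(aln)
        assert census["ambiguous"] == 1

    def test_abutting_opposite_row_runs_flagged_complex(self):
        aln = PairwiseAlignment("AA--GGTT", "AACC--TT")
        indels = call_indels(aln)
        assert len(indels) == 2
        assert all(ev.complex for ev in indels)

    def test_census_partitions_columns(self, small_pair):
        aln = small_pair[2].alignment
        census = column_census(aln)
        assert (census["identical"] + census["snp"] + census["ambiguous"]
                + census["gap"]) == census["total"] == len(aln)


class TestClassify:
    def test_sevenfold_boundary_counts_flank_extension(self):
        ev = IndelEvent(columns=(0, 2), carrier="b", indel_seq="AA", length=2,
                        flank_left="CGTAAA", flank_right="AACG")
        # run = 3 (left) + 2 (indel) + 2 (right) = 7
        assert classify_indel(ev) == POLY_N

    def test_six_base_run_is_not_polyn(self):
        ev = IndelEvent(columns=(0, 2), carrier="b", indel_seq="AA", length=2,
                        flank_left="CGTAA", flank_right="AGCG")
        assert classify_indel(ev) != POLY_N

    def test_tandem_motif_is_ssr(self):
        ev = IndelEvent(columns=(0, 4), carrier="a", indel_seq="ATAT", length=4,
                        flank_left="GGCC", flank_right="ATATGG")
        assert classify_indel(ev) == SSR_OR_INVERSION

    def test_inverted_repeat_is_ssr_class(self):
        ev = IndelEvent(columns=(0, 4), carrier="a", indel_seq="AACC", length=4,
                        flank_left="CGGGTT", flank_right="TTCA")
        # revcomp(AACC) = GGTT adjoins on the left
        assert classify_indel(ev) == SSR_OR_INVERSION

    def test_unmotivated_indel_is_other(self):
        ev = IndelEvent(columns=(0, 5), carrier="a", indel_seq="GTCAG", length=5,
                        flank_left="CCCC", flank_right="TTTT")
        assert classify_indel(ev) == OTHER

    def test_empty_indel_rejected(self):
        ev = IndelEvent(columns=(0, 0), carrier="a", indel_seq="", length=0)
        with pytest.raises(ValueError):
            classify_indel(ev)

    @given(st.data())
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_agrees_with_brute_force(self, data):
        seq = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=10))
        left = data.draw(st.text(alphabet="ACGT", max_size=20))
        right = data.draw(st.text(alphabet="ACGT", max_size=20))
        ev = IndelEvent(columns=(0, len(seq)), carrier="a", indel_seq=seq,
                        length=len(seq), flank_left=left, flank_right=right)
        assert classify_indel(ev) == brute_force_classify(ev)


class TestInversions:
    def test_planted_inversion_detected_at_coordinates(self):
        rng = np.random.default_rng(0)
        s = "".join(rng.choice(list("AC"), size=40))
        flank1 = "".join(rng.choice(list("ACGT"), size=50))
        flank2 = "".join(rng.choice(list("ACGT"), size=50))
        row_a = flank1 + s + flank2
        row_b = flank1 + revcomp(s) + flank2
        inv = detect_inversions(PairwiseAlignment(row_a, row_b))
        assert len(inv) == 1
        assert inv[0].interval_a == (50, 90)
        assert inv[0].length == 40

    def test_short_mismatch_runs_ignored(self):
        aln = PairwiseAlignment("ACGTACGTA", "ACGTTCGTA")
        assert detect_inversions(aln) == []

    def test_palindromic_inversion_is_invisible(self):
        # flipping a self-reverse-complement block changes nothing, so no
        # (duplicate) event can be reported for it
        s = "AACCAACCAA"
        pal = s + revcomp(s)  # self reverse-complement
        assert revcomp(pal) == pal
        flank = "GGGGGTTTTTCCCCC"
        row_a = flank + pal + flank
        row_b = flank + revcomp(pal) + flank
        aln = PairwiseAlignment(row_a, row_b)
        assert row_a == row_b
        assert detect_inversions(aln) == []


class TestATProfiles:
    def test_single_event_profile(self):
        ev = IndelEvent(columns=(0, 2), carrier="a", indel_seq="AT", length=2,
                        klass=OTHER)
        prof = indel_at_profiles([ev])
        assert prof[OTHER]["values"] == [1.0]

    def test_mean_and_median_arithmetic(self):
        evs = [
            IndelEvent(columns=(0, 4), carrier="a", indel_seq="AAAA", length=4,
                       klass=OTHER),
            IndelEvent(columns=(5, 9), carrier="a", indel_seq="GGGG", length=4,
                       klass=OTHER),
        ]
        prof = indel_at_profiles(evs)
        assert prof[OTHER]["mean"] == pytest.approx(0.5)
        assert prof[OTHER]["median"] == pytest.approx(0.5)

    def test_empty_class_is_not_an_error(self):
        prof = indel_at_profiles([])
        assert prof[POLY_N]["n"] == 0


class TestSNPNeighborhood:
    def _profile(self, bases, snp_col, radii):
        from plastscan.variants import SNP

        cons = consensus(PairwiseAlignment(bases, bases))
        snp = SNP(column=snp_col, pos_a=snp_col, pos_b=snp_col,
                  base_a="A", base_b="C")
        return snp_neighborhood_at(cons, [snp], radii=radii)

    def test_all_at_flanks(self):
        prof = self._profile("TTTTTGAAAAA", 5, radii=(5,))
        assert prof.at[0, 0] == pytest.approx(1.0)

    def test_all_gc_flanks(self):
        prof = self._profile("GGGGGACCCCC", 5, radii=(5,))
        assert prof.at[0, 0] == pytest.approx(0.0)

    def test_snp_site_excluded_from_window(self):
        # flanks are G/C only; the A at the SNP site must not count
        prof = self._profile("GGAGG", 2, radii=(2,))
        assert prof.at[0, 0] == pytest.approx(0.0)

    def test_truncated_windows_flagged(self):
        prof = self._profile("ACGTACGT", 1, radii=(5,))
        assert prof.truncated[0, 0]

    def test_window_recomputable_from_base_counts(self, small_pair):
        # conservation: profile at the largest radius equals a direct count
        truth = small_pair[2]
        aln = truth.alignment
        cons = consensus(aln)
        snps = call_snps(aln)[:50]
        prof = snp_neighborhood_at(cons, snps, radii=(100,))
        for i, snp in enumerate(snps):
            c = snp.column
            lo, hi = max(0, c - 100), min(len(cons), c + 101)
            window = cons.bases[:c][lo:] + cons.bases[c + 1 : hi]
            at = sum(window.count(b) for b in "AT")
            det = at + sum(window.count(b) for b in "GC")
            expected = at / det if det else np.nan
            assert prof.at[i, 0] == pytest.approx(expected)

    def test_nonpositive_radius_rejected(self, small_pair):
        cons = consensus(small_pair[2].alignment)
        with pytest.raises(ValueError):
            snp_neighborhood_at(cons, [], radii=(0,))
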