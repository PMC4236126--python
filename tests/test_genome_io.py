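"""Genome parsing, quadripartite detection and region extraction."""
from __future__ import annotations

import numpy as np
import pytest

from plastscan.genome_io import (
    AnnotatedGenome,
    Feature,
    StructureNotFoundError,
    ValidationError,
    at_content,
    detect_quadripartite,
    extract_noncoding_regions,
    gc_content,
    read_annotated_genome,
    revcomp,
    write_genbank,
)
from plastscan.synthetic_data import SimConfig, simulate_genome


class TestReadGenbank:
    def test_toy_record_features_and_coordinates(self, toy_genbank):
        g = read_annotated_genome(toy_genbank)
        assert g.id.startswith("TOY00001")
        assert len(g) == 600
        assert g.circular
        by_name = {f.name: f for f in g.features}
        assert set(by_name) == {"geneA", "geneB", "trnX", "geneC"}
        assert by_name["geneA"].intervals == ((0, 100),)
        assert by_name["geneB"].intervals == ((160, 360),)
        assert by_name["geneB"].strand == "-"
        assert by_name["trnX"].kind == "tRNA"
        assert by_name["geneC"].intervals == ((480, 520), (540, 580))

    def test_roundtrip_through_genbank(self, tmp_path):
        g = simulate_genome(SimConfig(genome_length=40_000, ir_length=8_000,
                                      n_genes=12, n_trnas=6, seed=2))
        path = tmp_path / "sim.gb"
        write_genbank(g, path)
        g2 = read_annotated_genome(path)
        assert g2.sequence == g.sequence
        assert g2.circular == g.circular
        key = lambda f: (f.name, f.kind, f.strand, f.intervals)
        assert sorted(map(key, g2.features)) == sorted(map(key, g.features))

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            read_annotated_genome(tmp_path / "nope.gb")

    def test_feature_outside_bounds_names_feature(self):
        with pytest.raises(ValidationError, match="bad"):
            AnnotatedGenome(id="x", sequence="ACGT" * 10, features=[
                Feature(name="bad", kind="gene", strand="+", intervals=((30, 50),))
            ])


class TestQuadripartite:
    def test_planted_ir_recovered_exactly(self):
        cfg = SimConfig(genome_length=160_000, ir_length=25_000, seed=3)
        g = simulate_genome(cfg)
        qs = detect_quadripartite(g)
        assert qs.ir_length == 25_000
        # the simulator lays out LSC | IRa | SSC | IRb
        ssc = int(cfg.ssc_fraction * cfg.genome_length)
        lsc = cfg.genome_length - 2 * 25_000 - ssc
        assert qs.ira == (lsc, lsc + 25_000)
        assert qs.irb == (lsc + 25_000 + ssc, cfg.genome_length)

    def test_tiling_invariant(self):
        g = simulate_genome(SimConfig(seed=4))
        qs = detect_quadripartite(g)
        assert qs.lsc_length + qs.ssc_length + 2 * qs.ir_length == len(g)

    def test_random_sequence_has_no_structure(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        g = AnnotatedGenome(id="r", sequence=seq, features=[
            Feature(name="g1", kind="gene", strand="+", intervals=((10, 500),))
        ])
        with pytest.raises(StructureNotFoundError):
            detect_quadripartite(g, min_ir_len=10_000)

    def test_annotated_ir_takes_precedence(self):
        g = simulate_genome(SimConfig(genome_length=60_000, ir_length=11_000,
                                      n_genes=20, n_trnas=8, seed=5))
        qs_detected = detect_quadripartite(g)
        g.features.append(Feature(name="IRa", kind="IR", strand="+",
                                  intervals=(qs_detected.ira,)))
        g.features.append(Feature(name="IRb", kind="IR", strand="+",
                                  intervals=(qs_detected.irb,)))
        qs = detect_quadripartite(g)
        assert (qs.ira, qs.irb) == (qs_detected.ira, qs_detected.irb)


def _linear_genome(features, length=1_000):
    seq = ("ACGTTGCA" * ((length // 8) + 1))[:length]
    return AnnotatedGenome(id="t", sequence=seq, circular=False,
                           features=features)


class TestRegionExtraction:
    def test_short_spacer_dropped(self):
        g = _linear_genome([
            Feature("geneA", "gene", "+", ((0, 100),)),
            Feature("geneB", "gene", "+", ((150, 400),)),
        ])
        regions = extract_noncoding_regions(g, dedupe_ir=False)
        assert [r.name for r in regions if r.kind == "spacer"] == []

    def test_spacer_retained_with_flank_names(self):
        g = _linear_genome([
            Feature("geneA", "gene", "+", ((0, 100),)),
            Feature("geneB", "gene", "+", ((220, 400),)),
        ])
        regions = extract_noncoding_regions(g, dedupe_ir=False)
        spacers = [r for r in regions if r.kind == "spacer"]
        assert len(spacers) == 1
        assert spacers[0].name == "geneA-geneB"
        assert spacers[0].interval == (100, 220)
        assert spacers[0].length == 120

    def test_spacer_boundaries_abut_features_exactly(self):
        g = _linear_genome([
            Feature("a", "gene", "+", ((0, 150),)),
            Feature("b", "gene", "-", ((300, 500),)),
            Feature("c", "tRNA", "+", ((640, 720),)),
        ])
        regions = extract_noncoding_regions(g, dedupe_ir=False)
        assert [(r.name, r.interval) for r in regions] == [
            ("a-b", (150, 300)), ("b-c", (500, 640)),
        ]

    def test_trnk_intron_split_at_matk(self):
        g = _linear_genome([
            Feature("trnK", "tRNA", "+", ((0, 37), (2000, 2035))),
            Feature("matK", "gene", "+", ((300, 1800),)),
            Feature("geneZ", "gene", "+", ((2200, 2500),)),
        ], length=2_600)
        regions = extract_noncoding_regions(g, dedupe_ir=False)
        names = {r.name: r for r in regions}
        assert names["trnK intron 5'"].interval == (37, 300)
        assert names["trnK intron 3'"].interval == (1800, 2000)

    def test_trnk_split_follows_strand(self):
        g = _linear_genome([
            Feature("trnK", "tRNA", "-", ((0, 37), (2000, 2035))),
            Feature("matK", "gene", "-", ((300, 1800),)),
            Feature("geneZ", "gene", "+", ((2200, 2500),)),
        ], length=2_600)
        names = {r.name: r for r in
                 extract_noncoding_regions(g, dedupe_ir=False)}
        assert names["trnK intron 3'"].interval == (37, 300)
        assert names["trnK intron 5'"].interval == (1800, 2000)

    def test_nested_feature_does_not_create_negative_spacer(self):
        # an embedded gene is absorbed into the host footprint
        g = _linear_genome([
            Feature("host", "gene", "+", ((0, 500),)),
            Feature("inner", "gene", "+", ((100, 400),)),
            Feature("next", "gene", "+", ((700, 900),)),
        ])
        regions = extract_noncoding_regions(g, dedupe_ir=False)
        assert [(r.name, r.interval) for r in regions] == [("host-next", (500, 700))]

    def test_partition_no_overlap(self, default_pair):
        genome = default_pair[0]
        regions = extract_noncoding_regions(genome, dedupe_ir=False)
        flat = sorted(r.interval for r in regions if not r.wraps)
        for (s1, e1), (s2, e2) in zip(flat, flat[1:]):
            assert e1 <= s2, "regions overlap on the reference"

    def test_ir_duplicates_marked_once(self, default_pair):
        genome = default_pair[0]
        regions = extract_noncoding_regions(genome, dedupe_ir=True)
        copies = [r for r in regions if r.copy_of is not None]
        assert copies, "expected IR duplicate regions"
        originals = {r.name for r in regions if r.copy_of is None}
        assert all(r.copy_of in originals for r in copies)


class TestBaseComposition:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 1.0),
        ("ATGCN", 0.5),
        ("AATT", 0.0),
    ])
    def test_gc_content_definition(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")

    def test_gc_plus_at_is_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 200)))
            assert gc_content(seq) + at_content(seq) == pytest.approx(1.0)

    def test_revcomp_involution(self):
        assert revcomp("ACGT") == "ACGT"
        assert revcomp(revcomp("AACGTTGCA")) == "AACGTTGCA"
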