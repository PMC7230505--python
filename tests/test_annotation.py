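"""Interval algebra, negative-annotation construction, and GTF round trips."""

import numpy as np
import pytest

from introshift.annotation import (
    CompartmentAnnotation,
    GeneModel,
    GenomicInterval,
    build_intergenic_annotation,
    build_intron_annotation,
    merge_intervals,
    parse_gene_gtf,
    parse_repeat_annotation,
    read_gtf_annotation,
    subtract_intervals,
    write_gtf,
)

from conftest import (
    base_mask,
    intervals_as_triples,
    mask_to_intervals,
    random_gene_set,
    random_intervals,
)


def iv(start, end, seq="chr1", strand=".", fid="", attrs=None):
    return GenomicInterval(seq, start, end, strand, fid, attrs or {})


class TestGenomicInterval:
    def test_rejects_empty_and_inverted(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 20, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_gene_rejects_exon_outside_span(self):
        span = iv(100, 200, fid="G1")
        with pytest.raises(ValueError, match="G1"):
            GeneModel("G1", span, [iv(150, 250)])


class TestMergeSubtract:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([(10, 20), (15, 30)], [(10, 30)]),
            ([(10, 20), (20, 30)], [(10, 30)]),  # abutting merge, half-open
            ([(10, 20), (25, 30)], [(10, 20), (25, 30)]),
            ([], []),
        ],
    )
    def test_merge_examples(self, pairs, expected):
        got = merge_intervals([iv(s, e) for s, e in pairs])
        assert [(g.start, g.end) for g in got] == expected

    @pytest.mark.parametrize(
        "minuend,subtrahend,expected",
        [
            ([(0, 1000)], [(0, 100), (200, 300), (950, 1000)], [(100, 200), (300, 950)]),
            ([(0, 1000)], [], [(0, 1000)]),
            ([(0, 100)], [(0, 100)], []),
        ],
    )
    def test_subtract_examples(self, minuend, subtrahend, expected):
        got = subtract_intervals(
            [iv(s, e) for s, e in minuend], [iv(s, e) for s, e in subtrahend]
        )
        assert [(g.start, g.end) for g in got] == expected

    def test_merge_matches_per_base_oracle_on_random_input(self, rng):
        for _ in range(20):
            ivs = random_intervals(rng, 100, 5000)
            got = intervals_as_triples(merge_intervals(ivs))
            assert got == mask_to_intervals(base_mask(ivs, "chr1", 5000), "chr1")

    def test_subtract_matches_per_base_oracle_on_random_input(self, rng):
        for _ in range(20):
            a = random_intervals(rng, 40, 5000)
            b = random_intervals(rng, 40, 5000)
            got = intervals_as_triples(subtract_intervals(a, b))
            mask = base_mask(a, "chr1", 5000) & ~base_mask(b, "chr1", 5000)
            assert got == mask_to_intervals(mask, "chr1")

    def test_merge_is_strand_blind_and_multi_sequence(self):
        got = merge_intervals([iv(0, 10, strand="+"), iv(5, 20, strand="-"), iv(0, 5, seq="chr2")])
        assert intervals_as_triples(got) == [("chr1", 0, 20), ("chr2", 0, 5)]


class TestGeneGtfParsing:
    def test_coordinates_and_hull(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "A";\n'
            'chr1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "A";\n'
            'chr1\tsrc\texon\t1\t100\t.\t-\t.\tgene_id "B";\n'
            'chr1\tsrc\texon\t201\t300\t.\t-\t.\tgene_id "B";\n'
        )
        genes = {g.gene_id: g for g in parse_gene_gtf(gtf)}
        assert (genes["A"].span.start, genes["A"].span.end) == (100, 200)
        # no gene record for B: span is the hull of its exons
        assert (genes["B"].span.start, genes["B"].span.end) == (0, 300)

    def test_duplicate_gene_id_across_sequences_is_an_error(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t1\t100\t.\t+\t.\tgene_id "A";\n'
            'chr2\tsrc\tgene\t1\t100\t.\t+\t.\tgene_id "A";\n'
        )
        with pytest.raises(ValueError, match="multiple sequences"):
            parse_gene_gtf(gtf)

    def test_malformed_line_names_line_number(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text('chr1\tsrc\tgene\t1\t100\t.\t+\t.\tgene_id "A";\nnot a gtf line\n')
        with pytest.raises(ValueError, match="line 2"):
            parse_gene_gtf(gtf)

    def test_exon_without_gene_id_is_skipped(self, tmp_path, caplog):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "A";\n'
            'chr1\tsrc\texon\t200\t300\t.\t+\t.\tother "x";\n'
        )
        genes = parse_gene_gtf(gtf)
        assert [g.gene_id for g in genes] == ["A"]


class TestIntronConstruction:
    def test_single_gene_introns(self):
        g = GeneModel(
            "A",
            iv(0, 1000, fid="A"),
            [iv(0, 100), iv(200, 300), iv(950, 1000)],
        )
        ann = build_intron_annotation([g])
        assert intervals_as_triples(ann.features) == [("chr1", 100, 200), ("chr1", 300, 950)]
        assert all(f.attributes["gene_id"] == "A" for f in ann.features)

    def test_overlapping_gene_exon_carves_other_genes_intron(self):
        a = GeneModel("A", iv(0, 1000, fid="A"), [iv(0, 100)])
        b = GeneModel("B", iv(500, 900, fid="B"), [iv(500, 900)])
        ann = build_intron_annotation([a, b])
        assert intervals_as_triples(ann.features) == [("chr1", 100, 500), ("chr1", 900, 1000)]
        assert [f.attributes["gene_id"] for f in ann.features] == ["A", "A"]

    def test_single_exon_gene_contributes_no_intron(self):
        g = GeneModel("A", iv(0, 500, fid="A"), [iv(0, 500)])
        b = GeneModel("B", iv(1000, 2000, fid="B"), [iv(1000, 1100), iv(1900, 2000)])
        ann = build_intron_annotation([g, b])
        assert all(f.attributes["gene_id"] == "B" for f in ann.features)

    def test_shared_intron_carries_both_host_ids(self):
        a = GeneModel("A", iv(0, 1000, fid="A"), [iv(0, 100), iv(900, 1000)])
        b = GeneModel("B", iv(50, 950, fid="B"), [iv(50, 100), iv(900, 950)])
        ann = build_intron_annotation([a, b])
        assert intervals_as_triples(ann.features) == [("chr1", 100, 900)]
        assert ann.features[0].attributes["gene_id"] == "A,B"

    def test_every_intron_contained_in_a_host_span(self, rng):
        for _ in range(10):
            genes = random_gene_set(rng)
            ann = build_intron_annotation(genes)
            for f in ann.features:
                hosts = f.attributes["gene_id"].split(",")
                assert hosts and all(h for h in hosts)
                for h in hosts:
                    g = next(g for g in genes if g.gene_id == h)
                    assert g.span.start <= f.start and f.end <= g.span.end

    def test_exon_intron_partition_of_gene_spans(self, rng):
        """Merged exon bases and intron bases partition the gene-span bases."""
        for _ in range(15):
            genes = random_gene_set(rng, seq_len=8000)
            intron = build_intron_annotation(genes)
            span_mask = base_mask([g.span for g in genes], "chr1", 8000)
            exon_mask = base_mask([e for g in genes for e in g.exons], "chr1", 8000)
            intron_mask = base_mask(intron.features, "chr1", 8000)
            assert not (exon_mask & intron_mask).any()
            assert ((exon_mask | intron_mask) == span_mask).all()

    def test_idempotence_exons_equal_spans_yield_nothing(self):
        genes = [
            GeneModel("A", iv(0, 500, fid="A"), [iv(0, 500)]),
            GeneModel("B", iv(600, 900, fid="B"), [iv(600, 900)]),
        ]
        assert len(build_intron_annotation(genes)) == 0

    def test_strand_aware_mode_keeps_antisense_introns(self):
        a = GeneModel("A", iv(0, 1000, fid="A", strand="+"), [iv(0, 100, strand="+")], "+")
        b = GeneModel("B", iv(400, 600, fid="B", strand="-"), [iv(400, 600, strand="-")], "-")
        blind = build_intron_annotation([a, b])
        aware = build_intron_annotation([a, b], strand_aware=True)
        assert intervals_as_triples(blind.features) == [("chr1", 100, 400), ("chr1", 600, 1000)]
        # on the + strand B's exon does not carve A's intron
        plus = [f for f in aware.features if f.strand == "+"]
        assert intervals_as_triples(plus) == [("chr1", 100, 1000)]


class TestIntergenic:
    def test_complement_examples(self):
        g = GeneModel("A", iv(100, 200, fid="A"), [iv(100, 200)])
        ann = build_intergenic_annotation([g], {"chr1": 300})
        assert intervals_as_triples(ann.features) == [("chr1", 0, 100), ("chr1", 200, 300)]
        full = GeneModel("B", iv(0, 300, fid="B"), [iv(0, 300)])
        assert len(build_intergenic_annotation([full], {"chr1": 300})) == 0

    def test_gene_beyond_sequence_length_is_an_error(self):
        g = GeneModel("A", iv(100, 400, fid="A"), [iv(100, 400)])
        with pytest.raises(ValueError, match="beyond declared length"):
            build_intergenic_annotation([g], {"chr1": 300})

    def test_complement_matches_per_base_oracle(self, rng):
        for _ in range(10):
            genes = random_gene_set(rng, seq_len=6000)
            ann = build_intergenic_annotation(genes, {"chr1": 6000})
            mask = ~base_mask([g.span for g in genes], "chr1", 6000)
            assert intervals_as_triples(ann.features) == mask_to_intervals(mask, "chr1")


class TestRepeatAnnotation:
    def test_ucsc_rmsk_row_with_bin_column(self, tmp_path):
        row = "\t".join(
            ["607", "1234", "50", "10", "5", "chr1", "1000", "1500", "-100000", "+",
             "L1-2_EC", "LINE", "L1", "1", "500", "0", "7"]
        )
        p = tmp_path / "rmsk.txt"
        p.write_text(row + "\n")
        ann = parse_repeat_annotation(p)
        f = ann.features[0]
        assert (f.start, f.end) == (1000, 1500)  # genoStart already 0-based
        assert f.attributes["repeat_class"] == "LINE"
        assert f.attributes["repeat_family"] == "L1"

    def test_two_loci_of_same_name_get_distinct_ids(self, tmp_path):
        p = tmp_path / "rmsk.tsv"
        p.write_text(
            "chr1\t100\t200\t+\tL1-2_EC\tLINE\tL1\n"
            "chr1\t400\t500\t+\tL1-2_EC\tLINE\tL1\n"
        )
        ann = parse_repeat_annotation(p)
        assert len({f.feature_id for f in ann.features}) == 2

    def test_missing_class_becomes_unknown(self, tmp_path):
        p = tmp_path / "rmsk.tsv"
        p.write_text("chr1\t100\t200\t+\tMysteryRep\t\t\n")
        ann = parse_repeat_annotation(p)
        assert ann.features[0].attributes["repeat_class"] == "Unknown"

    def test_gtf_round_trip_preserves_feature_set(self, tmp_path, rng):
        feats = []
        for i, r in enumerate(random_intervals(rng, 30, 10_000)):
            r.attributes = {
                "repeat_name": f"rep{i % 5}",
                "repeat_class": ["LINE", "SINE", "LTR"][i % 3],
                "repeat_family": "fam",
            }
            r.feature_id = f"rep{i % 5}|chr1:{r.start}-{r.end}#{i}"
            r.strand = "+"
            feats.append(r)
        ann = CompartmentAnnotation("repeat", feats)
        p = tmp_path / "rep.gtf"
        write_gtf(ann, p)
        back = parse_repeat_annotation(p, dialect="gtf")
        orig = sorted(
            (f.seq_id, f.start, f.end, f.strand, f.feature_id, tuple(sorted(f.attributes.items())))
            for f in ann.features
        )
        got = sorted(
            (f.seq_id, f.start, f.end, f.strand, f.feature_id, tuple(sorted(f.attributes.items())))
            for f in back.features
        )
        assert got == orig


class TestGtfIO:
    def test_coordinate_convention(self, tmp_path):
        ann = CompartmentAnnotation("intron", [iv(100, 200, fid="i0", attrs={"gene_id": "A"})])
        p = tmp_path / "x.gtf"
        write_gtf(ann, p)
        cols = p.read_text().strip().split("\t")
        assert (cols[3], cols[4]) == ("101", "200")

    def test_empty_annotation_writes_empty_file(self, tmp_path):
        p = tmp_path / "x.gtf"
        write_gtf(CompartmentAnnotation("intron", []), p)
        assert p.read_text() == ""
        assert len(read_gtf_annotation(p, "intron")) == 0

    def test_round_trip_identity_random(self, tmp_path, rng):
        for trial in range(20):
            feats = []
            for i in range(int(rng.integers(0, 25))):
                s = int(rng.integers(0, 10_000))
                ln = int(rng.integers(1, 500))
                strand = ["+", "-", "."][int(rng.integers(0, 3))]
                attrs = {"gene_id": f"G{i % 4}"} if rng.random() < 0.5 else {}
                feats.append(GenomicInterval("chr1", s, s + ln, strand, f"f{i}", attrs))
            ann = CompartmentAnnotation("exon", feats)
            p = tmp_path / f"rt{trial}.gtf"
            write_gtf(ann, p)
            back = read_gtf_annotation(p, "exon")
            assert [
                (f.seq_id, f.start, f.end, f.strand, f.feature_id, f.attributes)
                for f in back.features
            ] == [
                (f.seq_id, f.start, f.end, f.strand, f.feature_id, f.attributes)
                for f in ann.features
            ]
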