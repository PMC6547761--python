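"""Annotation parsing and exon classification against definitions and oracles."""

import numpy as np
import pytest

from asnmd.annotation import (
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    classify_essential,
    classify_gwn,
    classify_poison,
    find_cassette_exons,
    frame_class,
    label_nmd,
    parse_annotation,
    relative_position,
)
from conftest import write_toy_fasta, write_toy_gtf
from _oracles import cassette_oracle, essential_oracle, random_coding_transcript, random_gene_structure


def _attrs(gene, tx=None, biotype="protein_coding"):
    s = f'gene_id "{gene}";'
    if tx:
        s += f' transcript_id "{tx}"; transcript_type "{biotype}";'
    return s


class TestParseAnnotation:
    def test_counts_and_coordinate_conversion(self, tmp_path):
        lines = [
            "\t".join(["chr1", "t", "gene", "101", "900", ".", "+", ".", _attrs("g1")]),
            "\t".join(["chr1", "t", "transcript", "101", "600", ".", "+", ".", _attrs("g1", "t1")]),
            "\t".join(["chr1", "t", "exon", "101", "200", ".", "+", ".", _attrs("g1", "t1")]),
            "\t".join(["chr1", "t", "exon", "301", "400", ".", "+", ".", _attrs("g1", "t1")]),
            "\t".join(["chr1", "t", "exon", "501", "600", ".", "+", ".", _attrs("g1", "t1")]),
            "\t".join(["chr1", "t", "transcript", "101", "400", ".", "+", ".", _attrs("g1", "t2")]),
            "\t".join(["chr1", "t", "exon", "101", "200", ".", "+", ".", _attrs("g1", "t2")]),
            "\t".join(["chr1", "t", "exon", "301", "400", ".", "+", ".", _attrs("g1", "t2")]),
        ]
        genes = parse_annotation(write_toy_gtf(tmp_path / "a.gtf", lines))
        assert len(genes) == 1
        assert len(genes[0].transcripts) == 2
        t1 = next(t for t in genes[0].transcripts if t.transcript_id == "t1")
        assert t1.exons[0] == (100, 200)  # 1-based [101,200] -> 0-based [100,200)
        assert len(t1.exons) == 3

    def test_minus_strand_transcript_orientation(self, tmp_path):
        lines = [
            "\t".join(["chr1", "t", "gene", "101", "600", ".", "-", ".", _attrs("g1")]),
            "\t".join(["chr1", "t", "transcript", "101", "600", ".", "-", ".", _attrs("g1", "t1")]),
            "\t".join(["chr1", "t", "exon", "101", "200", ".", "-", ".", _attrs("g1", "t1")]),
            "\t".join(["chr1", "t", "exon", "501", "600", ".", "-", ".", _attrs("g1", "t1")]),
        ]
        genes = parse_annotation(write_toy_gtf(tmp_path / "a.gtf", lines))
        t = genes[0].transcripts[0]
        assert t.exons == [(500, 600), (100, 200)]  # 5'->3' on the minus strand

    def test_malformed_line_reports_line_number(self, tmp_path):
        lines = [
            "\t".join(["chr1", "t", "gene", "101", "900", ".", "+", ".", _attrs("g1")]),
            "chr1\tonly\tthree",
        ]
        with pytest.raises(ValueError, match="line 2"):
            parse_annotation(write_toy_gtf(tmp_path / "a.gtf", lines))

    def test_absent_chromosome_errors(self, tmp_path):
        lines = [
            "\t".join(["chrZ", "t", "gene", "101", "200", ".", "+", ".", _attrs("g1")]),
            "\t".join(["chrZ", "t", "transcript", "101", "200", ".", "+", ".", _attrs("g1", "t1")]),
            "\t".join(["chrZ", "t", "exon", "101", "200", ".", "+", ".", _attrs("g1", "t1")]),
        ]
        fasta = write_toy_fasta(tmp_path / "g.fa", {"chr1": "ACGT" * 100})
        with pytest.raises(ValueError, match="chrZ"):
            parse_annotation(write_toy_gtf(tmp_path / "a.gtf", lines), fasta)


def _coding_transcript(stop_codon, biotype="protein_coding"):
    """3-exon plus-strand transcript; spliced exon blocks are 100 nt each."""
    return TranscriptModel(
        transcript_id="t",
        gene_id="g",
        chrom="chr1",
        strand="+",
        exons=[(0, 100), (200, 300), (400, 500)],
        cds=[(10, 100), (200, 250)],
        stop_codon=[stop_codon],
        biotype=biotype,
    )


class TestNmdRule:
    def test_stop_60nt_upstream_of_last_junction_is_nmd(self):
        # last junction at spliced 200; stop codon ends at spliced 140
        t = _coding_transcript(stop_codon=(237, 240))
        assert label_nmd(t) is True
        assert t.nmd_source == "rule"

    def test_exactly_50nt_is_not_nmd(self):
        t = _coding_transcript(stop_codon=(247, 250))  # ends at spliced 150
        assert label_nmd(t) is False

    def test_51nt_is_nmd(self):
        t = _coding_transcript(stop_codon=(246, 249))  # ends at spliced 149
        assert label_nmd(t) is True

    def test_single_exon_transcript_never_nmd(self):
        t = TranscriptModel("t", "g", "chr1", "+", exons=[(0, 500)],
                            cds=[(10, 100)], stop_codon=[(100, 103)])
        assert label_nmd(t) is False

    def test_biotype_tag_overrides_rule(self):
        t = _coding_transcript(stop_codon=(247, 250), biotype="nonsense_mediated_decay")
        assert label_nmd(t) is True
        assert t.nmd_source == "tag"

    def test_no_cds_flagged_not_nmd(self):
        t = TranscriptModel("t", "g", "chr1", "+", exons=[(0, 100), (200, 300)])
        assert label_nmd(t) is False
        assert t.nmd_source == "no_cds"


class TestGwn:
    def _gene(self, labels):
        txs = []
        for i, nmd in enumerate(labels):
            t = TranscriptModel(f"t{i}", "g", "chr1", "+", exons=[(0, 100)])
            t.nmd = nmd
            txs.append(t)
        return GeneModel("g", "chr1", "+", txs)

    def test_any_nmd_isoform_makes_gwn(self):
        assert classify_gwn(self._gene([False, True])) == "GWN"

    def test_all_productive_is_gwo(self):
        assert classify_gwn(self._gene([False, False])) == "GWO"

    def test_empty_gene_warns_gwo(self):
        with pytest.warns(UserWarning):
            assert classify_gwn(GeneModel("g", "chr1", "+", [])) == "GWO"


def _gene_from_transcript_exons(tx_exons, strand="+"):
    txs = [
        TranscriptModel(f"t{i}", "g", "chr1", strand, exons=list(ex))
        for i, ex in enumerate(tx_exons)
    ]
    return GeneModel("g", "chr1", strand, txs)


class TestCassette:
    A, B, C = (0, 100), (200, 300), (400, 500)

    def test_skipping_isoform_defines_cassette(self):
        gene = _gene_from_transcript_exons([[self.A, self.B, self.C], [self.A, self.C]])
        ctx = find_cassette_exons(gene)
        assert list(ctx) == [self.B]
        assert ctx[self.B] == [(100, 400)]

    def test_no_skipping_intron_no_cassette(self):
        gene = _gene_from_transcript_exons([[self.A, self.B, self.C]])
        assert find_cassette_exons(gene) == {}

    def test_matches_bruteforce_on_random_structures(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            exons, introns, tx = random_gene_structure(rng)
            gene = _gene_from_transcript_exons(tx)
            got = set(find_cassette_exons(gene))
            expected = cassette_oracle(exons, introns)
            assert got == expected


class TestPoison:
    def _gene(self, stop, nmd=True):
        t = TranscriptModel(
            "t1", "g", "chr1", "+",
            exons=[(0, 100), (200, 300), (400, 500)],
            cds=[(10, 100)], stop_codon=[stop],
        )
        t.nmd = nmd
        return GeneModel("g", "chr1", "+", [t])

    def test_stop_inside_cassette_exon(self):
        assert classify_poison((200, 300), self._gene((250, 253))) is True

    def test_gwo_gene_has_no_poison(self):
        assert classify_poison((200, 300), self._gene((250, 253), nmd=False)) is False

    def test_partial_overlap_counts(self):
        # stop codon straddles the exon's 3' boundary: bases 298,299 inside
        assert classify_poison((200, 300), self._gene((298, 301))) is True

    def test_disjoint_stop_is_not_poison(self):
        assert classify_poison((200, 300), self._gene((300, 303))) is False


class TestEssential:
    def test_matches_translation_oracle_on_random_transcripts(self):
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 200:
            exons, strand, cds_start, chrom_seq, internal = random_coding_transcript(rng)
            if not internal:
                continue
            genome = GenomeSequence.from_dict({"chr1": chrom_seq})
            if strand == "+":
                cds = [(cds_start, exons[-1][1])]
            else:
                cds = [(exons[0][0], cds_start + 1)]
            t = TranscriptModel("t", "g", "chr1", strand, exons=exons, cds=cds)
            exon = internal[int(rng.integers(0, len(internal)))]
            got = classify_essential(exon, t, genome)
            expected = essential_oracle(exon, exons, cds_start, strand, chrom_seq)
            assert got == expected
            checked += 1

    def test_exon_not_in_transcript_errors(self):
        genome = GenomeSequence.from_dict({"chr1": "A" * 1000})
        t = TranscriptModel("t", "g", "chr1", "+", exons=[(0, 100), (200, 300)],
                            cds=[(10, 100)])
        with pytest.raises(ValueError):
            classify_essential((500, 600), t, genome)


class TestFrameAndPosition:
    @pytest.mark.parametrize(
        "length,expected", [(67, "3n+1"), (90, "3n"), (2, "3n+2"), (3, "3n")]
    )
    def test_frame_class(self, length, expected):
        assert frame_class((0, length)) == expected

    def test_relative_position_endpoints_and_interpolation(self):
        t = TranscriptModel(
            "t", "g", "chr1", "+",
            exons=[(0, 100), (200, 1100), (1200, 1300)],
        )
        # spliced midpoints: 50, 550, 1050
        assert relative_position((0, 100), t) == 0.0
        assert relative_position((1200, 1300), t) == 100.0
        assert relative_position((200, 1100), t) == 50.0

    def test_relative_position_monotone_in_transcript_order(self):
        rng = np.random.default_rng(3)
        for strand in "+-":
            exons, _, _, _, _ = random_coding_transcript(rng)
            t = TranscriptModel("t", "g", "chr1", strand, exons=exons)
            values = [relative_position(iv, t) for iv in t.exons]
            assert values == sorted(values)

    def test_single_exon_is_50pct(self):
        t = TranscriptModel("t", "g", "chr1", "+", exons=[(0, 100)])
        assert relative_position((0, 100), t) == 50.0
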