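"""GenBank parsing, genome partitioning, and region-set extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifmc import genome_io as gio
from motifmc.alphabet import revcomp
from motifmc.genome_io import (CdsFeature, GenomeRecord, GenomeParseError,
                               extract_region_set, partition_genome,
                               read_genbank, write_genbank)


class TestReadGenbank:
    def test_plus_strand_cds_coordinates(self, toy_gb_factory):
        g = read_genbank(toy_gb_factory("7..36"))
        assert g.length == 60
        (f,) = g.features
        assert (f.start, f.end, f.strand, f.compound) == (6, 36, "+", False)

    def test_complement_location(self, toy_gb_factory):
        (f,) = read_genbank(toy_gb_factory("complement(7..36)")).features
        assert (f.start, f.end, f.strand) == (6, 36, "-")

    def test_join_location_flagged_compound(self, toy_gb_factory):
        (f,) = read_genbank(toy_gb_factory("join(7..18,22..36)")).features
        assert f.compound
        assert f.parts == ((6, 18), (21, 36))

    def test_origin_lowercase_and_ambiguity_to_n(self, toy_gb_factory):
        origin = ("ORIGIN\n        1 acgtrcgtac gtacgtacgt nacgtacgta"
                  " cgtacgtacg tacgtacgta cgtacgtacg\n//\n")
        g = read_genbank(toy_gb_factory(origin=origin))
        assert g.length == 60
        assert set(g.sequence) <= set("ACGTN")
        assert g.sequence[4] == "N" and g.sequence[20] == "N"

    def test_missing_sequence_block_fatal(self, toy_gb_factory, tmp_path):
        text = (toy_gb_factory().read_text().split("ORIGIN")[0] + "//\n")
        p = tmp_path / "noseq.gb"
        p.write_text(text)
        with pytest.raises((GenomeParseError, ValueError)):
            read_genbank(p)

    def test_cds_outside_sequence_fatal(self):
        with pytest.raises(GenomeParseError):
            GenomeRecord("x", "ACGT" * 3,
                         features=[CdsFeature(0, 30, "+")])

    def test_zero_cds_warns_but_returns(self, tmp_path):
        g = GenomeRecord("empty", "ACGT" * 15)
        p = tmp_path / "nocds.gb"
        write_genbank(g, p)
        with pytest.warns(UserWarning, match="no CDS"):
            g2 = read_genbank(p)
        assert g2.sequence == g.sequence


class TestPartition:
    def test_single_cds(self):
        g = GenomeRecord("x", "ACGTACGTACGT",
                         features=[CdsFeature(3, 9, "+")])
        segs = [(s.start, s.end, s.klass) for s in partition_genome(g)]
        assert segs == [(0, 3, "intergenic"), (3, 9, "gene"),
                        (9, 12, "intergenic")]

    def test_overlap_earlier_gene_wins_whole(self):
        g = GenomeRecord("x", "ACGTACGTACGT",
                         features=[CdsFeature(0, 6, "+"),
                                   CdsFeature(3, 12, "+")])
        segs = [(s.start, s.end, s.klass) for s in partition_genome(g)]
        assert segs == [(0, 6, "gene"), (6, 12, "unmodeled")]

    def test_zero_cds_single_intergenic(self):
        part = partition_genome(GenomeRecord("x", "ACGT" * 5))
        assert [(s.start, s.end, s.klass) for s in part] == \
            [(0, 20, "intergenic")]

    def test_compound_and_frameshifted_cds_are_unmodeled(self):
        g = GenomeRecord(
            "x", "A" * 30,
            features=[CdsFeature(0, 6, "+", compound=True,
                                 parts=((0, 3), (3, 6))),
                      CdsFeature(10, 14, "+")])  # length 4, not codons
        klasses = {(s.start, s.end): s.klass for s in partition_genome(g)}
        assert klasses[(0, 6)] == "unmodeled"
        assert klasses[(10, 14)] == "unmodeled"

    @given(st.data())
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_partition_tiles_genome(self, data):
        n = data.draw(st.integers(30, 200))
        seq = "".join(data.draw(
            st.lists(st.sampled_from("ACGT"), min_size=n, max_size=n)))
        feats = []
        for _ in range(data.draw(st.integers(0, 6))):
            a = data.draw(st.integers(0, n - 2))
            b = data.draw(st.integers(a + 1, n))
            strand = data.draw(st.sampled_from("+-"))
            feats.append(CdsFeature(a, b, strand))
        part = partition_genome(GenomeRecord("x", seq, features=feats))
        assert sum(s.length for s in part) == n
        pos = 0
        for s in part:
            assert s.start == pos
            pos = s.end


class TestRegionSets:
    def _genome(self):
        # 6 nt ig, minus gene AAACCC at [6,12), 6 nt ig
        return GenomeRecord("x", "GGGTTT" + "AAACCC" + "GGGTTT",
                            features=[CdsFeature(6, 12, "-")])

    def test_genome_mode_is_whole_chromosome(self):
        g = self._genome()
        part = partition_genome(g)
        rs = extract_region_set(g, part, "genome")
        assert len(rs) == 1
        assert rs.entries[0].sequence == g.sequence
        assert rs.scan_mode == "both_strands"

    def test_minus_gene_coding_is_reverse_complement(self):
        g = self._genome()
        part = partition_genome(g)
        coding = extract_region_set(g, part, "coding").entries[0]
        template = extract_region_set(g, part, "template").entries[0]
        assert coding.sequence == "GGGTTT"  # rc of genome slice AAACCC
        assert template.sequence == "AAACCC"
        assert coding.scan_mode == "given_strand_only"

    def test_intergenic_entries(self):
        g = GenomeRecord("x", "ACGTACGTACGT",
                         features=[CdsFeature(3, 9, "+")])
        rs = extract_region_set(g, partition_genome(g), "intergenic")
        assert [len(e.sequence) for e in rs] == [3, 3]

    def test_unknown_mode_fatal(self):
        g = self._genome()
        with pytest.raises(ValueError):
            extract_region_set(g, partition_genome(g), "exonic")

    def test_coding_template_duality(self, small_genome):
        genome, part = small_genome
        cod = extract_region_set(genome, part, "coding")
        tem = extract_region_set(genome, part, "template")
        for c, t in zip(cod, tem):
            assert t.sequence == revcomp(c.sequence)


class TestRoundTrip:
    def test_write_read_preserves_sequence_and_features(self, small_genome,
                                                        tmp_path):
        genome, part = small_genome
        p = tmp_path / "g.gb"
        write_genbank(genome, p)
        g2 = read_genbank(p)
        assert g2.sequence == genome.sequence
        assert g2.features == genome.features
        part2 = partition_genome(g2)
        assert [(s.start, s.end, s.klass, s.strand) for s in part2] == \
            [(s.start, s.end, s.klass, s.strand) for s in part]

    def test_bed_export(self, small_genome, tmp_path):
        _, part = small_genome
        p = tmp_path / "part.bed"
        part.to_bed(p)
        lines = p.read_text().splitlines()
        assert len(lines) == len(part) + 1
        start, end, klass, strand = lines[1].split("\t")
        assert int(end) > int(start) and klass in (
            "gene", "intergenic", "unmodeled")
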