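import pytest

from phagecharm import genome_io
from phagecharm.genome_io import (
    GenomeParseError,
    estimate_terminal_redundancy,
    gc_skew_profile,
    genome_summary,
    read_fasta,
    read_genbank,
    rotate_origin,
    write_genbank,
)
from phagecharm.model import AnnotatedGenome, Feature, revcomp

from conftest import random_dna


class TestGenBankIO:
    def test_two_cds_fixture_round_trips(self, tmp_path, two_cds_genome, two_cds_genbank):
        genome = read_genbank(two_cds_genbank)
        assert len(genome.cds) == 2
        assert genome.sequence == two_cds_genome.sequence
        for orig, back in zip(two_cds_genome.features, genome.features):
            assert (back.start, back.end, back.strand) == (orig.start, orig.end, orig.strand)
        # second round trip is byte-stable on coordinates too
        again = tmp_path / "again.gb"
        write_genbank(genome, again)
        genome2 = read_genbank(again)
        assert [(f.start, f.end, f.strand) for f in genome2.features] == \
               [(f.start, f.end, f.strand) for f in genome.features]

    def test_truncated_file_without_origin_fails(self, tmp_path):
        bad = tmp_path / "bad.gb"
        bad.write_text("LOCUS       broken 100 bp DNA linear\nFEATURES\n")
        with pytest.raises(GenomeParseError):
            read_genbank(bad)

    def test_translations_kept(self, tmp_path):
        genome = AnnotatedGenome(
            "t", "ATGAAATAA" + "C" * 21, "linear",
            [Feature("CDS", 0, 9, "+", "g1", translation="MK")])
        path = tmp_path / "t.gb"
        write_genbank(genome, path)
        assert read_genbank(path).cds[0].translation == "MK"


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nACGT\n")
        g = read_fasta(p)
        assert len(g) == 4 and g.features == []

    def test_lowercase_is_uppercased(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nacgtn\n")
        assert read_fasta(p).sequence == "ACGTN"

    def test_empty_file_fails(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(GenomeParseError):
            read_fasta(p)

    def test_multi_record_error_names_count(self, tmp_path):
        p = tmp_path / "multi.fa"
        p.write_text(">a\nACGT\n>b\nACGT\n>c\nACGT\n")
        with pytest.raises(GenomeParseError, match="3"):
            read_fasta(p)


class TestSummary:
    def test_atgc_no_features(self):
        g = AnnotatedGenome("t", "ATGC")
        s = genome_summary(g)
        assert s.gc_percent == 50.0
        assert s.coding_fraction == 0
        assert s.trna_count == 0

    def test_tiling_cds_give_coding_fraction_one(self):
        seq = "ATG" + "AAA" * 10 + "TAA" + "ATG" + "CCC" * 10 + "TGA"
        g = AnnotatedGenome("t", seq, "linear", [
            Feature("CDS", 0, 36, "+", "a"),
            Feature("CDS", 36, 72, "+", "b"),
        ])
        assert genome_summary(g).coding_fraction == 1.0

    def test_overlapping_cds_counted_once(self):
        g = AnnotatedGenome("t", "A" * 100, "linear", [
            Feature("CDS", 0, 60, "+", "a"),
            Feature("CDS", 30, 90, "+", "b"),
        ])
        assert genome_summary(g).coding_fraction == 0.9

    def test_start_codon_usage_reads_the_sequence(self):
        # one + strand ATG gene, one - strand GTG gene (CAC at the right edge)
        seq = "ATG" + "AAA" * 31 + "TAA" + revcomp("GTG" + "CCC" * 31 + "TGA")
        L1 = 3 + 93 + 3
        g = AnnotatedGenome("t", seq, "linear", [
            Feature("CDS", 0, L1, "+", "a"),
            Feature("CDS", L1, 2 * L1, "-", "b"),
        ])
        usage = genome_summary(g).start_codon_usage
        assert usage == {"ATG": 50.0, "GTG": 50.0}
        assert abs(sum(usage.values()) - 100.0) <= 0.1

    def test_trna_gc_range(self):
        g = AnnotatedGenome("t", "GGGGGGGGGG" + "ATATATATAT", "linear", [
            Feature("tRNA", 0, 10, "+", "t1"),
            Feature("tRNA", 10, 20, "+", "t2"),
        ])
        s = genome_summary(g)
        assert s.trna_count == 2
        assert s.trna_gc_range == (0.0, 100.0)

    def test_generator_gc_reproduced_within_one_point(self, rng):
        from phagecharm.synthetic_data import GenomeSpec, generate_genome
        g, _ = generate_genome(GenomeSpec(length=50_000, gc=0.55, n_genes=10,
                                          n_promoters=2, n_terminators=2), seed=9)
        assert abs(genome_summary(g).gc_percent - 55.0) <= 1.0


class TestGcSkew:
    @pytest.mark.parametrize("seq,expected", [("GGGG", 1.0), ("CCCC", -1.0)])
    def test_pure_windows(self, seq, expected):
        (pt,) = gc_skew_profile(seq, 4, 4)
        assert pt.skew == expected and pt.defined

    def test_gc_free_window_is_flagged_zero(self):
        (pt,) = gc_skew_profile("ATAT", 4, 4)
        assert pt.skew == 0.0 and not pt.defined

    def test_bounds_and_revcomp_negation(self, rng):
        seq = random_dna(rng, 4000)
        prof = gc_skew_profile(seq, 500, 500)
        assert all(-1.0 <= p.skew <= 1.0 for p in prof)
        rc = gc_skew_profile(revcomp(seq), 500, 500)
        # window i of the reverse complement covers window n-1-i of the original
        assert all(abs(a.skew + b.skew) < 1e-12
                   for a, b in zip(prof, reversed(rc)))

    def test_window_longer_than_sequence_fails(self):
        with pytest.raises(ValueError):
            gc_skew_profile("ACGT", 5, 1)


class TestRotation:
    def _circular(self, rng):
        seq = random_dna(rng, 300)
        return AnnotatedGenome("c", seq, "circular_permuted",
                               [Feature("CDS", 100, 150, "+", "g")])

    def test_identity_rotation(self, rng):
        g = self._circular(rng)
        r = rotate_origin(g, 1)
        assert r.sequence == g.sequence
        assert r.features[0].start == 100

    def test_inverse_property(self, rng):
        g = self._circular(rng)
        k = 37
        back = rotate_origin(rotate_origin(g, k), len(g) - k + 2)
        assert back.sequence == g.sequence
        assert back.features[0].start == g.features[0].start

    def test_gc_conserved(self, rng):
        g = self._circular(rng)
        assert genome_summary(rotate_origin(g, 211)).gc_percent == \
               genome_summary(g).gc_percent

    def test_linear_genome_refuses(self):
        g = AnnotatedGenome("l", "ACGT" * 10)
        with pytest.raises(ValueError):
            rotate_origin(g, 5)

    def test_feature_spanning_cut_refuses(self, rng):
        g = self._circular(rng)
        with pytest.raises(ValueError, match="spans"):
            rotate_origin(g, 120)


class TestTerminalRedundancy:
    def test_study_arithmetic(self):
        assert estimate_terminal_redundancy(165, 158) == 3.5

    def test_no_gap(self):
        assert estimate_terminal_redundancy(100, 100) == 0.0

    def test_experimental_below_assembled_fails(self):
        with pytest.raises(ValueError):
            estimate_terminal_redundancy(150, 158)


def test_gff3_export_uses_one_based_coordinates(tmp_path, two_cds_genome):
    out = tmp_path / "f.gff3"
    genome_io.write_gff3(two_cds_genome, out)
    lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
    cols = lines[0].split("\t")
    assert cols[2] == "CDS" and cols[3] == "1" and cols[4] == "18"
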