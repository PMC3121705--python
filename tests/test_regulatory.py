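import math

import pytest

from phagecharm.model import AnnotatedGenome, Feature, revcomp
from phagecharm.regulatory import (
    IUPAC,
    DegeneratePattern,
    assign_upstream,
    build_consensus,
    dedupe_palindromic,
    find_terminators,
    hairpin_delta_g,
    scan_bipartite,
    scan_degenerate,
    scan_fixed_motif,
    validate_terminator,
)

from conftest import random_dna


# ---------------------------------------------------------------------------
# Brute-force oracles (character-by-character, independent of the scanners)
# ---------------------------------------------------------------------------

def oracle_scan(sequence, pattern, max_mismatch):
    """Naive both-strand IUPAC scan returning {(position, strand, mismatches)}."""
    hits = set()
    w, L = len(pattern), len(sequence)
    for strand in "+-":
        seq = sequence if strand == "+" else revcomp(sequence)
        for i in range(L - w + 1):
            mm = sum(seq[i + j] not in IUPAC[pattern[j]] for j in range(w))
            if mm <= max_mismatch:
                pos = i if strand == "+" else L - i - w
                hits.add((pos, strand, mm))
    return hits


def oracle_bipartite(sequence, box1, box2, smin, smax, budget):
    """Naive two-box scan; per (anchor, strand) the min-mismatch, shortest-spacer hit."""
    best = {}
    L, w1, w2 = len(sequence), len(box1), len(box2)
    for strand in "+-":
        seq = sequence if strand == "+" else revcomp(sequence)
        for i in range(L - w1 + 1):
            for spacer in range(smin, smax + 1):
                j = i + w1 + spacer
                if j + w2 > L:
                    continue
                mm = sum(a != b for a, b in zip(seq[i : i + w1], box1)) + \
                     sum(a != b for a, b in zip(seq[j : j + w2], box2))
                if mm <= budget:
                    key = (i, strand)
                    if key not in best or mm < best[key][0]:
                        best[key] = (mm, spacer)
    out = set()
    for (i, strand), (mm, spacer) in best.items():
        b35 = i if strand == "+" else L - i - w1
        out.add((b35, strand, mm, spacer))
    return out


class TestFixedMotifScan:
    def test_planted_exact_motif(self, rng):
        bg = random_dna(rng, 500).replace("T", "C")  # motif cannot occur by chance
        seq = bg[:200] + "TATAAATA" + bg[200:]
        hits = [h for h in scan_fixed_motif(seq, "TATAAATA", 0) if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].position == 200 and hits[0].mismatches == 0

    def test_planted_one_mismatch_variant(self, rng):
        bg = random_dna(rng, 400).replace("T", "C").replace("A", "C")
        seq = bg[:100] + "TATAAATG" + bg[100:]
        hits = [h for h in scan_fixed_motif(seq, "TATAAATA", 1) if h.strand == "+"]
        assert len(hits) == 1 and hits[0].mismatches == 1
        assert scan_fixed_motif(seq, "TATAAATA", 0) == []

    def test_matches_oracle_on_random_20kb(self, rng):
        seq = random_dna(rng, 20_000)
        got = {(h.position, h.strand, h.mismatches)
               for h in scan_fixed_motif(seq, "TATAAATA", 1)}
        assert got == oracle_scan(seq, "TATAAATA", 1)

    def test_zero_budget_equals_substring_search(self, rng):
        seq = random_dna(rng, 5_000)
        plus = {h.position for h in scan_fixed_motif(seq, "ACGTAC", 0)
                if h.strand == "+"}
        naive = {i for i in range(len(seq) - 5) if seq[i : i + 6] == "ACGTAC"}
        assert plus == naive

    def test_strand_symmetry(self, rng):
        seq = random_dna(rng, 5_000)
        L = len(seq)
        fwd = {(h.position, h.strand) for h in scan_fixed_motif(seq, "TTGACAA", 1)}
        mirrored = {(L - h.position - 7, "+" if h.strand == "-" else "-")
                    for h in scan_fixed_motif(revcomp(seq), "TTGACAA", 1)}
        assert fwd == mirrored

    def test_iupac_motif_rejected(self):
        with pytest.raises(ValueError):
            scan_fixed_motif("ACGT" * 10, "TANT", 0)

    def test_palindromic_motif_collapse(self):
        seq = "CCCC" + "GAATTC" + "CCCC"
        hits = scan_fixed_motif(seq, "GAATTC", 0)
        assert len(hits) == 2  # one per strand at the same locus
        assert len(dedupe_palindromic(hits)) == 1


class TestBipartiteScan:
    def test_exact_promoter_with_spacer_17(self, rng):
        bg = random_dna(rng, 300).replace("T", "G")
        core = "TTGACA" + "C" * 17 + "TATAAT"
        seq = bg[:150] + core + bg[150:]
        hits = [h for h in scan_bipartite(seq) if h.strand == "+"]
        assert len(hits) == 1
        h = hits[0]
        assert (h.box35, h.spacer_len, h.total_mismatches) == (150, 17, 0)
        assert h.box10 == 150 + 6 + 17

    def test_spacer_14_outside_range(self):
        seq = "C" * 50 + "TTGACA" + "C" * 14 + "TATAAT" + "C" * 50
        assert all(h.box35 != 50 for h in scan_bipartite(seq))

    def test_matches_oracle_on_random_50kb(self, rng):
        seq = random_dna(rng, 50_000)
        got = {(h.box35, h.strand, h.total_mismatches, h.spacer_len)
               for h in scan_bipartite(seq, max_mismatch_total=2)}
        assert got == oracle_bipartite(seq, "TTGACA", "TATAAT", 15, 18, 2)


class TestConsensus:
    def test_identical_sites_reproduce_the_site(self):
        pat = build_consensus(["TTGACA"] * 10)
        assert pat.iupac_string == "TTGACA"

    def test_half_half_column_uses_two_base_code(self):
        sites = ["A" * 4] * 5 + ["T" + "A" * 3] * 5
        pat = build_consensus(sites, threshold=0.8)
        assert pat.iupac_string[0] == "W"

    def test_half_half_without_pair_rule_gives_n(self):
        sites = ["A" * 4] * 5 + ["T" + "A" * 3] * 5
        pat = build_consensus(sites, threshold=0.8, pair_min_each=0.51)
        assert pat.iupac_string[0] == "N"

    def test_four_way_tie_gives_n(self):
        pat = build_consensus(["AA", "CA", "GA", "TA"])
        assert pat.iupac_string == "NA"

    def test_unequal_lengths_fail(self):
        with pytest.raises(ValueError):
            build_consensus(["AAA", "AAAA"])


class TestDegenerateScan:
    def test_n_matches_anything(self):
        hits = [h for h in scan_degenerate("CCTATCC", "TNT", 0) if h.strand == "+"]
        assert len(hits) == 1 and hits[0].position == 2 and hits[0].mismatches == 0

    def test_mismatch_counted_at_constrained_columns(self):
        hits = [h for h in scan_degenerate("GATCCCC", "TNT", 1) if h.strand == "+"]
        assert any(h.position == 0 and h.mismatches == 1 for h in hits)

    def test_invalid_code_fails(self):
        with pytest.raises(ValueError):
            scan_degenerate("ACGT" * 5, "TZT", 0)

    def test_consensus_pattern_matches_oracle_on_random_50kb(self, rng):
        pattern = "TNT" + "NNN" + "A" + "N" * 10 + "C" + "NN" + "ATNAATA"
        seq = random_dna(rng, 50_000)
        got = {(h.position, h.strand, h.mismatches)
               for h in scan_degenerate(seq, pattern, 1)}
        assert got == oracle_scan(seq, pattern, 1)


class TestHairpinDeltaG:
    # expected values are hand sums over the bundled stack table:
    #   GCGCGC stem: GC+CG+GC+CG+GC = -(2.24+2.17+2.24+2.17+2.24) = -11.06; loop4 +3.5
    #   GGGG/CCCC stem: 3 x GG = -5.52; loop3 +3.5
    #   ATAT stem: AT+TA+AT = -(0.88+0.58+0.88) = -2.34; loop4 +3.5
    @pytest.mark.parametrize("stem5,loop,stem3,expected", [
        ("GCGCGC", "TTTT", "GCGCGC", -7.56),
        ("GGGG", "AAA", "CCCC", -2.02),
        ("ATAT", "TTTT", "ATAT", 1.16),
    ])
    def test_hand_summed_toy_hairpins(self, stem5, loop, stem3, expected):
        assert hairpin_delta_g(stem5, loop, stem3) == pytest.approx(expected)

    def test_zero_stem_is_never_stabilizing(self):
        assert hairpin_delta_g("", "TTTT", "") >= 0

    def test_adding_gc_stack_strictly_stabilizes(self):
        base = hairpin_delta_g("GCGC", "TTTT", "GCGC")
        extended = hairpin_delta_g("GGCGC", "TTTT", "GCGCC")
        assert extended < base

    def test_short_loop_fails(self):
        with pytest.raises(ValueError):
            hairpin_delta_g("GC", "TT", "GC")

    def test_mismatch_penalized_not_stacked(self):
        perfect = hairpin_delta_g("GCGCGC", "TTTT", "GCGCGC")
        # central pair broken: position 2 of stem3's partner mismatched
        broken = hairpin_delta_g("GCGCGC", "TTTT", "GCGAGC")
        assert broken > perfect


def _intergenic_test_genome(insert, rng, with_cds=True):
    bg = random_dna(rng, 2_000).replace("T", "C")  # background without T runs
    seq = bg[:500] + "ATG" + "GCA" * 40 + "TAA" + bg[500:1000] + insert + \
        bg[1000:1500] + "ATG" + "GCC" * 40 + "TAA" + bg[1500:]
    feats = []
    if with_cds:
        g1_start = 500
        g1_end = g1_start + 3 + 120 + 3
        g2_start = 500 + 126 + 500 + len(insert) + 500
        feats = [Feature("CDS", g1_start, g1_end, "+", "g1"),
                 Feature("CDS", g2_start, g2_start + 126, "+", "g2")]
    return AnnotatedGenome("t", seq, "linear", feats)


class TestTerminators:
    STRONG = "GCCGCGGCCG" + "TCTA" + revcomp("GCCGCGGCCG")

    def test_planted_strong_terminator_reported(self, rng):
        genome = _intergenic_test_genome(self.STRONG + "TTTTTTTT" + "A", rng)
        calls = find_terminators(genome)
        assert len(calls) == 1
        c = calls[0]
        assert c.delta_g < -10 and c.intergenic
        assert validate_terminator(genome, c)

    def test_same_hairpin_without_polyt_not_reported(self, rng):
        genome = _intergenic_test_genome(self.STRONG + "ACACACAC", rng)
        assert find_terminators(genome) == []

    def test_weak_hairpin_above_threshold_not_reported(self, rng):
        # GCGCG stem: GC+CG+GC+CG = -8.82, loop 4 -> dG = -5.32 > -10
        weak = "GCGCG" + "TCTA" + revcomp("GCGCG")
        genome = _intergenic_test_genome(weak + "TTTTTTTT" + "A", rng)
        assert find_terminators(genome, dg_max=-10.0) == []
        assert len(find_terminators(genome, dg_max=-5.0)) == 1

    def test_genic_terminator_suppressed_by_intergenic_rule(self, rng):
        insert = self.STRONG + "TTTTTTTT" + "A"
        genome = _intergenic_test_genome(insert, rng)
        # wrap the terminator inside a covering CDS interval
        pos = genome.sequence.find(self.STRONG)
        covered = AnnotatedGenome("t", genome.sequence, "linear", [
            Feature("CDS", pos - 30, pos + len(insert) + 30, "+", "big")])
        assert find_terminators(covered, require_intergenic=True) == []
        assert len(find_terminators(covered, require_intergenic=False)) == 1

    def test_minus_strand_terminator_found(self, rng):
        insert = revcomp(self.STRONG + "TTTTTTTT" + "A")
        genome = _intergenic_test_genome(insert, rng)
        calls = find_terminators(genome)
        assert len(calls) == 1 and calls[0].strand == "-"
        assert validate_terminator(genome, calls[0])

    def test_every_call_passes_independent_validator(self):
        from phagecharm.synthetic_data import GenomeSpec, generate_genome
        genome, _ = generate_genome(
            GenomeSpec(length=30_000, n_genes=10, n_promoters=0,
                       n_terminators=8), seed=21)
        calls = find_terminators(genome)
        assert calls and all(validate_terminator(genome, c) for c in calls)


class TestExpectedHitCounts:
    def test_random_sequence_hit_count_matches_binomial(self, rng):
        """Aggregate hit count over 20 random replicates vs the closed form
        sum_{k<=m} C(w,k) 3^k (1/4)^w * 2(L - w + 1)."""
        motif, budget, L, reps = "TATAAATA", 1, 20_000, 20
        w = len(motif)
        p = sum(math.comb(w, k) * 3**k for k in range(budget + 1)) / 4**w
        expected_total = reps * p * 2 * (L - w + 1)
        total = 0
        for _ in range(reps):
            seq = random_dna(rng, L)
            total += len(scan_fixed_motif(seq, motif, budget))
        sigma = math.sqrt(expected_total)
        assert abs(total - expected_total) <= 3 * sigma


class TestAssignUpstream:
    def _genome(self):
        seq = "C" * 300 + "ATG" + "GCA" * 40 + "TAA" + "C" * 300
        return AnnotatedGenome("t", seq, "linear",
                               [Feature("CDS", 300, 426, "+", "orf001")])

    def test_hit_50bp_upstream_assigned(self):
        g = self._genome()
        hit = scan_fixed_motif(g.sequence[:260] + "TATAAATA" + g.sequence[268:],
                               "TATAAATA", 0)
        plus = [h for h in hit if h.strand == "+"]
        (res,) = [r for r in assign_upstream(plus, g, max_distance=150)]
        assert res[1] == "orf001" and not res[2]

    def test_hit_beyond_limit_unassigned(self):
        g = self._genome()
        seq = "TATAAATA" + g.sequence[8:]
        hits = [h for h in scan_fixed_motif(seq, "TATAAATA", 0)
                if h.strand == "+" and h.position == 0]
        (res,) = assign_upstream(hits, g, max_distance=150)
        assert res[1] is None

    def test_hit_inside_cds_flagged(self):
        g = self._genome()
        seq = g.sequence[:330] + "TATAAATA" + g.sequence[338:]
        g2 = AnnotatedGenome("t", seq, "linear", g.features)
        hits = [h for h in scan_fixed_motif(seq, "TATAAATA", 0)
                if h.strand == "+" and h.position == 330]
        (res,) = assign_upstream(hits, g2, max_distance=1000)
        assert res[2] is True
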