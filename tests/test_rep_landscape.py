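import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pangrep.genome_io import CdsFeature, GenomeRecord, reverse_complement
from pangrep.rep_landscape import (
    RepFamily,
    RepOccurrence,
    annotate_genic_context,
    build_consensus,
    detect_palindrome_arms,
    filter_primary_families,
    find_rep_deserts,
    find_rep_pairs,
    mine_repeat_families,
    rayt_rep_flanking,
    scan_consensus,
)

MOTIF = "GTAGGAGCGAGTTCAACTGGCAATCTCGCTCCTAC"  # 35 nt


def bg(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def plant(rng, n_copies, motif=MOTIF, gap=300, mutations=0, strands=None):
    """Genome with copies at known positions separated by random background."""
    parts, positions, pos = [], [], 0
    for i in range(n_copies):
        spacer = bg(rng, gap)
        parts.append(spacer)
        pos += len(spacer)
        copy = list(motif)
        for p in rng.choice(len(copy), size=mutations, replace=False):
            copy[p] = rng.choice([b for b in "ACGT" if b != copy[p]])
        strand = strands[i] if strands else ("+" if rng.random() < 0.5 else "-")
        seq = "".join(copy)
        parts.append(seq if strand == "+" else reverse_complement(seq))
        positions.append((pos, pos + len(motif), strand))
        pos += len(motif)
    parts.append(bg(rng, gap))
    return GenomeRecord(strain_id="g", sequence="".join(parts)), positions


def family_for(consensus):
    L = len(consensus)
    return RepFamily("rep1", consensus, np.full((L, 4), 0.25))


class TestMining:
    def test_exact_planted_copies_recovered(self, rng):
        genome, _ = plant(rng, 20, mutations=0)
        fams = mine_repeat_families(genome)
        assert len(fams) == 1
        assert fams[0].consensus in (MOTIF, reverse_complement(MOTIF))

    def test_below_copy_threshold_no_family(self, rng):
        genome, _ = plant(rng, 9, mutations=0)
        assert mine_repeat_families(genome) == []

    def test_random_genome_no_family(self, rng):
        genome = GenomeRecord(strain_id="g", sequence=bg(rng, 100_000))
        # brute-force check: no exact >=30-mer occurs twice in this instance
        seen, repeated = set(), 0
        s = genome.sequence
        for i in range(len(s) - 30 + 1):
            k = s[i : i + 30]
            if k in seen:
                repeated += 1
            seen.add(k)
        assert repeated == 0
        assert mine_repeat_families(genome) == []

    def test_genome_too_short(self):
        with pytest.raises(ValueError):
            mine_repeat_families(GenomeRecord(strain_id="g", sequence="ACGT"))


class TestConsensus:
    def test_identical_strings(self):
        cons, freqs = build_consensus(["AATT"] * 3)
        assert cons == "AATT"
        assert freqs[0].tolist() == [1.0, 0, 0, 0]

    def test_majority_by_hand(self):
        cons, _ = build_consensus(["AAT", "AAT", "ACT"])
        assert cons == "AAT"

    def test_tie_breaks_alphabetically(self):
        cons, _ = build_consensus(["A", "A", "C", "C"])
        assert cons == "A"

    def test_zero_occurrences(self):
        with pytest.raises(ValueError, match="zero"):
            build_consensus([])


class TestScan:
    def test_identity_cutoff_three_vs_four_mismatches(self, rng):
        # 3 mismatches in 35 nt = 91.4% (reported); 4 = 88.6% (not reported)
        g3, pos3 = plant(rng, 1, mutations=3, strands=["+"])
        assert [(o.start, o.end) for o in scan_consensus(g3, family_for(MOTIF))] == [
            (pos3[0][0], pos3[0][1])
        ]
        g4, _ = plant(rng, 1, mutations=4, strands=["+"])
        assert scan_consensus(g4, family_for(MOTIF)) == []

    def test_strand_symmetry(self, rng):
        genome, positions = plant(rng, 12, mutations=1)
        occs = scan_consensus(genome, family_for(MOTIF))
        mirror = GenomeRecord(strain_id="g", sequence=reverse_complement(genome.sequence))
        mocc = scan_consensus(mirror, family_for(MOTIF))
        L = genome.length
        mirrored = sorted((L - o.end, L - o.start, "-" if o.strand == "+" else "+") for o in mocc)
        assert sorted((o.start, o.end, o.strand) for o in occs) == mirrored

    def test_exact_scan_returns_planted_set(self, rng):
        genome, positions = plant(rng, 15, mutations=0)
        occs = scan_consensus(genome, family_for(MOTIF), min_identity=1.0)
        assert sorted((o.start, o.end, o.strand) for o in occs) == sorted(positions)


class TestGenicContextAndPrimary:
    def make(self, start, end):
        return RepOccurrence("g", start, end, "+", 1.0)

    def test_overlap_rules(self):
        features = [CdsFeature("c1", 100, 200, "+")]
        occs = annotate_genic_context(
            [self.make(120, 155), self.make(300, 335), self.make(66, 101)], features
        )
        assert [o.intergenic for o in occs] == [False, True, False]  # 1-bp overlap counts

    @pytest.mark.parametrize("count,expect", [(300, True), (249, False)])
    def test_primary_threshold(self, count, expect):
        fam = family_for(MOTIF)
        occs = [
            RepOccurrence("g", i * 100, i * 100 + 35, "+", 1.0, intergenic=True)
            for i in range(count)
        ]
        primary = filter_primary_families([fam], {"rep1": occs})
        assert (fam in primary) is expect

    def test_empty_families(self):
        assert filter_primary_families([], {}) == []


class TestPalindromeArms:
    def test_hand_checkable_arms(self):
        arms = detect_palindrome_arms("GGATC" + "AAA" + "GATCC", min_arm=5)
        assert arms is not None
        assert (arms.left_arm, arms.right_arm, arms.mismatches) == ("GGATC", "GATCC", 0)

    def test_homopolymer_has_no_arms(self):
        assert detect_palindrome_arms("A" * 20, max_mismatch=0) is None

    def test_perfect_palindrome_full_arm(self):
        s = "GGATCC"  # GGA | TCC, TCC == revcomp(GGA)
        arms = detect_palindrome_arms(s, min_arm=3, max_mismatch=0)
        assert arms.arm_length == 3

    def test_default_consensus_arms_detected(self):
        arms = detect_palindrome_arms(MOTIF)
        assert arms is not None
        assert arms.arm_length >= 11
        assert arms.mismatches <= 2


class TestPairs:
    def occ(self, center, strand):
        return RepOccurrence("g", int(center - 17), int(center - 17) + 35, strand, 1.0)

    def test_planted_spacing_mode(self):
        occs = []
        for i in range(120):
            base = 1000 + i * 700
            occs += [self.occ(base, "+"), self.occ(base + 65, "-")]
        pairs, hist, mode = find_rep_pairs(occs)
        assert mode == 65
        assert len(pairs) == 120
        assert all(p.opposite_orientation for p in pairs)

    def test_far_apart_not_paired(self):
        pairs, _, mode = find_rep_pairs([self.occ(100, "+"), self.occ(400, "-")])
        assert pairs == [] and mode is None

    def test_exactly_200_excluded(self):
        pairs, _, _ = find_rep_pairs([self.occ(100, "+"), self.occ(300, "-")])
        assert pairs == []

    def test_orientation_flag(self):
        pairs, _, _ = find_rep_pairs([self.occ(100, "+"), self.occ(180, "+")])
        assert pairs[0].opposite_orientation is False


class TestDeserts:
    def brute_force(self, occs, genome_length, min_len=25000):
        # independent per-base occupancy scan: mark covered bases, read off
        # maximal free runs, keep those >= min_len
        occupied = np.zeros(genome_length + 2, dtype=np.int8)
        occupied[0] = occupied[-1] = 1  # sentinels
        for o in occs:
            occupied[o.start + 1 : o.end + 1] = 1
        edges = np.diff(occupied)
        starts = np.nonzero(edges == -1)[0]
        ends = np.nonzero(edges == 1)[0]
        return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]

    def test_worked_example(self):
        occs = [
            RepOccurrence("g", 10_000, 10_035, "+", 1.0),
            RepOccurrence("g", 80_000, 80_035, "+", 1.0),
        ]
        got = [(d.start, d.end) for d in find_rep_deserts(occs, 100_000)]
        assert got == [(10_035, 80_000)]  # end gaps of 10 kb / 20 kb excluded

    def test_dense_occurrences_no_desert(self):
        occs = [RepOccurrence("g", i * 5000, i * 5000 + 35, "+", 1.0) for i in range(20)]
        assert find_rep_deserts(occs, 100_000) == []

    def test_no_occurrences_whole_genome(self):
        got = find_rep_deserts([], 30_000, strain_id="g")
        assert [(d.start, d.end) for d in got] == [(0, 30_000)]
        assert find_rep_deserts([], 20_000, strain_id="g") == []

    @given(st.integers(0, 2**31 - 1))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genome_length = int(rng.integers(30_000, 120_000))
        n = int(rng.integers(0, 8))
        occs = []
        for _ in range(n):
            start = int(rng.integers(0, genome_length - 35))
            occs.append(RepOccurrence("g", start, start + 35, "+", 1.0))
        got = [(d.start, d.end) for d in find_rep_deserts(occs, genome_length, strain_id="g")]
        assert got == self.brute_force(occs, genome_length)

    def test_deserts_disjoint_from_occurrences(self, rng):
        occs = [
            RepOccurrence("g", int(s), int(s) + 35, "+", 1.0)
            for s in sorted(rng.integers(0, 200_000 - 35, size=6))
        ]
        deserts = find_rep_deserts(occs, 200_000)
        for d in deserts:
            for o in occs:
                assert o.end <= d.start or o.start >= d.end
        assert sum(d.length for d in deserts) <= 200_000


class TestRaytFlanking:
    def gene(self, start, end):
        return CdsFeature("rayt1", start, end, "+", product_class="RAYT")

    def occ_at(self, center):
        # even length so the center falls on an integer coordinate
        return RepOccurrence("g", int(center) - 17, int(center) + 17, "+", 1.0)

    def test_flanked_both_sides(self):
        flank = rayt_rep_flanking(
            [self.gene(1000, 2000)], [self.occ_at(880), self.occ_at(2090)]
        )
        ok, up, down = flank["rayt1"]
        assert ok and up == 120 and down == 90

    def test_one_sided_false(self):
        flank = rayt_rep_flanking([self.gene(1000, 2000)], [self.occ_at(880)])
        assert flank["rayt1"][0] is False

    def test_zero_window_requires_abutting(self):
        assert rayt_rep_flanking([self.gene(1000, 2000)], [self.occ_at(990), self.occ_at(2010)], window=0)[
            "rayt1"
        ][0] is False
        assert rayt_rep_flanking(
            [self.gene(1000, 2000)], [self.occ_at(1000), self.occ_at(2000)], window=0
        )["rayt1"][0] is True
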