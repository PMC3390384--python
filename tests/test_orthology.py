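import numpy as np
import pytest

from pangrep.orthology import (
    BestHitMap,
    OrthologyError,
    PresenceAbsenceMatrix,
    SearchParams,
    SimilarityHit,
    best_match,
    build_families,
    family_stats,
    internal_similarity_search,
    karlin_altschul_evalue,
    smith_waterman_score,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n=100):
    return "".join(rng.choice(list(AA), size=n))


def make_hit(q, s, evalue, bitscore, qs="A", ss="B"):
    return SimilarityHit(
        query_id=q, subject_id=s, query_strain=qs, subject_strain=ss,
        identity=0.5, aln_length=100, evalue=evalue, bitscore=bitscore,
    )


class TestInternalSearch:
    def test_identical_sequences_strong_hit(self, rng):
        seq = random_protein(rng, 100)
        hits = internal_similarity_search({"q": seq}, {"s": seq}, query_strain="A", subject_strain="B")
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(1.0)
        assert hits[0].evalue < 1e-5

    def test_random_pair_no_significant_hit(self, rng):
        # exhaustive Smith-Waterman on the pair is the oracle: its score
        # must imply E > 1e-5, and the seeded search must agree
        a, b = random_protein(rng, 100), random_protein(rng, 100)
        oracle_score = smith_waterman_score(a, b)
        assert karlin_altschul_evalue(oracle_score, 100, 100) > 1e-5
        hits = internal_similarity_search(
            {"q": a}, {"s": b}, SearchParams(report_max=1e-5),
            query_strain="A", subject_strain="B",
        )
        assert hits == []

    def test_search_symmetric_up_to_transpose(self, rng):
        prot_a = {f"a{i}": random_protein(rng, 80) for i in range(4)}
        prot_b = {f"b{i}": random_protein(rng, 80) for i in range(4)}
        prot_b["b0"] = prot_a["a0"]  # one orthologous pair
        fwd = internal_similarity_search(prot_a, prot_b, query_strain="A", subject_strain="B")
        rev = internal_similarity_search(prot_b, prot_a, query_strain="B", subject_strain="A")
        fwd_pairs = {(h.query_id, h.subject_id, round(h.bitscore, 6)) for h in fwd}
        rev_pairs = {(h.subject_id, h.query_id, round(h.bitscore, 6)) for h in rev}
        assert fwd_pairs == rev_pairs

    def test_empty_proteome_rejected(self):
        with pytest.raises(OrthologyError):
            internal_similarity_search({}, {"s": "MKL"})


class TestBestMatch:
    def test_e_cutoff_applied(self):
        hits = [make_hit("q", "s1", 1e-4, 50.0), make_hit("q", "s2", 1e-6, 40.0)]
        bm = best_match(hits)  # default cutoff 1e-5
        assert bm.entries == {"q": ("s2", 1e-6, 40.0)}

    def test_tie_broken_by_smaller_subject_id(self):
        hits = [make_hit("q", "sB", 1e-10, 99.0), make_hit("q", "sA", 1e-10, 99.0)]
        assert best_match(hits).best("q") == "sA"

    def test_best_by_bitscore(self):
        hits = [make_hit("q", "s1", 1e-10, 80.0), make_hit("q", "s2", 1e-12, 70.0)]
        assert best_match(hits).best("q") == "s1"

    def test_empty_input(self):
        assert best_match([]).entries == {}

    def test_mixed_pairs_rejected(self):
        hits = [make_hit("q", "s", 1e-9, 50.0, "A", "B"), make_hit("q", "s", 1e-9, 50.0, "A", "C")]
        with pytest.raises(OrthologyError, match="mixed"):
            best_match(hits)


def maps_from_edges(strains, genes, edges):
    """Best-hit maps where each (a_gene, b_gene) edge is mutual-best."""
    maps = {}
    for a in strains:
        for b in strains:
            if a != b:
                maps[(a, b)] = BestHitMap(query_strain=a, subject_strain=b)
    for (sa, ga), (sb, gb) in edges:
        maps[(sa, sb)].entries[ga] = (gb, 1e-20, 100.0)
        maps[(sb, sa)].entries[gb] = (ga, 1e-20, 100.0)
    return list(maps.values())


class TestBuildFamilies:
    def test_three_strain_mutual_family(self):
        strains = ["A", "B", "C"]
        genes = {"A": ["a1"], "B": ["b1"], "C": ["c1"]}
        edges = [(("A", "a1"), ("B", "b1")), (("A", "a1"), ("C", "c1")), (("B", "b1"), ("C", "c1"))]
        mat = build_families(maps_from_edges(strains, genes, edges), genes)
        assert len(mat.families) == 1
        assert mat.occupancy(next(iter(mat.families))) == frozenset(strains)

    def test_gene_without_hits_is_singleton(self):
        strains = ["A", "B"]
        genes = {"A": ["a1", "a2"], "B": ["b1"]}
        edges = [(("A", "a1"), ("B", "b1"))]
        mat = build_families(maps_from_edges(strains, genes, edges), genes)
        assert len(mat.families) == 2
        sizes = sorted(sum(len(v) for v in occ.values()) for occ in mat.families.values())
        assert sizes == [1, 2]

    def test_missing_map_rejected(self):
        with pytest.raises(OrthologyError, match="missing"):
            build_families([], {"A": ["a1"], "B": ["b1"]})

    def test_unidirectional_mode_chains(self):
        # one-way best hit a1->b1 with the reverse map pointing b1->a2
        maps = {}
        for a, b in [("A", "B"), ("B", "A")]:
            maps[(a, b)] = BestHitMap(query_strain=a, subject_strain=b)
        maps[("A", "B")].entries["a1"] = ("b1", 1e-20, 90.0)
        maps[("B", "A")].entries["b1"] = ("a2", 1e-20, 95.0)
        genes = {"A": ["a1", "a2"], "B": ["b1"]}
        uni = build_families(list(maps.values()), genes, mode="unidirectional")
        assert len(uni.families) == 1  # chained into one component
        rec = build_families(list(maps.values()), genes, mode="reciprocal")
        assert len(rec.families) == 3  # no mutual pair -> all singletons

    def test_partition_invariant(self, clean_dataset, clean_matrix):
        for s in clean_matrix.strains:
            assert clean_matrix.gene_count(s) == len(clean_dataset.proteins[s])

    def test_planted_families_recovered_exactly(self, clean_dataset, clean_matrix):
        truth = {frozenset(m) for m in clean_dataset.truth.family_membership.values()}
        recovered = {
            frozenset((s, l) for s, loci in occ.items() for l in loci)
            for occ in clean_matrix.families.values()
        }
        assert recovered == truth


class TestFamilyStats:
    def test_paralog_counts(self):
        mat = PresenceAbsenceMatrix(
            {"f1": {"A": {"a1", "a2"}, "B": {"b1"}}, "f2": {"B": {"b2"}}}, ["A", "B"]
        )
        df = family_stats(mat).set_index("family_id")
        assert df.loc["f1", "paralogs_A"] == 2
        assert df.loc["f1", "n_strains"] == 2
        assert df.loc["f2", "paralogs_A"] == 0

    def test_empty_matrix(self):
        df = family_stats(PresenceAbsenceMatrix({}, ["A"]))
        assert df.empty

    def test_gene_in_two_families_rejected(self):
        with pytest.raises(OrthologyError):
            PresenceAbsenceMatrix({"f1": {"A": {"a1"}}, "f2": {"A": {"a1"}}}, ["A"])
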