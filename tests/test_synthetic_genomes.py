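import json

import numpy as np
import pytest

from pangrep.composition_atypia import trinucleotide_background
from pangrep.genome_io import reverse_complement
from pangrep.synthetic_genomes import (
    DEFAULT_REP_CONSENSUS,
    EffectorSpec,
    GroundTruth,
    SyntheticConfig,
    assemble_genome,
    evolve_protein_families,
    mutation_rate_for_divergence,
    product_trinucleotide_distribution,
    sample_pangenome_truth,
    shifted_trinucleotide_distribution,
    simulate_dataset,
    write_fixtures,
)

SMALL = dict(
    n_strains=3,
    clade_assignment={"a": "c1", "b": "c1", "c": "c2"},
    n_core_families=10,
    n_clade_families={"c1": 2, "c2": 1},
    n_unique=2,
    rep_copies=40,
    rayt_per_strain=0,
    effector_spec=EffectorSpec(n_conforming=0, decoys=(), n_no_motif=0),
    desert_spec=(),
)


class TestTruthSkeleton:
    def test_core_only_counts(self):
        cfg = SyntheticConfig(
            **{**SMALL, "n_clade_families": {}, "n_unique": 0, "n_core_families": 10}
        )
        truth = sample_pangenome_truth(cfg)
        for s in cfg.strains:
            assert len(truth.strain_loci(s)) == 10

    def test_clade_pattern_exact(self):
        cfg = SyntheticConfig(**SMALL)
        truth = sample_pangenome_truth(cfg)
        for fid in truth.families_of_class("clade:c1"):
            assert {s for s, _ in truth.family_membership[fid]} == {"a", "b"}
        assert len(truth.families_of_class("clade:c1")) == 2
        assert len(truth.families_of_class("unique:c")) == 2

    def test_infeasible_clade(self):
        with pytest.raises(ValueError, match="no strains"):
            SyntheticConfig(**{**SMALL, "n_clade_families": {"ghost": 3}})

    def test_deterministic(self):
        cfg = SyntheticConfig(**SMALL, seed=5)
        t1, t2 = sample_pangenome_truth(cfg), sample_pangenome_truth(cfg)
        assert t1.family_membership == t2.family_membership


class TestProteinEvolution:
    def test_zero_divergence_identical(self):
        cfg = SyntheticConfig(**SMALL, divergence=0.0)
        truth = sample_pangenome_truth(cfg)
        prot = evolve_protein_families(truth, cfg)
        for fid, members in truth.family_membership.items():
            seqs = {prot[s][l] for s, l in members}
            assert len(seqs) == 1

    def test_pairwise_identity_matches_divergence(self, rng):
        # closed form: two copies mutated at rate r differ at 2r(1-r)+r^2*18/19
        # of sites; r is solved so this equals d, hence identity = 1 - 18d/19
        d = 0.3
        r = mutation_rate_for_divergence(d)
        expected = 1.0 - (18.0 / 19.0) * d
        cfg = SyntheticConfig(
            **{**SMALL, "n_core_families": 120},
            divergence=d,
            protein_length_range=(200, 200),
            seed=3,
        )
        truth = sample_pangenome_truth(cfg)
        prot = evolve_protein_families(truth, cfg)
        idents = []
        for fid in truth.families_of_class("core"):
            (s1, l1), (s2, l2) = sorted(truth.family_membership[fid])[:2]
            a, b = prot[s1][l1], prot[s2][l2]
            idents.append(np.mean([x == y for x, y in zip(a, b)]))
        se = np.std(idents) / np.sqrt(len(idents))
        assert np.mean(idents) == pytest.approx(expected, abs=4 * se + 0.005)
        assert 0 < r < d

    def test_distinct_families_near_random_identity(self):
        cfg = SyntheticConfig(**SMALL, divergence=0.0, protein_length_range=(200, 200), seed=4)
        truth = sample_pangenome_truth(cfg)
        prot = evolve_protein_families(truth, cfg)
        fams = truth.families_of_class("core")[:6]
        seqs = [prot[s][l] for f in fams for s, l in sorted(truth.family_membership[f])[:1]]
        idents = [
            np.mean([x == y for x, y in zip(seqs[i], seqs[j])])
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        ]
        assert np.mean(idents) == pytest.approx(1 / 20, abs=0.03)

    def test_identity_monotone_in_divergence(self):
        means = []
        for d in (0.05, 0.2, 0.4):
            cfg = SyntheticConfig(**SMALL, divergence=d, protein_length_range=(150, 150), seed=6)
            truth = sample_pangenome_truth(cfg)
            prot = evolve_protein_families(truth, cfg)
            vals = []
            for fid in truth.families_of_class("core"):
                (s1, l1), (s2, l2) = sorted(truth.family_membership[fid])[:2]
                vals.append(np.mean([x == y for x, y in zip(prot[s1][l1], prot[s2][l2])]))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestAssembly:
    def test_gene_count_conservation(self, default_dataset):
        ds = default_dataset
        for s, genome in ds.genomes.items():
            assert len(genome.features) == len(ds.truth.strain_loci(s))
            assert set(f.locus_tag for f in genome.features) == set(ds.truth.strain_loci(s))

    def test_desert_blocks_planted(self, default_dataset):
        ds = default_dataset
        spec_lengths = sorted(d.length for d in ds.config.desert_spec)
        for s in ds.genomes:
            atyp = [iv for iv in ds.truth.planted_atypical if iv.strain_id == s]
            assert sorted(iv.length for iv in atyp) == spec_lengths

    def test_deserts_contain_no_rep(self, default_dataset):
        ds = default_dataset
        for iv in ds.truth.planted_deserts:
            for start, end, _, _ in ds.truth.rep_occurrences[iv.strain_id]:
                assert end <= iv.start or start >= iv.end

    def test_saturated_background_gaps_below_desert_limit(self, default_dataset):
        # outside planted deserts, consecutive REP gaps stay < 25 kb
        ds = default_dataset
        for s, genome in ds.genomes.items():
            occs = sorted(ds.truth.rep_occurrences[s])
            deserts = [iv for iv in ds.truth.planted_deserts if iv.strain_id == s]
            bounds = [0] + [e for _, e, _, _ in occs] + [genome.length]
            starts = [s0 for s0, _, _, _ in occs]
            gaps = zip([0] + [o[1] for o in occs], starts + [genome.length])
            for gs, ge in gaps:
                if ge - gs >= 25000:
                    assert any(d.start <= gs and ge <= d.end for d in deserts)

    def test_pairs_at_configured_spacing(self, default_dataset):
        ds = default_dataset
        for s in ds.genomes:
            for s1, s2, dist in ds.truth.planted_pairs[s]:
                assert dist == ds.config.pair_spacing_bp

    def test_planted_copies_within_scan_identity(self, default_dataset):
        ds = default_dataset
        for s in ds.genomes:
            for _, _, _, ident in ds.truth.rep_occurrences[s]:
                assert ident >= 0.90

    def test_seeded_rerun_byte_identical(self):
        cfg = SyntheticConfig(**SMALL, seed=9)
        g1 = simulate_dataset(cfg).genomes["a"].sequence
        g2 = simulate_dataset(cfg).genomes["a"].sequence
        assert g1 == g2

    def test_rep_consensus_palindrome_not_self_similar(self):
        # the default consensus must not match its own reverse complement at
        # the scan threshold, or strand assignment becomes ambiguous
        rc = reverse_complement(DEFAULT_REP_CONSENSUS)
        ident = np.mean([a == b for a, b in zip(DEFAULT_REP_CONSENSUS, rc)])
        assert ident < 0.85


class TestShiftedDistribution:
    def test_exact_tv_distance(self):
        p = product_trinucleotide_distribution((0.2, 0.3, 0.3, 0.2))
        for tv in (0.0, 0.1, 0.35):
            q = shifted_trinucleotide_distribution(p, tv)
            assert 0.5 * np.abs(p - q).sum() == pytest.approx(tv, abs=1e-9)
            assert q.sum() == pytest.approx(1.0)
            assert (q >= 0).all()

    def test_unattainable_shift_rejected(self):
        p = product_trinucleotide_distribution((0.25, 0.25, 0.25, 0.25))
        with pytest.raises(ValueError):
            shifted_trinucleotide_distribution(p, 0.99)


class TestFixtures:
    def test_file_set_and_truth_roundtrip(self, tmp_path):
        cfg = SyntheticConfig(**SMALL, seed=2)
        ds = simulate_dataset(cfg)
        manifest = write_fixtures(ds, tmp_path / "fix")
        names = set(manifest["files"])
        for s in cfg.strains:
            assert {f"{s}.fna", f"{s}.gff", f"{s}.faa"} <= names
        truth2 = GroundTruth.from_json((tmp_path / "fix" / "truth.json").read_text())
        assert truth2.family_membership == ds.truth.family_membership
        assert truth2.rep_occurrences == ds.truth.rep_occurrences

    def test_rerun_same_manifest(self, tmp_path):
        cfg = SyntheticConfig(**SMALL, seed=2)
        m1 = write_fixtures(simulate_dataset(cfg), tmp_path / "f1")
        m2 = write_fixtures(simulate_dataset(cfg), tmp_path / "f2")
        assert m1["files"] == m2["files"]
        assert m1["config_hash"] == m2["config_hash"]

    def test_refuses_nonempty_dir(self, tmp_path):
        d = tmp_path / "fix"
        d.mkdir()
        (d / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_fixtures(simulate_dataset(SyntheticConfig(**SMALL)), d)
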