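"""Synthetic multi-strain genomes with planted, machine-readable ground truth.

The generator emulates the structures the downstream analyses look for, so
every stage of the pipeline is testable without real assemblies:

* a pan-genome of core, clade-core and strain-unique protein families under
  a controlled i.i.d. amino-acid substitution model (no indels), so the
  expected within-family identity has a closed form: 1 - (18/19) * d for a
  between-strain divergence d;
* intergenic REP elements planted as mutated copies of a 35-nt imperfect
  palindrome, a configured fraction as oppositely oriented pairs at a fixed
  center-to-center spacing (REPIN doublets);
* REP-free desert blocks (>= 25 kb) whose sequence follows a trinucleotide
  distribution shifted from the background by a configurable total-variation
  distance (they double as atypical-composition islands);
* RAYT-like genes flanked by a REP copy within 300 bp on both sides;
* effector-like genes with a promoter motif planted at a fixed upstream
  offset and N-termini constructed to pass all, or violate exactly one, of
  the published composition rules.

Genes are reverse-translated with a fixed codon per amino acid by default,
keeping the nucleotide background composition controlled; genomes are
linear and gene-dense with short intergenic gaps, so the non-desert
inter-REP distances stay far below the desert threshold (saturated
background: desert recovery is exact by construction).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_io import (
    CdsFeature,
    GenomeRecord,
    GenomicInterval,
    reverse_complement,
    write_fasta,
    write_gff3,
)

__all__ = [
    "DesertSpec",
    "EffectorSpec",
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "DEFAULT_REP_CONSENSUS",
    "sample_pangenome_truth",
    "evolve_protein_families",
    "assemble_genome",
    "simulate_dataset",
    "write_fixtures",
    "mutation_rate_for_divergence",
    "shifted_trinucleotide_distribution",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: One fixed codon per amino acid (controlled nucleotide background).
FIXED_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTT", "W": "TGG", "Y": "TAT",
}

#: 35-nt imperfect palindrome: 11-nt arms (right = revcomp(left)) around an
#: asymmetric 13-nt core, so the full-length reverse complement is only ~74%
#: identical to the consensus and plus/minus scans cannot double-report.
DEFAULT_REP_CONSENSUS = "GTAGGAGCGAG" + "TTCAACTGGCAAT" + "CTCGCTCCTAC"

STOP_CODON = "TAA"


@dataclass(frozen=True)
class DesertSpec:
    """One REP-free block: length (bp) and trinucleotide total-variation
    shift of its sequence relative to the background."""

    length: int = 30000
    composition_shift: float = 0.35


@dataclass(frozen=True)
class EffectorSpec:
    """Planted effector-like genes per strain.

    ``n_conforming`` genes pass all four N-terminal rules and carry the
    promoter motif; one decoy per entry of ``decoys`` violates exactly that
    rule (motif still planted); ``n_no_motif`` genes conform but lack the
    motif. ``upstream_offset`` is the distance from the CDS start to the
    motif start, in gene orientation.
    """

    n_conforming: int = 2
    decoys: tuple[str, ...] = ("acidic", "aliphatic", "ser", "polar")
    n_no_motif: int = 1
    motif: str = "GGAACCGCTC"
    upstream_offset: int = 120


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_strains: int = 4
    clade_assignment: dict[str, str] = field(
        default_factory=lambda: {"s1": "c1", "s2": "c1", "s3": "c2", "s4": "c2"}
    )
    n_core_families: int = 120
    n_clade_families: dict[str, int] = field(default_factory=lambda: {"c1": 15, "c2": 15})
    n_unique: int = 25
    protein_length_range: tuple[int, int] = (100, 200)
    divergence: float = 0.1
    rep_consensus: str = DEFAULT_REP_CONSENSUS
    rep_copies: int = 300
    rep_pair_fraction: float = 0.6
    pair_spacing_bp: int = 65
    rep_max_mutations: int = 2
    desert_spec: tuple[DesertSpec, ...] = (DesertSpec(),)
    rayt_per_strain: int = 1
    effector_spec: EffectorSpec = field(default_factory=EffectorSpec)
    intergenic_gap_range: tuple[int, int] = (250, 450)
    base_probs: tuple[float, float, float, float] = (0.20, 0.30, 0.30, 0.20)  # A,C,G,T
    codon_mode: str = "fixed"  # or "uniform" synonymous choice
    seed: int = 0

    def __post_init__(self) -> None:
        strains = sorted(self.clade_assignment)
        if len(strains) != self.n_strains:
            raise ValueError(
                f"clade_assignment covers {len(strains)} strains, n_strains={self.n_strains}"
            )
        for clade in self.n_clade_families:
            if clade not in set(self.clade_assignment.values()):
                raise ValueError(f"clade {clade!r} has no strains")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must lie in [0, 1)")
        if min(self.n_core_families, self.n_unique, self.rep_copies, self.rayt_per_strain) < 0:
            raise ValueError("counts must be >= 0")
        if len(self.rep_consensus) < 30:
            raise ValueError("rep consensus must be >= 30 nt")
        if not 0 <= self.rep_pair_fraction <= 1:
            raise ValueError("rep_pair_fraction must lie in [0, 1]")
        if not len(self.rep_consensus) < self.pair_spacing_bp < 200:
            raise ValueError("pair_spacing_bp must exceed the REP length and stay below 200")
        if self.rep_max_mutations > int(0.10 * len(self.rep_consensus)):
            raise ValueError("rep_max_mutations must keep planted copies within 90% identity")
        for d in self.desert_spec:
            if d.length < 25000:
                raise ValueError("desert blocks must be >= 25 kb")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        if self.codon_mode not in ("fixed", "uniform"):
            raise ValueError("codon_mode must be 'fixed' or 'uniform'")

    @property
    def strains(self) -> list[str]:
        return sorted(self.clade_assignment)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PlantedEffector:
    strain_id: str
    locus_tag: str
    conforming: bool
    violated_rule: str | None
    has_motif: bool
    motif_offset: int | None


@dataclass
class GroundTruth:
    """All planted structures, the recovery oracle for every stage."""

    family_membership: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    family_class: dict[str, str] = field(default_factory=dict)
    rep_occurrences: dict[str, list[tuple[int, int, str, float]]] = field(default_factory=dict)
    planted_pairs: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    planted_deserts: list[GenomicInterval] = field(default_factory=list)
    planted_atypical: list[GenomicInterval] = field(default_factory=list)
    planted_rayts: list[tuple[str, str]] = field(default_factory=list)
    planted_effectors: list[PlantedEffector] = field(default_factory=list)

    def strain_loci(self, strain: str) -> list[str]:
        loci = [
            locus
            for members in self.family_membership.values()
            for s, locus in members
            if s == strain
        ]
        return sorted(loci)

    def families_of_class(self, cls: str) -> list[str]:
        return sorted(f for f, c in self.family_class.items() if c == cls)

    def to_json(self) -> str:
        payload = {
            "family_membership": {
                f: sorted(map(list, members)) for f, members in self.family_membership.items()
            },
            "family_class": self.family_class,
            "rep_occurrences": self.rep_occurrences,
            "planted_pairs": self.planted_pairs,
            "planted_deserts": [
                [iv.strain_id, iv.start, iv.end] for iv in self.planted_deserts
            ],
            "planted_atypical": [
                [iv.strain_id, iv.start, iv.end] for iv in self.planted_atypical
            ],
            "planted_rayts": [list(t) for t in self.planted_rayts],
            "planted_effectors": [asdict(e) for e in self.planted_effectors],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        gt = cls()
        gt.family_membership = {
            f: {tuple(m) for m in members} for f, members in raw["family_membership"].items()
        }
        gt.family_class = raw["family_class"]
        gt.rep_occurrences = {
            s: [tuple(o) for o in occs] for s, occs in raw["rep_occurrences"].items()
        }
        gt.planted_pairs = {s: [tuple(p) for p in ps] for s, ps in raw["planted_pairs"].items()}
        gt.planted_deserts = [
            GenomicInterval(s, a, b, kind="rep_desert") for s, a, b in raw["planted_deserts"]
        ]
        gt.planted_atypical = [
            GenomicInterval(s, a, b, kind="atypical") for s, a, b in raw["planted_atypical"]
        ]
        gt.planted_rayts = [tuple(t) for t in raw["planted_rayts"]]
        gt.planted_effectors = [PlantedEffector(**e) for e in raw["planted_effectors"]]
        return gt


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: GroundTruth
    genomes: dict[str, GenomeRecord]
    proteins: dict[str, dict[str, str]]


# ---------------------------------------------------------------------------
# pan-genome truth + protein evolution


def sample_pangenome_truth(config: SyntheticConfig) -> GroundTruth:
    """Assign families to classes and strains (deterministic under the seed)."""
    truth = GroundTruth()
    strains = config.strains
    counter = {s: 0 for s in strains}

    def new_locus(strain: str) -> str:
        counter[strain] += 1
        return f"{strain}_{counter[strain]:04d}"

    fam_no = 0

    def add_family(cls: str, members: Sequence[str]) -> None:
        nonlocal fam_no
        fam_no += 1
        fid = f"tfam{fam_no:04d}"
        truth.family_class[fid] = cls
        truth.family_membership[fid] = {(s, new_locus(s)) for s in members}

    for _ in range(config.n_core_families):
        add_family("core", strains)
    for clade, n in sorted(config.n_clade_families.items()):
        clade_strains = [s for s in strains if config.clade_assignment[s] == clade]
        for _ in range(n):
            add_family(f"clade:{clade}", clade_strains)
    for s in strains:
        for _ in range(config.n_unique):
            add_family(f"unique:{s}", [s])
    return truth


def mutation_rate_for_divergence(d: float) -> float:
    """Per-copy, per-site substitution rate r such that two independently
    mutated copies differ at an expected fraction d of sites.

    Matches differ with probability 2r(1-r) + r^2 * 18/19 under uniform
    replacement over the 19 alternative residues; solving for r gives
    r = (19/20) (1 - sqrt(1 - (360/361) d)).
    """
    if not 0 <= d < 1:
        raise ValueError("divergence must lie in [0, 1)")
    return (19.0 / 20.0) * (1.0 - float(np.sqrt(1.0 - (360.0 / 361.0) * d)))


def _mutate_protein(ancestor: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return ancestor
    seq = np.array(list(ancestor))
    hit = rng.random(len(seq)) < rate
    for i in np.nonzero(hit)[0]:
        alternatives = [a for a in AMINO_ACIDS if a != seq[i]]
        seq[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def _random_protein(length: int, rng: np.random.Generator, start_met: bool = True) -> str:
    body = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ("M" + body[1:]) if start_met else body


def evolve_protein_families(
    truth: GroundTruth, config: SyntheticConfig, rng: np.random.Generator | None = None
) -> dict[str, dict[str, str]]:
    """One uniform-random ancestor per family; every strain copy mutated
    i.i.d. per site so between-strain divergence equals ``config.divergence``.
    Distinct families share no ancestry."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    rate = mutation_rate_for_divergence(config.divergence)
    lo, hi = config.protein_length_range
    proteins: dict[str, dict[str, str]] = {s: {} for s in config.strains}
    for fid in sorted(truth.family_membership):
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_protein(length, rng, start_met=False)
        for strain, locus in sorted(truth.family_membership[fid]):
            proteins[strain][locus] = _mutate_protein(ancestor, rate, rng)
    return proteins


# ---------------------------------------------------------------------------
# nucleotide-level helpers


def _background(rng: np.random.Generator, length: int, base_probs) -> str:
    if length <= 0:
        return ""
    return "".join(rng.choice(list("ACGT"), size=length, p=list(base_probs)))


def product_trinucleotide_distribution(base_probs) -> np.ndarray:
    p = np.asarray(base_probs, dtype=float)
    return np.einsum("i,j,k->ijk", p, p, p).reshape(64)


def shifted_trinucleotide_distribution(p: np.ndarray, tv: float) -> np.ndarray:
    """A distribution at exactly total-variation distance ``tv`` from ``p``.

    The extreme profile places all mass uniformly on the 32 trinucleotides
    the background disfavours most; blending linearly toward it reaches any
    smaller distance exactly, and the blend stays non-degenerate (every
    trinucleotide keeps positive probability).
    """
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    q_extreme = np.zeros_like(p)
    q_extreme[order[: len(p) // 2]] = 1.0 / (len(p) // 2)
    tv_max = 0.5 * float(np.abs(p - q_extreme).sum())
    if tv > tv_max + 1e-12:
        raise ValueError(f"requested shift {tv} exceeds attainable maximum {tv_max:.3f}")
    alpha = 0.0 if tv_max == 0 else tv / tv_max
    return (1 - alpha) * p + alpha * q_extreme


def _sample_from_trinuc(rng: np.random.Generator, length: int, q: np.ndarray) -> str:
    codes = rng.choice(64, size=(length + 2) // 3, p=q / q.sum())
    bases = "ACGT"
    out = "".join(bases[c >> 4] + bases[(c >> 2) & 3] + bases[c & 3] for c in codes)
    return out[:length]


def _codons(protein: str, rng: np.random.Generator, mode: str) -> str:
    if mode == "fixed":
        return "".join(FIXED_CODON[a] for a in protein)
    from Bio.Data.CodonTable import standard_dna_table

    by_aa: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    return "".join(by_aa[a][rng.integers(len(by_aa[a]))] for a in protein)


def _mutated_rep(consensus: str, rng: np.random.Generator, max_mut: int) -> tuple[str, float]:
    m = int(rng.integers(0, max_mut + 1))
    seq = list(consensus)
    for pos in rng.choice(len(seq), size=m, replace=False):
        seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
    return "".join(seq), (len(seq) - m) / len(seq)


# ---------------------------------------------------------------------------
# effector N-terminus construction


def _effector_nterm(rng: np.random.Generator, violated: str | None) -> str:
    """A 50-aa N-terminus passing all four rules, or violating exactly one.

    Base template: M, K, aliphatic at 3, then a shuffled polar-rich fill
    with >= 6 Ser and >= 22 polar residues in the first 50 and no acidic
    residue in the first 12.
    """
    head = ["M", "K", str(rng.choice(list("LVIA")))]  # aliphatic at position 3
    fill_first12 = list(rng.choice(list("KTNQGHR"), size=9))  # 4-12: zero acidic
    # positions 13-50: 6 Ser, 16 other polar, 16 gene-specific filler, so the
    # rules hold with margin but no two planted genes share a residue multiset
    tail = (
        ["S"] * 6
        + list(rng.choice(list("TNQ"), size=16))
        + list(rng.choice(list("GKHRAVLIPWFM"), size=16))
    )
    rng.shuffle(tail)
    seq = head + fill_first12 + tail

    if violated == "acidic":
        seq[1], seq[6] = "D", "E"  # two acidic residues within the first 12
    elif violated == "aliphatic":
        seq[2], seq[3] = "W", "G"  # neither position 3 nor 4 aliphatic
    elif violated == "ser":
        seq = [("T" if a == "S" else a) for a in seq]  # polar stays high, Ser drops
    elif violated == "polar":
        polar = set("STNQCY")
        seen_ser = 0
        for i in range(3, 50):
            if seq[i] == "S" and seen_ser < 5:
                seen_ser += 1  # keep exactly 5 Ser (10%) so only polar fails
            elif seq[i] in polar:
                seq[i] = str(rng.choice(list("GKHR")))
    elif violated is not None:
        raise ValueError(f"unknown rule {violated!r}")
    return "".join(seq)


# ---------------------------------------------------------------------------
# genome assembly


def assemble_genome(
    strain: str,
    truth: GroundTruth,
    proteins: Mapping[str, Mapping[str, str]],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> GenomeRecord:
    """Lay out one strain: genes with intergenic gaps, REP singletons and
    pairs inside gaps only, desert blocks, RAYT and effector genes. Planted
    structures are appended to ``truth``."""
    espec = config.effector_spec
    rep_len = len(config.rep_consensus)
    strain_proteins = dict(proteins[strain])

    # --- extra genes: RAYTs + effectors (registered as accessory families)
    rayt_loci, effector_plan = [], []
    for i in range(config.rayt_per_strain):
        locus = f"{strain}_rayt{i + 1}"
        rayt_loci.append(locus)
        strain_proteins[locus] = _random_protein(int(rng.integers(200, 300)), rng)
        truth.family_membership[f"tfam_rayt_{strain}_{i + 1}"] = {(strain, locus)}
        truth.family_class[f"tfam_rayt_{strain}_{i + 1}"] = f"accessory:{strain}"
        truth.planted_rayts.append((strain, locus))
    plan: list[tuple[str | None, bool]] = [(None, True)] * espec.n_conforming
    plan += [(rule, True) for rule in espec.decoys]
    plan += [(None, False)] * espec.n_no_motif
    for i, (violated, has_motif) in enumerate(plan):
        locus = f"{strain}_eff{i + 1}"
        effector_plan.append((locus, violated, has_motif))
        nterm = _effector_nterm(rng, violated)
        strain_proteins[locus] = nterm + _random_protein(
            int(rng.integers(60, 120)), rng, start_met=False
        )
        truth.family_membership[f"tfam_eff_{strain}_{i + 1}"] = {(strain, locus)}
        truth.family_class[f"tfam_eff_{strain}_{i + 1}"] = f"accessory:{strain}"

    # --- gene order and strands
    family_loci = truth.strain_loci(strain)
    family_loci = [l for l in family_loci if l in proteins[strain]]
    loci = family_loci + rayt_loci + [l for l, _, _ in effector_plan]
    order = list(rng.permutation(len(loci)))
    loci = [loci[i] for i in order]
    strands = {l: ("+" if rng.random() < 0.5 else "-") for l in loci}
    is_rayt = set(rayt_loci)
    eff_info = {l: (v, m) for l, v, m in effector_plan}

    # --- REP insertion units
    n_pairs = int(round(config.rep_copies * config.rep_pair_fraction / 2))
    n_singles = config.rep_copies - 2 * n_pairs
    units = ["pair"] * n_pairs + ["single"] * n_singles
    rng.shuffle(units)
    n_gaps = len(loci) + 1
    special = {
        i
        for i, l in enumerate(loci)
        if l in is_rayt or l in eff_info
    }
    eligible_gaps = [g for g in range(n_gaps) if g not in special and (g - 1) not in special]
    if not eligible_gaps:
        raise ValueError("genome too short for requested content: no free intergenic gaps")
    units_in_gap: dict[int, list[str]] = {}
    for u in units:
        g = eligible_gaps[int(rng.integers(len(eligible_gaps)))]
        units_in_gap.setdefault(g, []).append(u)

    # --- desert slots: spread across non-special gaps
    free_gaps = [g for g in eligible_gaps if 0 < g < n_gaps - 1]
    if config.desert_spec and len(free_gaps) < len(config.desert_spec):
        raise ValueError("genome too short for requested content: too few gaps for deserts")
    desert_gaps = {}
    for i, dspec in enumerate(config.desert_spec):
        idx = (i + 1) * len(free_gaps) // (len(config.desert_spec) + 1)
        while free_gaps[idx] in desert_gaps:
            idx = (idx + 1) % len(free_gaps)
        desert_gaps[free_gaps[idx]] = dspec

    background_q = product_trinucleotide_distribution(config.base_probs)

    parts: list[str] = []
    pos = 0
    occs: list[tuple[int, int, str, float]] = []
    pair_records: list[tuple[int, int, float]] = []
    atypical: list[GenomicInterval] = []
    features: list[CdsFeature] = []

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        start = pos
        pos += len(seq)
        return start, pos

    def emit_bg(length: int) -> None:
        emit(_background(rng, length, config.base_probs))

    def emit_rep(strand: str | None = None) -> tuple[int, int, str]:
        copy, ident = _mutated_rep(config.rep_consensus, rng, config.rep_max_mutations)
        st = strand or ("+" if rng.random() < 0.5 else "-")
        s, e = emit(copy if st == "+" else reverse_complement(copy))
        occs.append((s, e, st, ident))
        return s, e, st

    def emit_unit(kind: str) -> None:
        if kind == "single":
            emit_rep()
            return
        st = "+" if rng.random() < 0.5 else "-"
        s1, _, _ = emit_rep(st)
        emit_bg(config.pair_spacing_bp - rep_len)
        s2, _, _ = emit_rep("-" if st == "+" else "+")
        pair_records.append((s1, s2, float(s2 - s1)))

    for g in range(n_gaps):
        prev_locus = loci[g - 1] if g > 0 else None
        next_locus = loci[g] if g < len(loci) else None

        # head constraints from the previous gene
        if prev_locus in is_rayt:
            emit_bg(int(rng.integers(40, 180)))
            emit_rep()
        if prev_locus in eff_info and strands[prev_locus] == "-" and eff_info[prev_locus][1]:
            emit_bg(espec.upstream_offset - len(espec.motif))
            emit(reverse_complement(espec.motif))
            emit_bg(int(rng.integers(60, 150)))

        if g in desert_gaps:
            dspec = desert_gaps[g]
            emit_bg(int(rng.integers(60, 150)))
            q = shifted_trinucleotide_distribution(background_q, dspec.composition_shift)
            s, e = emit(_sample_from_trinuc(rng, dspec.length, q))
            atypical.append(GenomicInterval(strain, s, e, kind="atypical"))

        first = True
        for kind in units_in_gap.get(g, ()):
            emit_bg(int(rng.integers(60, 150)) if first else int(rng.integers(250, 400)))
            emit_unit(kind)
            first = False

        # tail constraints from the next gene
        if next_locus in is_rayt:
            emit_bg(int(rng.integers(200, 320)))
            emit_rep()
            emit_bg(int(rng.integers(40, 180)))
        elif next_locus in eff_info and strands[next_locus] == "+" and eff_info[next_locus][1]:
            emit_bg(int(rng.integers(150, 280)))
            emit(espec.motif)
            emit_bg(espec.upstream_offset - len(espec.motif))
        else:
            emit_bg(int(rng.integers(*config.intergenic_gap_range)))

        if next_locus is None:
            continue
        translation = strain_proteins[next_locus]
        coding = _codons(translation, rng, config.codon_mode)
        if strands[next_locus] == "+":
            s, _ = emit(coding)
            emit(STOP_CODON)
            cds = (s, s + len(coding))
        else:
            emit(reverse_complement(STOP_CODON))
            s, e = emit(reverse_complement(coding))
            cds = (s, e)
        features.append(
            CdsFeature(
                locus_tag=next_locus,
                start=cds[0],
                end=cds[1],
                strand=strands[next_locus],
                product_class="RAYT" if next_locus in is_rayt else None,
                translation=translation,
            )
        )

    genome = GenomeRecord(strain_id=strain, sequence="".join(parts), features=features)

    # --- ground-truth bookkeeping
    truth.rep_occurrences[strain] = sorted(occs)
    truth.planted_pairs[strain] = sorted(pair_records)
    truth.planted_atypical.extend(atypical)
    bounds = sorted((s, e) for s, e, _, _ in occs)
    for iv in atypical:
        prev_end = max((e for _, e in bounds if e <= iv.start), default=0)
        next_start = min((s for s, _ in bounds if s >= iv.end), default=genome.length)
        truth.planted_deserts.append(
            GenomicInterval(strain, prev_end, next_start, kind="rep_desert")
        )
    for locus, violated, has_motif in effector_plan:
        truth.planted_effectors.append(
            PlantedEffector(
                strain_id=strain,
                locus_tag=locus,
                conforming=violated is None,
                violated_rule=violated,
                has_motif=has_motif,
                motif_offset=espec.upstream_offset if has_motif else None,
            )
        )
    proteins[strain].update(strain_proteins)  # type: ignore[index]
    return genome


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full dataset: truth skeleton, evolved proteins, assembled genomes."""
    ss = np.random.SeedSequence(config.seed)
    evolve_seed, *strain_seeds = ss.spawn(1 + config.n_strains)
    truth = sample_pangenome_truth(config)
    proteins = evolve_protein_families(truth, config, np.random.default_rng(evolve_seed))
    genomes = {}
    for strain, seed in zip(config.strains, strain_seeds):
        genomes[strain] = assemble_genome(
            strain, truth, proteins, config, np.random.default_rng(seed)
        )
    return SyntheticDataset(config=config, truth=truth, genomes=genomes, proteins=proteins)


# ---------------------------------------------------------------------------
# fixture export


def write_fixtures(dataset: SyntheticDataset, outdir: str | Path, force: bool = False) -> dict:
    """Write per-strain FASTA/GFF3/protein-FASTA plus truth and a manifest."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for strain, genome in sorted(dataset.genomes.items()):
        fna = outdir / f"{strain}.fna"
        write_fasta([(strain, genome.sequence)], fna)
        gff = outdir / f"{strain}.gff"
        write_gff3(genome, gff)
        faa = outdir / f"{strain}.faa"
        write_fasta(
            sorted(dataset.proteins[strain].items()), faa
        )
        written += [fna, gff, faa]
    truth_path = outdir / "truth.json"
    truth_path.write_text(dataset.truth.to_json())
    written.append(truth_path)

    fam_tsv = outdir / "families.tsv"
    with open(fam_tsv, "w") as fh:
        fh.write("family_id\tclass\tmembers\n")
        for fid in sorted(dataset.truth.family_membership):
            members = ",".join(
                f"{s}:{l}" for s, l in sorted(dataset.truth.family_membership[fid])
            )
            fh.write(f"{fid}\t{dataset.truth.family_class[fid]}\t{members}\n")
    written.append(fam_tsv)

    manifest = {
        "seed": dataset.config.seed,
        "config_hash": dataset.config.config_hash(),
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(written)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
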