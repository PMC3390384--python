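"""Best-match protein orthology and presence/absence matrix assembly.

The layer mirrors a multiway best-match BLASTp workflow: per ordered strain
pair, every query keeps its single best-scoring subject above an E-value
cutoff (default 1e-5); gene families are connected components of the
resulting best-hit graph, either requiring reciprocity (default) or not.

The built-in similarity search is a desk-scale stand-in for BLASTp: exact
k-mer seeding restricts the candidate pairs, Smith-Waterman local alignment
(BLOSUM62, gap open 11 / extend 1) scores them, and E-values come from the
Karlin-Altschul formula E = K * m * n * exp(-lambda * S) with constants
K = 0.041, lambda = 0.267 applied to the raw score -- an approximation,
stated as such. Following the BLAST convention, m is the query length and n
the total residue count of the subject proteome (the database), so the
E-value reflects the whole search space and random cross-proteome hits are
not systematically under-estimated. Externally computed 12-column hit
tables can be used instead and take the same cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SimilarityHit",
    "SearchParams",
    "BestHitMap",
    "PresenceAbsenceMatrix",
    "OrthologyError",
    "internal_similarity_search",
    "best_match",
    "build_families",
    "family_stats",
    "DEFAULT_E_CUTOFF",
]

DEFAULT_E_CUTOFF = 1e-5

# Karlin-Altschul ungapped constants for BLOSUM62.
KA_K = 0.041
KA_LAMBDA = 0.267


class OrthologyError(Exception):
    pass


@dataclass
class SimilarityHit:
    """One local-alignment hit between proteins of two strains."""

    query_id: str
    subject_id: str
    query_strain: str
    subject_strain: str
    identity: float
    aln_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity must be a fraction in [0,1], got {self.identity}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class SearchParams:
    """Parameters of the internal k-mer seeded Smith-Waterman search."""

    k: int = 4
    gap_open: float = 11.0
    gap_extend: float = 1.0
    report_max: float = 1e-3

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class BestHitMap:
    """Per-query best subject for one ordered strain pair (A -> B)."""

    query_strain: str
    subject_strain: str
    entries: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    # entries: query locus -> (subject locus, evalue, bitscore)

    def best(self, query_id: str) -> str | None:
        entry = self.entries.get(query_id)
        return entry[0] if entry else None


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def bitscore_from_raw(score: float) -> float:
    return (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)


def _alignment_identity(aligner: Align.PairwiseAligner, query: str, subject: str) -> tuple[float, int]:
    aln = aligner.align(query, subject)[0]
    c = aln.counts()
    aln_length = c.identities + c.mismatches + c.gaps
    return (c.identities / aln_length if aln_length else 0.0), aln_length


def smith_waterman_score(query: str, subject: str, params: SearchParams | None = None) -> float:
    """Plain local-alignment score, no seeding (used as an exhaustive oracle)."""
    return _make_aligner(params or SearchParams()).score(query, subject)


def internal_similarity_search(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    params: SearchParams | None = None,
    query_strain: str = "A",
    subject_strain: str = "B",
) -> list[SimilarityHit]:
    """All-vs-all seeded local alignment between two proteomes.

    Only pairs sharing at least one exact ``k``-mer are aligned; hits with
    E-value <= ``params.report_max`` are reported. E-values use the subject
    proteome's total residue count as the database size.
    """
    params = params or SearchParams()
    if not proteome_a or not proteome_b:
        raise OrthologyError("empty proteome")
    aligner = _make_aligner(params)
    k = params.k
    n_db = sum(len(s) for s in proteome_b.values())

    index: dict[str, set[str]] = {}
    for sid, sseq in proteome_b.items():
        for i in range(len(sseq) - k + 1):
            index.setdefault(sseq[i : i + k], set()).add(sid)

    hits: list[SimilarityHit] = []
    for qid, qseq in proteome_a.items():
        candidates: set[str] = set()
        for i in range(len(qseq) - k + 1):
            candidates |= index.get(qseq[i : i + k], set())
        for sid in sorted(candidates):
            sseq = proteome_b[sid]
            score = aligner.score(qseq, sseq)
            evalue = karlin_altschul_evalue(score, len(qseq), n_db)
            if evalue > params.report_max:
                continue
            identity, aln_length = _alignment_identity(aligner, qseq, sseq)
            hits.append(
                SimilarityHit(
                    query_id=qid,
                    subject_id=sid,
                    query_strain=query_strain,
                    subject_strain=subject_strain,
                    identity=identity,
                    aln_length=aln_length,
                    evalue=evalue,
                    bitscore=bitscore_from_raw(score),
                )
            )
    return hits


def best_match(hits: Iterable[SimilarityHit], e_cutoff: float = DEFAULT_E_CUTOFF) -> BestHitMap:
    """Keep, per query, the best subject among hits passing the E-value cutoff.

    Best = maximal bitscore; ties broken by lower E-value, then by the
    lexicographically smallest subject id. All hits must share one ordered
    strain pair.
    """
    hits = list(hits)
    pairs = {(h.query_strain, h.subject_strain) for h in hits}
    if len(pairs) > 1:
        raise OrthologyError(f"mixed strain pairs in input: {sorted(pairs)}")
    qs, ss = next(iter(pairs)) if pairs else ("", "")
    bm = BestHitMap(query_strain=qs, subject_strain=ss)
    for h in hits:
        if h.evalue > e_cutoff:
            continue
        incumbent = bm.entries.get(h.query_id)
        key = (-h.bitscore, h.evalue, h.subject_id)
        if incumbent is None or key < (-incumbent[2], incumbent[1], incumbent[0]):
            bm.entries[h.query_id] = (h.subject_id, h.evalue, h.bitscore)
    return bm


class PresenceAbsenceMatrix:
    """Ortholog families x strains, with gene-id backreferences.

    ``families`` maps family id -> {strain -> set of locus tags}; every locus
    tag belongs to exactly one family.
    """

    def __init__(self, families: dict[str, dict[str, set[str]]], strains: Sequence[str]):
        self.families = families
        self.strains = list(strains)
        self._validate()

    def _validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for fam, occ in self.families.items():
            for strain, loci in occ.items():
                if strain not in self.strains:
                    raise OrthologyError(f"family {fam} references unknown strain {strain}")
                for locus in loci:
                    if (strain, locus) in seen:
                        raise OrthologyError(f"gene {strain}/{locus} in more than one family")
                    seen.add((strain, locus))

    def occupancy(self, family_id: str) -> frozenset[str]:
        return frozenset(s for s, loci in self.families[family_id].items() if loci)

    def families_of_strain(self, strain: str) -> set[str]:
        if strain not in self.strains:
            raise OrthologyError(f"unknown strain {strain}")
        return {f for f, occ in self.families.items() if occ.get(strain)}

    def gene_count(self, strain: str) -> int:
        return sum(len(occ.get(strain, ())) for occ in self.families.values())

    def to_binary_frame(self) -> pd.DataFrame:
        data = {
            fam: {s: int(bool(occ.get(s))) for s in self.strains}
            for fam, occ in self.families.items()
        }
        return pd.DataFrame.from_dict(data, orient="index").reindex(columns=self.strains).fillna(0)

    def to_gene_frame(self) -> pd.DataFrame:
        data = {
            fam: {s: ",".join(sorted(occ.get(s, ()))) for s in self.strains}
            for fam, occ in self.families.items()
        }
        return pd.DataFrame.from_dict(data, orient="index").reindex(columns=self.strains)


def build_families(
    best_hit_maps: Iterable[BestHitMap],
    proteomes: Mapping[str, Iterable[str]],
    mode: str = "reciprocal",
) -> PresenceAbsenceMatrix:
    """Assemble families as connected components of the best-hit graph.

    mode="reciprocal": an edge joins gene a of strain A to gene b of strain B
    iff a's best match in B is b AND b's best match in A is a.
    mode="unidirectional": a one-way best match suffices. Genes without any
    edge become singleton families. A map must exist for every ordered pair
    of distinct strains.
    """
    if mode not in ("reciprocal", "unidirectional"):
        raise ValueError(f"unknown mode {mode!r}")
    strains = sorted(proteomes)
    maps = {(m.query_strain, m.subject_strain): m for m in best_hit_maps}
    for a in strains:
        for b in strains:
            if a != b and (a, b) not in maps:
                raise OrthologyError(f"missing best-hit map for ordered pair ({a}, {b})")

    graph = nx.Graph()
    for strain in strains:
        for locus in proteomes[strain]:
            graph.add_node((strain, locus))
    for (a, b), bm in maps.items():
        if a >= b:  # handle each unordered pair once
            continue
        back = maps[(b, a)]
        for qa, (sb, _, _) in bm.entries.items():
            if mode == "unidirectional" or back.best(sb) == qa:
                graph.add_edge((a, qa), (b, sb))
        if mode == "unidirectional":
            for qb, (sa, _, _) in back.entries.items():
                graph.add_edge((b, qb), (a, sa))

    families: dict[str, dict[str, set[str]]] = {}
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    width = max(4, len(str(len(components))))
    for i, comp in enumerate(components, start=1):
        occ: dict[str, set[str]] = {}
        for strain, locus in comp:
            occ.setdefault(strain, set()).add(locus)
        families[f"fam{i:0{width}d}"] = occ
    return PresenceAbsenceMatrix(families, strains)


def family_stats(matrix: PresenceAbsenceMatrix) -> pd.DataFrame:
    """Per-family occupancy and per-strain paralog counts."""
    rows = []
    for fam, occ in matrix.families.items():
        row: dict[str, object] = {
            "family_id": fam,
            "n_strains": sum(1 for s in matrix.strains if occ.get(s)),
            "n_genes": sum(len(v) for v in occ.values()),
        }
        for s in matrix.strains:
            row[f"paralogs_{s}"] = len(occ.get(s, ()))
        rows.append(row)
    columns = ["family_id", "n_strains", "n_genes"] + [f"paralogs_{s}" for s in matrix.strains]
    return pd.DataFrame(rows, columns=columns)
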