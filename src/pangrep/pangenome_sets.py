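"""Set algebra over the ortholog presence/absence matrix.

Core, pan, strain-unique and lineage-specific family sets, exhaustive Venn
partitions, and the pairwise shared-gene proportion normalised by the
smaller of the two genomes. Counts are reported in families; per-strain gene
counts accompany them because family counts and CDS counts differ whenever
paralogs collapse into one family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .orthology import OrthologyError, PresenceAbsenceMatrix

__all__ = [
    "GeneSetReport",
    "core_families",
    "pan_families",
    "unique_families",
    "specific_shared_families",
    "venn_partition",
    "shared_proportion",
]


@dataclass
class GeneSetReport:
    """A named family set with per-strain gene counts."""

    label: str
    strain_scope: frozenset[str]
    family_ids: frozenset[str]
    genes_per_strain: dict[str, int] = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return len(self.family_ids)


def _check_strains(matrix: PresenceAbsenceMatrix, strains: Iterable[str]) -> list[str]:
    strains = list(strains)
    unknown = set(strains) - set(matrix.strains)
    if unknown:
        raise OrthologyError(f"unknown strain(s): {sorted(unknown)}")
    return strains


def _report(matrix: PresenceAbsenceMatrix, label: str, scope: Iterable[str], fams: set[str]) -> GeneSetReport:
    scope = frozenset(scope)
    genes = {
        s: sum(len(matrix.families[f].get(s, ())) for f in fams)
        for s in matrix.strains
    }
    return GeneSetReport(label=label, strain_scope=scope, family_ids=frozenset(fams), genes_per_strain=genes)


def core_families(matrix: PresenceAbsenceMatrix, strains: Sequence[str] | None = None) -> GeneSetReport:
    """Families present (>= 1 gene) in every strain of ``strains``."""
    strains = _check_strains(matrix, strains if strains is not None else matrix.strains)
    if not strains:
        raise OrthologyError("core requires a nonempty strain set")
    need = set(strains)
    fams = {f for f in matrix.families if need <= matrix.occupancy(f)}
    return _report(matrix, "core", strains, fams)


def pan_families(matrix: PresenceAbsenceMatrix, strains: Sequence[str] | None = None) -> GeneSetReport:
    """Families present in at least one strain of ``strains``."""
    strains = _check_strains(matrix, strains if strains is not None else matrix.strains)
    want = set(strains)
    fams = {f for f in matrix.families if matrix.occupancy(f) & want}
    return _report(matrix, "pan", strains, fams)


def unique_families(matrix: PresenceAbsenceMatrix, strain: str) -> GeneSetReport:
    """Families whose occupancy is exactly {strain}."""
    _check_strains(matrix, [strain])
    fams = {f for f in matrix.families if matrix.occupancy(f) == frozenset({strain})}
    return _report(matrix, f"unique:{strain}", [strain], fams)


def specific_shared_families(
    matrix: PresenceAbsenceMatrix,
    in_set: Sequence[str],
    out_set: Sequence[str],
) -> GeneSetReport:
    """Families in every ``in_set`` strain and absent from every ``out_set`` strain."""
    in_set = _check_strains(matrix, in_set)
    out_set = _check_strains(matrix, out_set)
    if not in_set:
        raise OrthologyError("in_set must be nonempty")
    overlap = set(in_set) & set(out_set)
    if overlap:
        raise OrthologyError(f"in_set and out_set overlap: {sorted(overlap)}")
    need, forbid = set(in_set), set(out_set)
    fams = {
        f
        for f in matrix.families
        if need <= matrix.occupancy(f) and not (forbid & matrix.occupancy(f))
    }
    return _report(matrix, "specific_shared", in_set, fams)


def venn_partition(
    matrix: PresenceAbsenceMatrix, strains: Sequence[str] | None = None
) -> dict[frozenset[str], int]:
    """Family counts per exact occupancy pattern over ``strains``.

    Every family present in at least one of the strains lands in exactly one
    cell; the counts sum to the pan-genome size of the strain set.
    """
    strains = _check_strains(matrix, strains if strains is not None else matrix.strains)
    if len(strains) > 10:
        raise OrthologyError("venn partition supports at most 10 strains (2^n patterns)")
    want = set(strains)
    partition: dict[frozenset[str], int] = {}
    for f in matrix.families:
        pattern = frozenset(matrix.occupancy(f) & want)
        if pattern:
            partition[pattern] = partition.get(pattern, 0) + 1
    return partition


def shared_proportion(
    matrix: PresenceAbsenceMatrix,
    strain_a: str,
    strain_b: str,
    denominator: str = "families",
) -> float:
    """Shared families divided by the smaller genome's content.

    ``denominator="families"`` divides by the smaller per-strain family
    count; ``"cds"`` divides by the smaller per-strain gene (CDS) count.
    The two agree exactly when no family has paralogs.
    """
    _check_strains(matrix, [strain_a, strain_b])
    if denominator not in ("families", "cds"):
        raise ValueError(f"unknown denominator {denominator!r}")
    fams_a = matrix.families_of_strain(strain_a)
    fams_b = matrix.families_of_strain(strain_b)
    shared = len(fams_a & fams_b)
    if denominator == "families":
        denom = min(len(fams_a), len(fams_b))
    else:
        denom = min(matrix.gene_count(strain_a), matrix.gene_count(strain_b))
    return shared / denom if denom else 0.0
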