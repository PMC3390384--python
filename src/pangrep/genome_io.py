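"""Genome, annotation, interval and similarity-hit I/O.

All coordinates inside the package are 0-based, half-open. Conversion to and
from the 1-based inclusive convention of GFF3 happens here and nowhere else.
Sequences are uppercase nucleotide strings over {A, C, G, T, N}; ``N`` never
matches any base in downstream scanning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeIOError",
    "NoRecordsError",
    "IllegalCharacterError",
    "FeatureBoundsError",
    "DuplicateLocusTagError",
    "HitTableError",
    "CdsFeature",
    "GenomeRecord",
    "GenomicInterval",
    "INTERVAL_KINDS",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "read_hit_table",
    "write_hit_table",
    "reverse_complement",
]

VALID_NUCLEOTIDES = frozenset("ACGTN")
INTERVAL_KINDS = ("rep_desert", "atypical", "mge", "custom")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(Exception):
    """Base class for I/O and validation failures in this module."""


class NoRecordsError(GenomeIOError):
    """A sequence file contained no records."""


class IllegalCharacterError(GenomeIOError):
    """A sequence contained a character outside the allowed alphabet."""


class FeatureBoundsError(GenomeIOError):
    """A feature or interval lies outside its genome's coordinates."""


class DuplicateLocusTagError(GenomeIOError):
    """Two CDS features in one strain share a locus tag."""


class HitTableError(GenomeIOError):
    """A tabular similarity-hit file is malformed."""


@dataclass
class CdsFeature:
    """A protein-coding feature on a genome, stop codon excluded.

    ``start``/``end`` are 0-based half-open; ``strand`` is ``+`` or ``-``.
    When a translation is attached its length must equal ``(end - start) // 3``.
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    product_class: str | None = None
    translation: str | None = None

    def __post_init__(self) -> None:
        if not self.locus_tag:
            raise ValueError("locus_tag must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.locus_tag}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")
        if self.translation is not None and len(self.translation) != (self.end - self.start) // 3:
            raise ValueError(
                f"{self.locus_tag}: translation length {len(self.translation)} != "
                f"CDS length {self.end - self.start} // 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """One strain's nucleotide sequence plus its CDS annotation."""

    strain_id: str
    sequence: str
    circular: bool = False
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise ValueError("strain_id must be nonempty")
        bad = set(self.sequence) - VALID_NUCLEOTIDES
        if bad:
            offset = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise IllegalCharacterError(
                f"{self.strain_id}: illegal character {self.sequence[offset]!r} at offset {offset}"
            )
        self.validate_features()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate_features(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.end > self.length:
                raise FeatureBoundsError(
                    f"{self.strain_id}/{f.locus_tag}: [{f.start}, {f.end}) exceeds "
                    f"genome length {self.length}"
                )
            if f.locus_tag in seen:
                raise DuplicateLocusTagError(f"{self.strain_id}: duplicate locus_tag {f.locus_tag}")
            seen.add(f.locus_tag)

    def proteome(self) -> dict[str, str]:
        """locus_tag -> translation for all features carrying one."""
        return {f.locus_tag: f.translation for f in self.features if f.translation is not None}


@dataclass
class GenomicInterval:
    """A typed interval (REP desert, atypical region, MGE, custom) on one strain."""

    strain_id: str
    start: int
    end: int
    kind: str = "custom"
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.kind not in INTERVAL_KINDS:
            raise ValueError(f"unknown interval kind {self.kind!r}; expected one of {INTERVAL_KINDS}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read nucleotide FASTA as ``[(id, sequence), ...]``.

    Sequences are uppercased and U is mapped to T; characters outside
    {A,C,G,T,N} raise :class:`IllegalCharacterError` naming the offset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - VALID_NUCLEOTIDES
        if bad:
            offset = next(i for i, c in enumerate(seq) if c in bad)
            raise IllegalCharacterError(
                f"{path.name}:{rec.id}: illegal character {seq[offset]!r} at offset {offset}"
            )
        if not seq:
            raise NoRecordsError(f"{path.name}: record {rec.id} is empty")
        records.append((rec.id, seq))
    if not records:
        raise NoRecordsError(f"{path.name}: no records")
    return records


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA keyed by record id (no alphabet coercion)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = {str(rec.id): str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not out:
        raise NoRecordsError(f"{path.name}: no records")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(
    path: str | Path,
    genome: GenomeRecord,
    protein_fasta: str | Path | Mapping[str, str] | None = None,
) -> list[CdsFeature]:
    """Read CDS features for ``genome`` from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open
    here. Translations come from the GFF attribute ``translation`` when
    present, else from ``protein_fasta`` keyed by locus tag. Features are
    returned sorted by start and attached to ``genome``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    proteins: Mapping[str, str] = {}
    if protein_fasta is not None:
        proteins = (
            protein_fasta
            if isinstance(protein_fasta, Mapping)
            else read_protein_fasta(protein_fasta)
        )

    features: list[CdsFeature] = []
    seen: set[str] = set()
    for f in gffutils.DataIterator(str(path)):
        if f.featuretype != "CDS" or f.seqid != genome.strain_id:
            continue
        locus = (f.attributes.get("ID") or f.attributes.get("locus_tag") or [None])[0]
        if locus is None:
            raise GenomeIOError(f"{path.name}: CDS line without ID/locus_tag attribute")
        if locus in seen:
            raise DuplicateLocusTagError(f"{genome.strain_id}: duplicate locus_tag {locus}")
        seen.add(locus)
        start, end = f.start - 1, f.end  # GFF3 1-based inclusive -> half-open
        if end > genome.length or start < 0:
            raise FeatureBoundsError(
                f"{genome.strain_id}/{locus}: [{start}, {end}) exceeds genome "
                f"length {genome.length}"
            )
        product_class = (f.attributes.get("product_class") or [None])[0]
        translation = (f.attributes.get("translation") or [None])[0]
        if translation is None:
            translation = proteins.get(locus)
        features.append(
            CdsFeature(
                locus_tag=locus,
                start=start,
                end=end,
                strand=f.strand,
                product_class=product_class,
                translation=translation,
            )
        )
    features.sort(key=lambda f: (f.start, f.locus_tag))
    genome.features = features
    genome.validate_features()
    return features


def write_gff3(genome: GenomeRecord, path: str | Path) -> None:
    """Write the genome's CDS features as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.strain_id} 1 {genome.length}\n")
        for f in sorted(genome.features, key=lambda f: (f.start, f.locus_tag)):
            attrs = [f"ID={f.locus_tag}"]
            if f.product_class:
                attrs.append(f"product_class={f.product_class}")
            fh.write(
                f"{genome.strain_id}\tpangrep\tCDS\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t0\t{';'.join(attrs)}\n"
            )


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals of a single kind as BED (0-based half-open).

    Rows are sorted by (strain, start). An empty list yields a file holding
    only the header comment. Mixing interval kinds in one track file raises
    ``ValueError``; write one file per kind.
    """
    kinds = {iv.kind for iv in intervals}
    if len(kinds) > 1:
        raise ValueError(f"one BED track per interval kind; got {sorted(kinds)}")
    kind = next(iter(kinds)) if kinds else "empty"
    with open(path, "w") as fh:
        fh.write(f"# pangrep track kind={kind}\n")
        for iv in sorted(intervals, key=lambda iv: (iv.strain_id, iv.start, iv.end)):
            score = "." if iv.score is None else f"{iv.score:.6g}"
            fh.write(f"{iv.strain_id}\t{iv.start}\t{iv.end}\t{iv.kind}\t{score}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    for line in path.read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        strain, start, end = parts[0], int(parts[1]), int(parts[2])
        kind = parts[3] if len(parts) > 3 else "custom"
        score = None if len(parts) < 5 or parts[4] == "." else float(parts[4])
        out.append(GenomicInterval(strain_id=strain, start=start, end=end, kind=kind, score=score))
    return out


# ---------------------------------------------------------------------------
# 12-column tabular similarity hits (BLAST outfmt 6 layout)

_HIT_COLUMNS = 12


def read_hit_table(
    path: str | Path,
    query_strain: str = "",
    subject_strain: str = "",
):
    """Read a 12-column tabular hit file into :class:`~pangrep.orthology.SimilarityHit`.

    Columns: query, subject, %identity, length, mismatches, gapopens,
    qstart, qend, sstart, send, evalue, bitscore. Percent identity is
    converted to a fraction. Strain labels are not part of the format and
    are supplied by the caller (one file per ordered strain pair).
    """
    from .orthology import SimilarityHit

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = re.split(r"\s+", line.strip())
        if len(parts) != _HIT_COLUMNS:
            raise HitTableError(
                f"{path.name}:{lineno}: expected {_HIT_COLUMNS} columns, got {len(parts)}"
            )
        try:
            identity = float(parts[2]) / 100.0
            aln_length = int(parts[3])
            evalue = float(parts[10])
            bitscore = float(parts[11])
        except ValueError as exc:
            raise HitTableError(f"{path.name}:{lineno}: non-numeric field ({exc})") from exc
        hits.append(
            SimilarityHit(
                query_id=parts[0],
                subject_id=parts[1],
                query_strain=query_strain,
                subject_strain=subject_strain,
                identity=identity,
                aln_length=aln_length,
                evalue=evalue,
                bitscore=bitscore,
            )
        )
    return hits


def write_hit_table(hits, path: str | Path) -> None:
    """Write hits in the 12-column layout (fields we do not track are 0)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{100.0 * h.identity:.1f}\t{h.aln_length}\t0\t0\t"
                f"0\t0\t0\t0\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )
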