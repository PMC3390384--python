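"""Rule-based screen for candidate type III secretion system effectors.

Candidates combine two signals: a promoter motif (an Hrp-box position weight
matrix supplied by the user; HrpL-dependent promoters precede many effector
genes) found in the strand-aware upstream window of a CDS, and an N-terminal
amino-acid composition typical of T3SS-secreted proteins -- abundance of
serine and polar residues near the N-terminus, at most one acidic residue
(D/E) in the first 12 positions, and an aliphatic residue at position 3 or 4
(1-based, initiator Met = position 1). The published screen does not
quantify "abundance"; the serine and polar fraction thresholds here are
configurable defaults chosen by this package, not published values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CdsFeature, GenomeRecord, reverse_complement

__all__ = [
    "NTermRules",
    "PromoterHit",
    "EffectorCandidate",
    "read_pwm",
    "pwm_from_motif",
    "scan_promoter_motif",
    "nterm_filter",
    "screen_effectors",
    "RULE_NAMES",
]

RULE_NAMES = ("ser", "polar", "acidic", "aliphatic")
_PWM_ROWS = "ACGT"


@dataclass(frozen=True)
class NTermRules:
    """Thresholds and residue sets of the N-terminal composition filter."""

    nterm_window: int = 50
    min_ser_frac: float = 0.10
    min_polar_frac: float = 0.40
    acidic_set: frozenset[str] = frozenset("DE")
    max_acidic_first_k: int = 1
    first_k: int = 12
    aliphatic_set: frozenset[str] = frozenset("AVLI")
    aliphatic_positions: tuple[int, ...] = (3, 4)  # 1-based incl. initiator Met
    polar_set: frozenset[str] = frozenset("STNQCY")

    def __post_init__(self) -> None:
        if not (0 <= self.min_ser_frac <= 1 and 0 <= self.min_polar_frac <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if min(self.aliphatic_positions) < 1 or self.first_k < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        if self.acidic_set & self.aliphatic_set:
            raise ValueError("acidic and aliphatic sets must be disjoint")


@dataclass
class PromoterHit:
    score: float
    offset: int  # bp from motif start to the CDS start, in gene orientation


@dataclass
class EffectorCandidate:
    locus_tag: str
    promoter_hit: PromoterHit | None
    rule_flags: dict[str, bool] = field(default_factory=dict)
    screenable: bool = True

    @property
    def overall_pass(self) -> bool:
        return (
            self.screenable
            and self.promoter_hit is not None
            and all(self.rule_flags.get(r, False) for r in RULE_NAMES)
        )


# ---------------------------------------------------------------------------
# PWM handling


def read_pwm(path: str | Path) -> np.ndarray:
    """Read a 4-row (A, C, G, T) tab-separated probability matrix.

    Each column must sum to 1 (tolerance 1e-3) before the log-odds
    transform; malformed matrices raise ``ValueError``.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].upper() in tuple(_PWM_ROWS):
            parts = parts[1:]
        rows.append([float(x) for x in parts])
    pwm = np.asarray(rows, dtype=float)
    return validate_pwm(pwm)


def validate_pwm(pwm: np.ndarray) -> np.ndarray:
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] != 4:
        raise ValueError(f"PWM must have 4 rows (A,C,G,T); got shape {pwm.shape}")
    sums = pwm.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError(f"PWM columns must sum to 1; sums are {sums}")
    return pwm


def pwm_from_motif(motif: str, match_prob: float = 0.97) -> np.ndarray:
    """Near-indicator PWM for an exact nucleotide motif (testing helper)."""
    off = (1.0 - match_prob) / 3.0
    pwm = np.full((4, len(motif)), off)
    for j, base in enumerate(motif):
        pwm[_PWM_ROWS.index(base), j] = match_prob
    return pwm


def _log_odds(pwm: np.ndarray, background: float = 0.25, eps: float = 1e-9) -> np.ndarray:
    return np.log2((pwm + eps) / background)


# ---------------------------------------------------------------------------
# promoter scan


def _upstream_sequence(genome: GenomeRecord, feature: CdsFeature, window: int) -> str:
    """Strand-aware upstream region, 5'->3' toward the start codon."""
    if feature.strand == "+":
        return genome.sequence[max(0, feature.start - window) : feature.start]
    return reverse_complement(genome.sequence[feature.end : min(genome.length, feature.end + window)])


def scan_promoter_motif(
    genome: GenomeRecord,
    features: Sequence[CdsFeature],
    pwm: np.ndarray,
    upstream_window: int = 500,
    score_threshold: float = 0.0,
) -> dict[str, PromoterHit | None]:
    """Best above-threshold motif position in each CDS's upstream window.

    Scoring is log-odds against a uniform background. The reported offset is
    the distance in bp from the motif start to the CDS start codon, in gene
    orientation (motif immediately abutting the start codon has offset
    == motif length).
    """
    pwm = validate_pwm(pwm)
    lo = _log_odds(pwm)
    width = pwm.shape[1]
    out: dict[str, PromoterHit | None] = {}
    for f in features:
        region = _upstream_sequence(genome, f, upstream_window)
        best: PromoterHit | None = None
        for i in range(len(region) - width + 1):
            window_seq = region[i : i + width]
            if "N" in window_seq:
                continue
            score = sum(lo[_PWM_ROWS.index(b), j] for j, b in enumerate(window_seq))
            if score >= score_threshold and (best is None or score > best.score):
                best = PromoterHit(score=float(score), offset=len(region) - i)
        out[f.locus_tag] = best
    return out


# ---------------------------------------------------------------------------
# N-terminal rules


def nterm_filter(translation: str, rules: NTermRules | None = None) -> dict[str, bool] | None:
    """Evaluate the four N-terminal composition rules on one translation.

    Returns None (not screenable) for sequences shorter than the first-K
    acidic window; otherwise a per-rule pass/fail dict with keys
    ``ser``, ``polar``, ``acidic``, ``aliphatic``.
    """
    rules = rules or NTermRules()
    if len(translation) < rules.first_k:
        return None
    head = translation[: rules.nterm_window]
    ser_frac = head.count("S") / len(head)
    polar_frac = sum(head.count(a) for a in rules.polar_set) / len(head)
    acidic_count = sum(translation[: rules.first_k].count(a) for a in rules.acidic_set)
    aliphatic_ok = any(
        pos <= len(translation) and translation[pos - 1] in rules.aliphatic_set
        for pos in rules.aliphatic_positions
    )
    return {
        "ser": ser_frac >= rules.min_ser_frac,
        "polar": polar_frac >= rules.min_polar_frac,
        "acidic": acidic_count <= rules.max_acidic_first_k,
        "aliphatic": aliphatic_ok,
    }


# ---------------------------------------------------------------------------
# combined screen


def screen_effectors(
    genome: GenomeRecord,
    features: Sequence[CdsFeature] | None = None,
    pwm: np.ndarray | None = None,
    rules: NTermRules | None = None,
    upstream_window: int = 500,
    score_threshold: float = 0.0,
) -> tuple[list[EffectorCandidate], pd.DataFrame]:
    """Screen all CDSs; candidates pass every N-terminal rule AND carry a
    promoter hit. With ``pwm=None`` the screen runs in rules-only mode and
    the promoter requirement is waived. Returns (candidates, audit table).
    """
    rules = rules or NTermRules()
    features = list(features) if features is not None else list(genome.features)
    hits: Mapping[str, PromoterHit | None]
    if pwm is not None:
        hits = scan_promoter_motif(genome, features, pwm, upstream_window, score_threshold)
    else:
        hits = {f.locus_tag: None for f in features}

    results: list[EffectorCandidate] = []
    rows = []
    for f in features:
        flags = nterm_filter(f.translation, rules) if f.translation else None
        cand = EffectorCandidate(
            locus_tag=f.locus_tag,
            promoter_hit=hits.get(f.locus_tag),
            rule_flags=flags or {},
            screenable=flags is not None,
        )
        results.append(cand)
        rows.append(
            {
                "locus_tag": f.locus_tag,
                "screenable": cand.screenable,
                **{f"rule_{r}": (flags or {}).get(r) for r in RULE_NAMES},
                "promoter_score": None if cand.promoter_hit is None else cand.promoter_hit.score,
                "promoter_offset": None if cand.promoter_hit is None else cand.promoter_hit.offset,
                "overall_pass": cand.overall_pass
                if pwm is not None
                else cand.screenable and all((flags or {}).values()),
            }
        )
    audit = pd.DataFrame(rows)
    if pwm is None:
        candidates = [c for c in results if c.screenable and c.rule_flags and all(c.rule_flags.values())]
    else:
        candidates = [c for c in results if c.overall_pass]
    return candidates, audit
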