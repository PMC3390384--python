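"""Pipeline orchestration: one config, deterministic seeding, a report
bundle with a manifest.

Stages run in dependency order (io -> orthology -> sets; io -> rep; io ->
composition; io -> effectors). A single top-level seed fans out to per-stage
child seeds through ``numpy.random.SeedSequence``, so adding or removing a
stage cannot perturb another stage's randomness. Every run writes a
``manifest.json`` listing parameters, the seed, the package version and a
sha256 per output file; two runs with the same config and seed produce
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import composition_atypia as ca
from . import effector_screen as es
from . import pangenome_sets as ps
from . import rep_landscape as rl
from .genome_io import write_bed
from .orthology import (
    SearchParams,
    best_match,
    build_families,
    family_stats,
    internal_similarity_search,
)
from .synthetic_genomes import (
    DesertSpec,
    EffectorSpec,
    SyntheticConfig,
    SyntheticDataset,
    simulate_dataset,
    write_fixtures,
)

logger = logging.getLogger("pangrep")

ALL_STAGES = ("io", "orthology", "pangenome", "rep", "composition", "effectors")
_STAGE_DEPS = {
    "io": (),
    "orthology": ("io",),
    "pangenome": ("io", "orthology"),
    "rep": ("io",),
    "composition": ("io",),
    "effectors": ("io",),
}


class PipelineConfigError(Exception):
    pass


@dataclass
class OrthologyParams:
    e_cutoff: float = 1e-5
    mode: str = "reciprocal"  # or "unidirectional"
    k: int = 4
    report_max: float = 1e-3


@dataclass
class RepParams:
    min_len: int = 30
    min_count: int = 11
    min_identity: float = 0.90
    primary_min_total: int = 250
    primary_intergenic_only: bool = True
    max_center_sep: float = 200.0
    desert_min_len: int = 25000
    desert_gap_mode: str = "edge"
    rayt_window: int = 300


@dataclass
class CompositionParams:
    window: int = 5000
    step: int = 1000
    percentile: float = 99.0
    threshold: str = "robust"


@dataclass
class EffectorParams:
    upstream_window: int = 500
    score_threshold_frac: float = 0.9  # fraction of the PWM's maximum score
    pwm_path: str | None = None  # defaults to the synthetic motif's PWM


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "pangrep_out"
    stages: tuple[str, ...] = ALL_STAGES
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    orthology: OrthologyParams = field(default_factory=OrthologyParams)
    rep: RepParams = field(default_factory=RepParams)
    composition: CompositionParams = field(default_factory=CompositionParams)
    effectors: EffectorParams = field(default_factory=EffectorParams)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stage(s): {sorted(unknown)}")


def _build_section(cls, raw: dict, path: str):
    if not isinstance(raw, dict):
        raise PipelineConfigError(f"{path}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise PipelineConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key == "desert_spec":
            value = tuple(DesertSpec(**d) for d in value)
        elif key == "effector_spec":
            value = EffectorSpec(**{**value, "decoys": tuple(value.get("decoys", EffectorSpec().decoys))})
        elif key in ("protein_length_range", "intergenic_gap_range", "base_probs", "stages", "decoys"):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise PipelineConfigError(f"{path}: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; unknown keys are rejected
    before any compute."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise PipelineConfigError("config must be a mapping")
    sections = {
        "synthetic": SyntheticConfig,
        "orthology": OrthologyParams,
        "rep": RepParams,
        "composition": CompositionParams,
        "effectors": EffectorParams,
    }
    known_top = set(sections) | {"seed", "outdir", "stages"}
    unknown = set(raw) - known_top
    if unknown:
        raise PipelineConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict = {k: raw[k] for k in ("seed", "outdir") if k in raw}
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    for name, cls in sections.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name], name)
    return PipelineConfig(**kwargs)


def _closure(stages) -> list[str]:
    wanted: set[str] = set()

    def add(stage: str) -> None:
        for dep in _STAGE_DEPS[stage]:
            add(dep)
        wanted.add(stage)

    for s in stages:
        add(s)
    return [s for s in ALL_STAGES if s in wanted]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig, force: bool = False) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the manifest dict. Any stage error propagates with the failing
    stage named.
    """
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    stages = _closure(config.stages)
    written: list[Path] = []
    state: dict = {}

    for stage in stages:
        try:
            _STAGE_FN[stage](config, state, outdir, written)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": stages,
        "parameters": dataclasses.asdict(config),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_io(config: PipelineConfig, state: dict, outdir: Path, written: list[Path]) -> None:
    syn = dataclasses.replace(config.synthetic, seed=config.seed)
    dataset: SyntheticDataset = simulate_dataset(syn)
    fixdir = outdir / "fixtures"
    write_fixtures(dataset, fixdir, force=True)
    written.extend(sorted(p for p in fixdir.iterdir()))
    state["dataset"] = dataset
    logger.info(
        "stage=io strains=%d genome_bp=%s",
        len(dataset.genomes),
        {s: g.length for s, g in dataset.genomes.items()},
    )


def _stage_orthology(config: PipelineConfig, state: dict, outdir: Path, written: list[Path]) -> None:
    ds: SyntheticDataset = state["dataset"]
    params = SearchParams(k=config.orthology.k, report_max=config.orthology.report_max)
    strains = sorted(ds.proteins)
    maps = []
    for a in strains:
        for b in strains:
            if a == b:
                continue
            hits = internal_similarity_search(
                ds.proteins[a], ds.proteins[b], params, query_strain=a, subject_strain=b
            )
            maps.append(best_match(hits, config.orthology.e_cutoff))
    matrix = build_families(maps, {s: sorted(ds.proteins[s]) for s in strains}, config.orthology.mode)
    state["matrix"] = matrix
    d = outdir / "orthology"
    d.mkdir(exist_ok=True)
    matrix.to_gene_frame().to_csv(d / "presence_absence.tsv", sep="\t", index_label="family_id")
    matrix.to_binary_frame().to_csv(d / "presence_binary.tsv", sep="\t", index_label="family_id")
    family_stats(matrix).to_csv(d / "family_stats.tsv", sep="\t", index=False)
    written.extend([d / "presence_absence.tsv", d / "presence_binary.tsv", d / "family_stats.tsv"])
    logger.info("stage=orthology families=%d", len(matrix.families))


def _stage_pangenome(config: PipelineConfig, state: dict, outdir: Path, written: list[Path]) -> None:
    matrix = state["matrix"]
    d = outdir / "pangenome"
    d.mkdir(exist_ok=True)
    reports = [ps.core_families(matrix), ps.pan_families(matrix)]
    reports += [ps.unique_families(matrix, s) for s in matrix.strains]
    with open(d / "sets.tsv", "w") as fh:
        fh.write("label\tn_families\t" + "\t".join(f"genes_{s}" for s in matrix.strains) + "\n")
        for r in reports:
            genes = "\t".join(str(r.genes_per_strain.get(s, 0)) for s in matrix.strains)
            fh.write(f"{r.label}\t{r.n_families}\t{genes}\n")
    venn = ps.venn_partition(matrix)
    venn_json = {
        "+".join(sorted(pattern)): count for pattern, count in sorted(venn.items(), key=lambda x: sorted(x[0]))
    }
    (d / "venn.json").write_text(json.dumps(venn_json, indent=1, sort_keys=True))
    with open(d / "shared_proportions.tsv", "w") as fh:
        fh.write("strain\t" + "\t".join(matrix.strains) + "\n")
        for a in matrix.strains:
            row = [f"{ps.shared_proportion(matrix, a, b):.4f}" for b in matrix.strains]
            fh.write(a + "\t" + "\t".join(row) + "\n")
    written.extend([d / "sets.tsv", d / "venn.json", d / "shared_proportions.tsv"])
    logger.info(
        "stage=pangenome core=%d pan=%d", reports[0].n_families, reports[1].n_families
    )


def _stage_rep(config: PipelineConfig, state: dict, outdir: Path, written: list[Path]) -> None:
    ds: SyntheticDataset = state["dataset"]
    p = config.rep
    d = outdir / "rep"
    d.mkdir(exist_ok=True)
    all_occurrences: dict[str, dict[str, list[rl.RepOccurrence]]] = {}
    families_per_strain: dict[str, list[rl.RepFamily]] = {}
    for strain, genome in sorted(ds.genomes.items()):
        families = rl.mine_repeat_families(genome, p.min_len, p.min_count)
        occ_by_family = {}
        for fam in families:
            occs = rl.scan_consensus(genome, fam, p.min_identity)
            occs = rl.annotate_genic_context(occs, genome.features)
            occ_by_family[fam.family_id] = occs
            fam.total_occurrences[strain] = len(occs)
        rl.filter_primary_families(
            families, occ_by_family, p.primary_min_total, p.primary_intergenic_only
        )
        families_per_strain[strain] = families
        all_occurrences[strain] = occ_by_family

    with open(d / "families.tsv", "w") as fh:
        fh.write(
            "strain\tfamily_id\tconsensus\tlength\tcopies\tintergenic_copies\t"
            "primary\tarm_length\tarm_mismatches\n"
        )
        for strain in sorted(families_per_strain):
            for fam in families_per_strain[strain]:
                occs = all_occurrences[strain][fam.family_id]
                arms = fam.palindrome_arms
                fh.write(
                    f"{strain}\t{fam.family_id}\t{fam.consensus}\t{len(fam.consensus)}\t"
                    f"{len(occs)}\t{sum(bool(o.intergenic) for o in occs)}\t"
                    f"{int(strain in fam.primary_strains)}\t"
                    f"{arms.arm_length if arms else 0}\t{arms.mismatches if arms else 0}\n"
                )
    written.append(d / "families.tsv")

    with open(d / "occurrences.tsv", "w") as fh:
        fh.write("strain\tfamily_id\tstart\tend\tstrand\tidentity\tintergenic\n")
        for strain in sorted(all_occurrences):
            for fam_id in sorted(all_occurrences[strain]):
                for o in all_occurrences[strain][fam_id]:
                    fh.write(
                        f"{strain}\t{fam_id}\t{o.start}\t{o.end}\t{o.strand}\t"
                        f"{o.identity:.4f}\t{int(bool(o.intergenic))}\n"
                    )
    written.append(d / "occurrences.tsv")

    deserts = []
    spacing_rows = []
    rayt_rows = []
    for strain, genome in sorted(ds.genomes.items()):
        union_occs = [o for occs in all_occurrences[strain].values() for o in occs]
        for fam in families_per_strain[strain]:
            occs = all_occurrences[strain][fam.family_id]
            deserts += rl.find_rep_deserts(
                occs, genome.length, p.desert_min_len, p.desert_gap_mode, strain
            )
            pairs, hist, mode = rl.find_rep_pairs(occs, p.max_center_sep)
            for dist in sorted(hist):
                spacing_rows.append((strain, fam.family_id, dist, hist[dist], mode))
        rayts = [f for f in genome.features if f.product_class == "RAYT"]
        flank = rl.rayt_rep_flanking(rayts, union_occs, p.rayt_window)
        for locus in sorted(flank):
            ok, up, down = flank[locus]
            rayt_rows.append((strain, locus, int(ok), up, down))

    write_bed(deserts, d / "deserts.bed")
    written.append(d / "deserts.bed")
    with open(d / "spacing_histogram.tsv", "w") as fh:
        fh.write("strain\tfamily_id\tcenter_distance\tcount\tmode\n")
        for row in spacing_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    written.append(d / "spacing_histogram.tsv")
    with open(d / "rayt_flanking.tsv", "w") as fh:
        fh.write("strain\tlocus_tag\tflanked\tupstream_dist\tdownstream_dist\n")
        for row in rayt_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    written.append(d / "rayt_flanking.tsv")
    state["rep_families"] = families_per_strain
    state["rep_occurrences"] = all_occurrences
    logger.info(
        "stage=rep families=%s deserts=%d",
        {s: len(f) for s, f in families_per_strain.items()},
        len(deserts),
    )


def _stage_composition(config: PipelineConfig, state: dict, outdir: Path, written: list[Path]) -> None:
    ds: SyntheticDataset = state["dataset"]
    p = config.composition
    d = outdir / "composition"
    d.mkdir(exist_ok=True)
    regions_all = []
    for strain, genome in sorted(ds.genomes.items()):
        bg = ca.trinucleotide_background(genome)
        profiles = ca.window_profiles(genome, p.window, p.step)
        scores = [ca.atypicality_score(pr, bg) for pr in profiles]
        skews = ca.gc_skew(genome, p.window, p.step)
        with open(d / f"windows.{strain}.tsv", "w") as fh:
            fh.write("start\tend\tatypicality\tgc_skew\n")
            for pr, sc, (_, _, sk) in zip(profiles, scores, skews):
                fh.write(f"{pr.window_start}\t{pr.window_end}\t{sc:.6f}\t{sk:.6f}\n")
        written.append(d / f"windows.{strain}.tsv")
        regions_all += ca.call_atypical_regions(
            profiles, scores, p.percentile, step=p.step, threshold=p.threshold
        )
    write_bed(regions_all, d / "atypical.bed")
    written.append(d / "atypical.bed")
    state["atypical"] = regions_all
    logger.info("stage=composition regions=%d", len(regions_all))


def _stage_effectors(config: PipelineConfig, state: dict, outdir: Path, written: list[Path]) -> None:
    ds: SyntheticDataset = state["dataset"]
    p = config.effectors
    d = outdir / "effectors"
    d.mkdir(exist_ok=True)
    if p.pwm_path:
        pwm = es.read_pwm(p.pwm_path)
    else:
        pwm = es.pwm_from_motif(ds.config.effector_spec.motif)
    max_score = float(np.log2(pwm.max(axis=0) / 0.25).sum())
    threshold = p.score_threshold_frac * max_score
    frames = []
    candidates = {}
    for strain, genome in sorted(ds.genomes.items()):
        cands, audit = es.screen_effectors(
            genome, pwm=pwm, upstream_window=p.upstream_window, score_threshold=threshold
        )
        audit.insert(0, "strain", strain)
        frames.append(audit)
        candidates[strain] = cands
    import pandas as pd

    full = pd.concat(frames, ignore_index=True)
    full.to_csv(d / "audit.tsv", sep="\t", index=False)
    full[full["overall_pass"] == True].to_csv(d / "candidates.tsv", sep="\t", index=False)  # noqa: E712
    written.extend([d / "audit.tsv", d / "candidates.tsv"])
    state["effector_candidates"] = candidates
    logger.info(
        "stage=effectors candidates=%s", {s: len(c) for s, c in candidates.items()}
    )


_STAGE_FN = {
    "io": _stage_io,
    "orthology": _stage_orthology,
    "pangenome": _stage_pangenome,
    "rep": _stage_rep,
    "composition": _stage_composition,
    "effectors": _stage_effectors,
}
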