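"""Run configuration and per-sample orchestration.

A run is described by a small YAML file: reference paths, a working
directory, a list of samples (each with an alignment against the joint
reference, or a FASTQ pair still to be aligned externally), and the
tunable thresholds.  Samples are processed independently — a failure in
one is isolated into its report section — and all results are collected
into one joint HTML report.

Alignment itself is an external step: for FASTQ-only samples the exact
``bwa mem`` recipe against the joint reference is printed and the sample
is skipped until an alignment file is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import chimera_scan, coverage_report, discordant_scan, tis_caller
from .alignment_io import (
    ConfigError,
    ReferenceSet,
    alignment_references,
    build_joint_reference,
    read_construct_bed,
    stream_alignments,
)
from .coverage_report import ReportBundle

logger = logging.getLogger("tishunt")

BWA_RECIPE = (
    "# external alignment recipe (minimum output alignment score 30):\n"
    "bwa index {joint}\n"
    "bwa mem -T 30 {joint} {fq1} {fq2} | samtools sort -o {out_bam} -\n"
    "samtools index {out_bam}\n"
)

EXIT_OK = 0
EXIT_DATA_ERROR = 1
EXIT_CONFIG_ERROR = 2


@dataclass
class SampleSpec:
    name: str
    alignment: Optional[Path] = None  # SAM/BAM over the joint reference
    fastq1: Optional[Path] = None
    fastq2: Optional[Path] = None


@dataclass
class RunConfig:
    host_fasta: Path
    construct_fasta: Path
    construct_bed: Path
    workdir: Path
    samples: list[SampleSpec]
    min_mapq: int = chimera_scan.DEFAULT_MIN_MAPQ
    min_clip: int = chimera_scan.DEFAULT_MIN_CLIP
    discordant_window: int = tis_caller.DEFAULT_DISCORDANT_WINDOW
    collapse_window: int = tis_caller.DEFAULT_COLLAPSE_WINDOW
    bin_size: int = coverage_report.DEFAULT_BIN_SIZE
    min_score: float = 0.0
    threads: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.min_mapq <= 60):
            raise ConfigError(f"min_mapq {self.min_mapq} outside [0, 60]")
        for name in ("discordant_window", "collapse_window", "bin_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


_REQUIRED_KEYS = ("host_fasta", "construct_fasta", "construct_bed", "workdir", "samples")
_KNOWN_KEYS = set(_REQUIRED_KEYS) | {
    "min_mapq",
    "min_clip",
    "discordant_window",
    "collapse_window",
    "bin_size",
    "min_score",
    "threads",
}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a run configuration file.

    All missing required keys are reported at once; unknown keys are
    warned about but tolerated; referenced paths must exist.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a key/value mapping")
    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise ConfigError(f"{path}: missing required keys: {', '.join(missing)}")
    for key in raw:
        if key not in _KNOWN_KEYS:
            logger.warning("%s: unknown configuration key %r ignored", path, key)
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    samples: list[SampleSpec] = []
    raw_samples = raw["samples"]
    if not isinstance(raw_samples, list) or not raw_samples:
        raise ConfigError(f"{path}: 'samples' must be a non-empty list")
    for i, entry in enumerate(raw_samples):
        if not isinstance(entry, dict) or "name" not in entry:
            raise ConfigError(f"{path}: sample #{i + 1} needs a 'name'")
        spec = SampleSpec(
            name=str(entry["name"]),
            alignment=resolve(entry["alignment"]) if entry.get("alignment") else None,
            fastq1=resolve(entry["fastq1"]) if entry.get("fastq1") else None,
            fastq2=resolve(entry["fastq2"]) if entry.get("fastq2") else None,
        )
        if spec.alignment is None and spec.fastq1 is None:
            raise ConfigError(
                f"{path}: sample {spec.name!r} needs 'alignment' or a FASTQ pair"
            )
        samples.append(spec)
    cfg = RunConfig(
        host_fasta=resolve(raw["host_fasta"]),
        construct_fasta=resolve(raw["construct_fasta"]),
        construct_bed=resolve(raw["construct_bed"]),
        workdir=resolve(str(raw["workdir"])),
        samples=samples,
        **{k: raw[k] for k in _KNOWN_KEYS - set(_REQUIRED_KEYS) if k in raw},
    )
    missing_paths = [
        str(p)
        for p in (cfg.host_fasta, cfg.construct_fasta, cfg.construct_bed)
        if not p.exists()
    ]
    for s in cfg.samples:
        for p in (s.alignment, s.fastq1, s.fastq2):
            if p is not None and not p.exists():
                missing_paths.append(str(p))
    if missing_paths:
        raise ConfigError(f"{path}: referenced files not found: {', '.join(missing_paths)}")
    return cfg


def build_references(cfg: RunConfig) -> ReferenceSet:
    cfg.workdir.mkdir(parents=True, exist_ok=True)
    joint = cfg.workdir / "joint_reference.fa"
    return build_joint_reference(cfg.host_fasta, cfg.construct_fasta, joint)


def run_sample(cfg: RunConfig, sample: SampleSpec, refset: ReferenceSet | None = None) -> ReportBundle:
    """Run the full detection pipeline for one sample.

    Streams the alignments three times (chimeric scan, discordant scan,
    coverage) so memory stays proportional to the evidence, not the
    sample.  Artifacts are written under ``workdir`` keyed by sample and
    candidate rank.
    """
    if refset is None:
        refset = build_references(cfg)
    annotation = read_construct_bed(cfg.construct_bed, refset.construct_length)
    wd = cfg.workdir
    wd.mkdir(parents=True, exist_ok=True)
    if sample.alignment is None:
        joint = wd / "joint_reference.fa"
        recipe = BWA_RECIPE.format(
            joint=joint, fq1=sample.fastq1, fq2=sample.fastq2,
            out_bam=wd / f"{sample.name}.bam",
        )
        logger.warning("sample %s: no alignment file; align externally first:\n%s", sample.name, recipe)
        return ReportBundle(
            sample=sample.name,
            candidates=[],
            error="no alignment provided; external alignment required (see log for the recipe)",
        )
    refs_in_header = set(alignment_references(sample.alignment))
    if refset.construct_name not in refs_in_header:
        raise ConfigError(
            f"sample {sample.name}: alignment header lacks the construct sequence "
            f"{refset.construct_name!r} — aligned to the wrong reference?"
        )

    chimeric = chimera_scan.scan_chimeric(
        stream_alignments(sample.alignment),
        refset,
        min_mapq=cfg.min_mapq,
        min_clip=cfg.min_clip,
        out_tsv=wd / f"{sample.name}_chimeric.tsv",
    )
    discordant = discordant_scan.scan_discordant(
        stream_alignments(sample.alignment),
        refset,
        min_mapq=cfg.min_mapq,
        out_sam=wd / f"{sample.name}_discordant.sam",
    )
    candidates = tis_caller.call_tis(
        chimeric,
        discordant,
        refset,
        collapse_window=cfg.collapse_window,
        discordant_window=cfg.discordant_window,
        min_score=cfg.min_score,
    )
    tis_caller.write_candidates_tsv(candidates, wd / f"{sample.name}_candidates.tsv")

    records = list(stream_alignments(sample.alignment))
    lengths = refset.lengths()
    host_cov = coverage_report.mean_coverage(
        records, {n: lengths[n] for n in refset.host_names}
    )
    con_cov = coverage_report.mean_coverage(
        records, {refset.construct_name: refset.construct_length}
    )
    bundle = ReportBundle(
        sample=sample.name,
        candidates=candidates,
        annotation=annotation,
        host_coverage=host_cov,
        construct_coverage=con_cov,
    )
    bundle.artifacts["chimeric_tsv"] = wd / f"{sample.name}_chimeric.tsv"
    bundle.artifacts["discordant_sam"] = wd / f"{sample.name}_discordant.sam"
    bundle.artifacts["candidates_tsv"] = wd / f"{sample.name}_candidates.tsv"
    for rank, cand in enumerate(candidates, 1):
        pad = cfg.discordant_window
        lo = max(1, cand.region_start - pad)
        hi = min(lengths[cand.chrom], cand.region_end + pad)
        host_track = coverage_report.depth_track(
            records, cand.chrom, lo, hi, cfg.bin_size, chrom_length=lengths[cand.chrom]
        )
        con_track = coverage_report.depth_track(
            records, refset.construct_name, 1, refset.construct_length, cfg.bin_size
        )
        bundle.tracks[rank] = (host_track, con_track)
        stem = f"{sample.name}_{rank}"
        kary, hist = coverage_report.emit_circular_data(
            cand, host_track, con_track, annotation, chimeric, discordant,
            wd / f"{stem}_karyotype.tsv", wd / f"{stem}_histogram.tsv",
            construct_name=refset.construct_name, window=cfg.discordant_window,
        )
        png = coverage_report.render_circular(
            kary, hist, wd / f"{stem}_circular.png",
            title=f"{sample.name}: {cand.chrom}:{cand.region_start:,}-{cand.region_end:,}",
        )
        bat = coverage_report.emit_igv_batch(
            cand, sample.alignment, wd / f"{stem}_igv.bat",
            genome_path=wd / "joint_reference.fa", snapshot_dir=wd,
        )
        bundle.artifacts[f"karyotype_{rank}"] = kary
        bundle.artifacts[f"histogram_{rank}"] = hist
        bundle.artifacts[f"circular_{rank}"] = png
        bundle.artifacts[f"igv_{rank}"] = bat
    return bundle


def run_all(cfg: RunConfig) -> tuple[list[ReportBundle], int]:
    """Process every sample independently and write the joint report.

    Per-sample failures become error sections rather than aborting the
    run; the exit code is nonzero only when every sample fails.
    """
    refset = build_references(cfg)
    bundles: list[ReportBundle] = []
    n_failed = 0
    for sample in cfg.samples:
        try:
            bundles.append(run_sample(cfg, sample, refset))
        except Exception as exc:  # isolate sibling samples
            logger.error("sample %s failed: %s", sample.name, exc)
            bundles.append(ReportBundle(sample=sample.name, candidates=[], error=str(exc)))
            n_failed += 1
    coverage_report.render_html(bundles, cfg.workdir / "report.html")
    code = EXIT_DATA_ERROR if n_failed == len(cfg.samples) else EXIT_OK
    return bundles, code
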