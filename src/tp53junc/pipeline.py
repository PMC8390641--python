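"""End-to-end orchestration: count -> fractions -> classify -> compare.

Every stage exchanges plain TSV tables; a JSON run manifest records the tool
version, a hash of the effective configuration, input checksums and per-stage
row counts.  Re-running with identical inputs and configuration yields an
identical configuration hash and byte-identical stage tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    ClassificationThresholds,
    build_cohorts,
    build_pairs,
    classify_samples,
    read_annotations_tsv,
    statuses_to_frame,
)
from .counting import (
    CountingParams,
    count_junction_reads,
    read_counts_tsv,
    write_audit_tsv,
    write_counts_tsv,
)
from .errors import ConfigurationError, InputDataError
from .fractions import fractions_table, read_fractions_tsv, write_fractions_tsv
from .model import builtin_tp53_model, derive_junctions, load_gene_model
from .stats import group_summaries, run_comparison_suite, run_paired_suite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs.

    ``model`` is a gene-model path or the literal ``"builtin"`` (the bundled
    TP53 annotation).  Input alignments are given as ``(sample_id, path)``
    pairs; alternatively a precomputed junction-counts TSV short-circuits the
    counting stage.
    """

    annotations: str
    outdir: str
    model: str = "builtin"
    alignments: tuple[tuple[str, str], ...] = ()
    counts: str | None = None
    counting: CountingParams = field(default_factory=CountingParams)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    family_alpha: float = 0.05
    min_group_size: int = 5
    fixed_m: int | None = None
    column: str = "cterm_fraction"
    include_truncating_classes: bool = True
    paired: bool = False
    audit: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.family_alpha <= 1:
            raise ConfigurationError("family_alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        counting = CountingParams(**doc.pop("counting", {}))
        thresholds = ClassificationThresholds(**doc.pop("thresholds", {}))
        alignments = tuple(
            (str(a["sample_id"]), str(a["path"])) for a in doc.pop("alignments", [])
        )
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(doc) - known
        if extra:
            raise ConfigurationError(f"unknown config key(s): {sorted(extra)}")
        return cls(counting=counting, thresholds=thresholds, alignments=alignments, **doc)

    def to_canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["counting"] = dataclasses.asdict(self.counting)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        d["alignments"] = [list(a) for a in self.alignments]
        return d


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Pre-flight checks; returns machine-readable findings (empty = OK)."""
    findings: list[dict] = []

    def finding(code: str, message: str) -> None:
        findings.append({"code": code, "message": message})

    model_path = None
    if config.model != "builtin":
        model_path = Path(config.model)
        if not model_path.exists():
            finding("missing_model", f"gene-model file not found: {model_path}")
    try:
        transcripts = (
            builtin_tp53_model() if model_path is None else load_gene_model(model_path)
        )
        catalog = derive_junctions(transcripts)
        chrom = catalog.chrom
    except Exception as exc:  # surfaced as a finding, not a crash
        finding("bad_model", str(exc))
        chrom = None

    if config.counts is None and not config.alignments:
        finding("no_input", "neither alignments nor a counts TSV configured")
    if config.counts is not None and not Path(config.counts).exists():
        finding("missing_counts", f"counts TSV not found: {config.counts}")
    for sample_id, path in config.alignments:
        p = Path(path)
        if not p.exists():
            finding("missing_alignments", f"{sample_id}: alignment file not found: {p}")
            continue
        if chrom is not None:
            import pysam

            try:
                with pysam.AlignmentFile(str(p)) as af:
                    if chrom not in af.references:
                        finding(
                            "chrom_mismatch",
                            f"{sample_id}: sequence {chrom!r} absent from alignment header "
                            f"(header has {list(af.references)[:5]}...)",
                        )
            except Exception as exc:
                finding("bad_alignments", f"{sample_id}: {exc}")

    ann = Path(config.annotations)
    if not ann.exists():
        finding("missing_annotations", f"annotation TSV not found: {ann}")
    else:
        try:
            read_annotations_tsv(ann)
        except Exception as exc:
            finding("bad_annotations", str(exc))

    if config.thresholds.min_expression < 0:
        finding("bad_thresholds", "min_expression must be non-negative")
    return findings


@dataclass
class PipelineResult:
    outdir: Path
    tables: dict[str, Path]
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order, writing one TSV per stage plus a manifest.

    Fails before any stage runs when pre-flight validation finds problems.
    """
    findings = validate_inputs(config)
    if findings:
        raise ConfigurationError(
            "pre-flight validation failed: "
            + "; ".join(f"[{f['code']}] {f['message']}" for f in findings)
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, Path] = {}
    row_counts: dict[str, int] = {}
    checksums: dict[str, str] = {}

    def stage(name):
        logger.info("stage: %s", name)

    # --- gene model / catalog
    stage("catalog")
    transcripts = (
        builtin_tp53_model() if config.model == "builtin" else load_gene_model(config.model)
    )
    if config.model != "builtin":
        checksums[config.model] = _sha256_file(Path(config.model))
    catalog = derive_junctions(transcripts)
    tables["catalog"] = outdir / "catalog.tsv"
    catalog.to_tsv(tables["catalog"])
    row_counts["catalog"] = len(catalog.junctions)

    # --- counting
    stage("count")
    if config.counts is not None:
        checksums[config.counts] = _sha256_file(Path(config.counts))
        counts_list = read_counts_tsv(config.counts)
    else:
        counts_list = []
        audit_all = []
        for sample_id, path in config.alignments:
            checksums[path] = _sha256_file(Path(path))
            if config.audit:
                c, audit = count_junction_reads(
                    path, catalog, config.counting, sample_id, collect_audit=True
                )
                audit_all.extend(audit)
            else:
                c = count_junction_reads(path, catalog, config.counting, sample_id)
            counts_list.append(c)
        if config.audit:
            tables["audit"] = outdir / "audit.tsv"
            write_audit_tsv(audit_all, tables["audit"])
            row_counts["audit"] = len(audit_all)
    counts_list.sort(key=lambda c: c.sample_id)
    tables["counts"] = outdir / "counts.tsv"
    write_counts_tsv(counts_list, tables["counts"])
    row_counts["counts"] = sum(len(c.counts) for c in counts_list)

    # --- fractions
    stage("fractions")
    frac = fractions_table(counts_list, catalog)
    tables["fractions"] = outdir / "fractions.tsv"
    write_fractions_tsv(frac, tables["fractions"])
    row_counts["fractions"] = len(frac)

    # --- classification
    stage("classify")
    checksums[config.annotations] = _sha256_file(Path(config.annotations))
    samples = read_annotations_tsv(config.annotations)
    statuses = classify_samples(samples, config.thresholds)
    tables["statuses"] = outdir / "statuses.tsv"
    statuses_to_frame(statuses).to_csv(tables["statuses"], sep="\t", index=False)
    row_counts["statuses"] = len(statuses)

    # --- summaries + comparisons
    stage("compare")
    from .cohort import annotations_to_frame

    ann_frame = annotations_to_frame(samples)
    summaries = group_summaries(frac, ann_frame, by="stratum", column=config.column)
    tables["summaries"] = outdir / "summaries.tsv"
    summaries.to_csv(tables["summaries"], sep="\t", index=False)
    row_counts["summaries"] = len(summaries)

    if config.paired:
        pairs = build_pairs(samples, statuses, status_filter="WT")
        comparisons, correction = run_paired_suite(
            frac, pairs, config.family_alpha, fixed_m=config.fixed_m
        )
    else:
        cohorts = build_cohorts(samples, statuses, config.min_group_size)
        comparisons, correction = run_comparison_suite(
            frac,
            statuses,
            cohorts,
            family_alpha=config.family_alpha,
            column=config.column,
            include_truncating_classes=config.include_truncating_classes,
            fixed_m=config.fixed_m,
        )
    tables["comparisons"] = outdir / "comparisons.tsv"
    comparisons.to_csv(tables["comparisons"], sep="\t", index=False)
    row_counts["comparisons"] = len(comparisons)

    # --- manifest
    config_hash = hashlib.sha256(
        json.dumps(config.to_canonical_dict(), sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "tool": "tp53junc",
        "version": __version__,
        "config_hash": config_hash,
        "input_checksums": checksums,
        "row_counts": row_counts,
        "adjusted_alpha": None if correction is None else correction.adjusted_alpha,
        "m_tests": None if correction is None else correction.m_tests,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(outdir=outdir, tables=tables, manifest=manifest)
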