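"""Strict junction-read classification and counting from SAM/BAM alignments.

A read supports a junction only when its spliced alignment skips the intron
with block boundaries *exactly* at the annotated donor/acceptor pair, carries
at least ``min_flank`` aligned bases in the blocks on both sides of the
breakpoint, has no mismatches or indels (aligner edit distance 0), and has at
most half of its bases soft-clipped.  Soft-clipped bases are not mismatches;
hard-clipped bases are absent from the stored sequence and never enter the
soft-clip denominator.

Each mate of a pair is evaluated independently.  A read with several skips is
matched against the catalog once per skip, so it may support more than one
junction but never the same junction twice.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .errors import ConfigurationError
from .model import Junction, JunctionCatalog

logger = logging.getLogger(__name__)

# reject reasons, in the fixed audit order
REJECT_NO_SPLICE = "no_splice"
REJECT_BREAKPOINT = "breakpoint_mismatch"
REJECT_SOFTCLIP = "excess_softclip"
REJECT_MISMATCH = "has_mismatch"
REJECT_INDEL = "has_indel"
REJECT_FLANK = "short_flank"
REJECT_SECONDARY = "secondary"
REJECT_UNMAPPED = "unmapped"

_MD_DELETION = re.compile(r"\^[A-Z]+")


@dataclass(frozen=True)
class CountingParams:
    """Knobs of the junction-read rule.

    min_flank
        aligned bases required on each side of the breakpoint (default 10).
    max_softclip_fraction
        maximum soft-clipped fraction of the stored read length; the boundary
        is inclusive, i.e. exactly half the read soft-clipped still passes.
    require_zero_mismatches
        demand aligner edit distance 0 and no indel CIGAR operators.
    count_duplicates / count_secondary
        whether duplicate-flagged / secondary alignments are evaluated;
        alignments are consumed as provided, so duplicates count by default.
    nm_tag_policy
        "strict": a record without an NM tag cannot prove zero mismatches and
        is rejected; "permissive": fall back to the MD tag, rejecting only
        when neither tag is present.
    """

    min_flank: int = 10
    max_softclip_fraction: float = 0.5
    require_zero_mismatches: bool = True
    count_duplicates: bool = True
    count_secondary: bool = False
    nm_tag_policy: str = "strict"

    def __post_init__(self) -> None:
        if self.min_flank < 1:
            raise ConfigurationError("min_flank must be >= 1")
        if not 0.0 <= self.max_softclip_fraction <= 1.0:
            raise ConfigurationError("max_softclip_fraction must be in [0, 1]")
        if self.nm_tag_policy not in ("strict", "permissive"):
            raise ConfigurationError(f"unknown nm_tag_policy {self.nm_tag_policy!r}")


@dataclass(frozen=True)
class ReadVerdict:
    read_id: str
    junction_label: str | None
    accepted: bool
    reject_reason: str | None = None

    def __post_init__(self) -> None:
        assert not (self.accepted and self.reject_reason is not None)


@dataclass(frozen=True)
class AlignedBlock:
    """Maximal run of reference-aligned bases, split at N (intron) operators."""

    ref_start: int  # 1-based inclusive
    ref_end: int
    aligned_bases: int  # read bases aligned within the block (M/=/X)


@dataclass(frozen=True)
class BlockInfo:
    blocks: tuple[AlignedBlock, ...]
    softclip_total: int
    has_indel: bool
    nm: int | None

    @property
    def skips(self) -> tuple[tuple[int, int, int], ...]:
        """(donor_end, acceptor_start, left_block_index) per skipped region."""
        return tuple(
            (a.ref_end, b.ref_start, i)
            for i, (a, b) in enumerate(zip(self.blocks, self.blocks[1:]))
        )


def read_blocks(rec: pysam.AlignedSegment) -> BlockInfo:
    """Decompose a mapped record's CIGAR into aligned genomic blocks.

    Insertions and deletions stay within a block (only N splits blocks) but
    are flagged as indel evidence; the NM tag is carried along when present.
    """
    if rec.cigartuples is None:
        raise ValueError(f"record {rec.query_name} has no CIGAR")
    ref = rec.reference_start + 1  # to 1-based
    blocks: list[AlignedBlock] = []
    block_start: int | None = None
    aligned = 0
    softclip = 0
    has_indel = False
    for op, length in rec.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            if block_start is None:
                block_start = ref
            ref += length
            aligned += length
        elif op == 1:  # I
            has_indel = True
        elif op == 2:  # D
            has_indel = True
            if block_start is None:
                block_start = ref
            ref += length
        elif op == 3:  # N
            if block_start is not None:
                blocks.append(AlignedBlock(block_start, ref - 1, aligned))
                block_start, aligned = None, 0
            ref += length
        elif op == 4:  # S
            softclip += length
        # H (5) and P (6) touch neither read sequence nor reference span
    if block_start is not None:
        blocks.append(AlignedBlock(block_start, ref - 1, aligned))
    nm = rec.get_tag("NM") if rec.has_tag("NM") else None
    return BlockInfo(tuple(blocks), softclip, has_indel, nm)


def _mismatch_reason(info: BlockInfo, rec: pysam.AlignedSegment, params: CountingParams) -> str | None:
    if not params.require_zero_mismatches:
        return None
    if info.has_indel:
        return REJECT_INDEL
    nm = info.nm
    if nm is None:
        if params.nm_tag_policy == "permissive" and rec.has_tag("MD"):
            # after stripping deletion runs (^ACGT...), remaining letters are mismatches
            nm = sum(c.isalpha() for c in _MD_DELETION.sub("", str(rec.get_tag("MD"))))
        else:
            return REJECT_MISMATCH  # cannot establish zero mismatches
    return REJECT_MISMATCH if nm > 0 else None


def _softclip_reason(info: BlockInfo, rec: pysam.AlignedSegment, params: CountingParams) -> str | None:
    seq_len = rec.query_length or (sum(b.aligned_bases for b in info.blocks) + info.softclip_total)
    if info.softclip_total > params.max_softclip_fraction * seq_len:
        return REJECT_SOFTCLIP
    return None


def classify_read(
    rec: pysam.AlignedSegment,
    junction: Junction,
    params: CountingParams | None = None,
) -> ReadVerdict:
    """Apply the junction-read rule to one record against one junction.

    The first failed criterion, in the fixed order no_splice ->
    breakpoint_mismatch -> excess_softclip -> has_mismatch/has_indel ->
    short_flank, becomes the reject reason.
    """
    params = params or CountingParams()
    name = rec.query_name or ""
    if rec.is_unmapped or rec.cigartuples is None:
        return ReadVerdict(name, junction.label, False, REJECT_UNMAPPED)
    if rec.is_secondary or rec.is_supplementary:
        if not params.count_secondary:
            return ReadVerdict(name, junction.label, False, REJECT_SECONDARY)
    info = read_blocks(rec)
    if not info.skips:
        return ReadVerdict(name, junction.label, False, REJECT_NO_SPLICE)
    match = None
    if rec.reference_name == junction.chrom:
        for donor, acceptor, i in info.skips:
            if donor == junction.donor_end and acceptor == junction.acceptor_start:
                match = i
                break
    if match is None:
        return ReadVerdict(name, junction.label, False, REJECT_BREAKPOINT)
    reason = (
        _softclip_reason(info, rec, params)
        or _mismatch_reason(info, rec, params)
        or _flank_reason(info, match, params)
    )
    if reason:
        return ReadVerdict(name, junction.label, False, reason)
    return ReadVerdict(name, junction.label, True)


def _flank_reason(info: BlockInfo, skip_index: int, params: CountingParams) -> str | None:
    left = info.blocks[skip_index].aligned_bases
    right = info.blocks[skip_index + 1].aligned_bases
    if left < params.min_flank or right < params.min_flank:
        return REJECT_FLANK
    return None


@dataclass
class JunctionCounts:
    """Per-sample junction-read counts over a catalog."""

    sample_id: str
    counts: dict[str, int]
    total_reads_scanned: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative junction count")


def _iter_records(af: pysam.AlignmentFile, chrom: str) -> Iterator[pysam.AlignedSegment]:
    if af.has_index():
        try:
            yield from af.fetch(chrom)
            return
        except ValueError:
            pass
    yield from af.fetch(until_eof=True)


def count_junction_reads(
    source: str | Path | pysam.AlignmentFile,
    catalog: JunctionCatalog,
    params: CountingParams | None = None,
    sample_id: str | None = None,
    collect_audit: bool = False,
) -> JunctionCounts | tuple[JunctionCounts, list[ReadVerdict]]:
    """Count qualifying junction reads per catalog junction in one alignment file.

    Every primary mapped record is decomposed once; each of its skipped
    regions is matched against the catalog, and the read-level criteria
    (soft-clip budget, zero mismatches) plus the per-skip flank criterion
    decide acceptance.  A read increments each matched junction at most once.
    With ``collect_audit`` the verdict list covers every spliced read that
    touched the catalog region of interest (matched junctions, plus one
    ``breakpoint_mismatch`` entry for spliced reads matching nothing).
    """
    params = params or CountingParams()
    own = False
    if isinstance(source, (str, Path)):
        af = pysam.AlignmentFile(str(source))
        own = True
        if sample_id is None:
            sample_id = Path(source).stem
    else:
        af = source
    sample_id = sample_id or "sample"

    counts = {lab: 0 for lab in catalog.labels()}
    audit: list[ReadVerdict] = []
    total = 0
    chrom = catalog.chrom
    try:
        if chrom not in af.references:
            logger.warning(
                "sequence %r absent from alignment header (%s); returning zero counts",
                chrom, sample_id,
            )
            return (JunctionCounts(sample_id, counts, 0), audit) if collect_audit else JunctionCounts(sample_id, counts, 0)
        by_coords = catalog.by_coords
        for rec in _iter_records(af, chrom):
            if rec.is_unmapped:
                continue
            if rec.is_supplementary:
                continue
            if rec.is_secondary and not params.count_secondary:
                continue
            if rec.is_duplicate and not params.count_duplicates:
                continue
            total += 1
            if rec.cigartuples is None:
                if collect_audit:
                    audit.append(ReadVerdict(rec.query_name or "", None, False, REJECT_UNMAPPED))
                continue
            if rec.reference_name != chrom:
                continue
            info = read_blocks(rec)
            skips = info.skips
            if not skips:
                continue
            matched = [
                (by_coords[(chrom, d, a)], i)
                for d, a, i in skips
                if (chrom, d, a) in by_coords
            ]
            if not matched:
                if collect_audit:
                    audit.append(
                        ReadVerdict(rec.query_name or "", None, False, REJECT_BREAKPOINT)
                    )
                continue
            read_reason = _softclip_reason(info, rec, params) or _mismatch_reason(info, rec, params)
            for junction, i in matched:
                reason = read_reason or _flank_reason(info, i, params)
                if reason is None:
                    counts[junction.label] += 1
                    if collect_audit:
                        audit.append(ReadVerdict(rec.query_name or "", junction.label, True))
                elif collect_audit:
                    audit.append(ReadVerdict(rec.query_name or "", junction.label, False, reason))
    finally:
        if own:
            af.close()

    result = JunctionCounts(sample_id, counts, total)
    return (result, audit) if collect_audit else result


# ---------------------------------------------------------------------------
# tabular interchange


def counts_to_frame(counts_list: Iterable[JunctionCounts]):
    import pandas as pd

    rows = [
        {"sample_id": c.sample_id, "junction_label": lab, "count": n}
        for c in counts_list
        for lab, n in sorted(c.counts.items())
    ]
    return pd.DataFrame(rows, columns=["sample_id", "junction_label", "count"])


def write_counts_tsv(counts_list: Iterable[JunctionCounts], path: str | Path) -> None:
    counts_to_frame(counts_list).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> list[JunctionCounts]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "junction_label", "count"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"{path}: counts TSV must have columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        out.append(
            JunctionCounts(
                sample_id=str(sid),
                counts={str(r.junction_label): int(r.count) for r in grp.itertuples()},
            )
        )
    return out


def write_audit_tsv(audit: Iterable[ReadVerdict], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "read_id": v.read_id,
                "junction_label": v.junction_label or "",
                "accepted": int(v.accepted),
                "reject_reason": v.reject_reason or "",
            }
            for v in audit
        ],
        columns=["read_id", "junction_label", "accepted", "reject_reason"],
    ).to_csv(path, sep="\t", index=False)
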