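"""Synthetic inputs for every pipeline stage.

Three generators, all deterministic given a seed:

* :func:`make_toy_locus` — a single-chromosome toy gene whose isoform
  topologies mirror the TP53 situation: an 11-exon main transcript, a
  C-terminal alternative inserting one extra exon between the penultimate
  main exons (two junctions absent from the main isoform), a 5'UTR
  alternative whose second-exon acceptor is shifted by exactly 3 bases, and a
  gamma-like alternative with its own inserted exon.
* :func:`simulate_alignments` — spliced single-end reads drawn from the
  transcript mixture, written as SAM, with configurable soft-clip, mismatch
  and splice-boundary-offset contamination and a per-read truth table.  The
  truth table's qualification flags are computed by a literal, standalone
  re-statement of the junction-read rule operating on the generator's own
  block lists, never on CIGAR strings, so it can serve as an independent
  oracle for the counting module.
* :func:`simulate_cohort` — per-sample junction counts drawn binomially
  around group-specific true fractions, plus annotation tables constructed so
  that status classification reproduces the intended group labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .cohort import (
    COHORT_NORMAL,
    COHORT_TUMOR,
    TRUNCATING_CLASSES,
    MutationCall,
    SampleAnnotation,
)
from .counting import JunctionCounts
from .errors import ConfigurationError
from .model import (
    JunctionCatalog,
    TranscriptModel,
    derive_junctions,
    junction_label,
    write_gene_model,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# toy locus layout (1-based genomic coordinates on a single toy chromosome)
_EXON_LENGTHS = (150, 102, 122, 279, 184, 113, 110, 137, 74, 107, 300)
_INTRON_LEN = 350
_CTERM_INTRON = 900  # intron between main exons 9 and 10, hosts the extra exons
_LOCUS_START = 1001
_CTERM_EXTRA = (80, 137)  # (offset into intron 9, length) of the beta-like exon
_GAMMA_EXTRA = (474, 102)
_UTR5_SHIFT = 3

MAIN_ID = "MAIN.1"
CTERM_ID = "CTERM_B.1"
GAMMA_ID = "GAMMA_G.1"
UTR5_ID = "UTR5_A.1"


@dataclass(frozen=True)
class ToyLocusConfig:
    seed: int = 0
    chrom: str = "toy1"
    strand: str = "+"
    include_gamma: bool = True


@dataclass(frozen=True)
class ToyLocus:
    chrom: str
    sequence: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def catalog(self) -> JunctionCatalog:
        return derive_junctions(self.transcripts)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


def _main_exon_plan() -> list[tuple[int, int]]:
    exons = []
    pos = _LOCUS_START
    for i, length in enumerate(_EXON_LENGTHS):
        exons.append((pos, pos + length - 1))
        intron = _CTERM_INTRON if i == 8 else _INTRON_LEN  # intron after exon 9
        pos += length + intron
    return exons


def make_toy_locus(config: ToyLocusConfig | None = None) -> ToyLocus:
    """Build the toy locus; byte-identical output for identical configs."""
    config = config or ToyLocusConfig()
    if config.strand not in ("+", "-"):
        raise ConfigurationError(f"bad strand {config.strand!r}")
    rng = np.random.default_rng(config.seed)
    main_exons = _main_exon_plan()
    e9_end = main_exons[8][1]
    x_start = e9_end + 1 + _CTERM_EXTRA[0]
    x = (x_start, x_start + _CTERM_EXTRA[1] - 1)
    y_start = e9_end + 1 + _GAMMA_EXTRA[0]
    y = (y_start, y_start + _GAMMA_EXTRA[1] - 1)
    utr5_exons = list(main_exons)
    s2, e2 = utr5_exons[1]
    utr5_exons[1] = (s2 + _UTR5_SHIFT, e2)

    def order(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
        ordered = sorted(intervals)
        return ordered if config.strand == "+" else ordered[::-1]

    chrom = config.chrom
    transcripts = [
        TranscriptModel.from_intervals(MAIN_ID, chrom, config.strand, order(main_exons), role="main"),
        TranscriptModel.from_intervals(
            CTERM_ID, chrom, config.strand, order(main_exons[:9] + [x] + main_exons[9:]),
            junction_role="cterm",
        ),
        TranscriptModel.from_intervals(
            UTR5_ID, chrom, config.strand, order(utr5_exons), junction_role="utr5"
        ),
    ]
    if config.include_gamma:
        transcripts.append(
            TranscriptModel.from_intervals(
                GAMMA_ID, chrom, config.strand, order(main_exons[:9] + [y] + main_exons[9:]),
                junction_role="gamma",
            )
        )
    length = main_exons[-1][1] + 400
    seq = rng.choice(_BASES, size=length).tobytes().decode()
    return ToyLocus(chrom=chrom, sequence=seq, strand=config.strand, transcripts=tuple(transcripts))


def write_locus(locus: ToyLocus, outdir: str | Path) -> dict[str, Path]:
    """Write the locus FASTA and gene-model JSON + GFF3; returns the paths."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "locus.fa"
    SeqIO.write([SeqRecord(Seq(locus.sequence), id=locus.chrom, description="")], str(fasta), "fasta")
    model_json = outdir / "model.json"
    write_gene_model(list(locus.transcripts), model_json)
    model_gff = outdir / "model.gff3"
    write_gene_model(list(locus.transcripts), model_gff)
    return {"fasta": fasta, "model_json": model_json, "model_gff3": model_gff}


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class MixtureConfig:
    """Isoform mixture and contamination settings for read simulation.

    ``proportions`` are transcript-molarity weights (must sum to 1); the
    default mixture puts the C-terminal alternative near the upper end of the
    normal-tissue range with the 5'UTR variant a couple of times lower and a
    rare gamma-like isoform.  ``read_length`` covers the short-read range of
    the emulated cohorts (48-101 bp).  ``offset_error_rate`` is the fraction
    of spliced reads whose skip boundary is shifted by one base.
    """

    proportions: Mapping[str, float] = field(
        default_factory=lambda: {MAIN_ID: 0.93, CTERM_ID: 0.04, UTR5_ID: 0.02, GAMMA_ID: 0.01}
    )
    read_length: int = 76
    n_reads: int = 10000
    softclip_rate: float = 0.0
    softclip_len_range: tuple[int, int] = (5, 40)
    mismatch_rate: float = 0.0
    offset_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 48 <= self.read_length <= 101:
            raise ConfigurationError("read_length must be in 48..101")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"proportions must sum to 1 (got {total})")
        for rate in (self.softclip_rate, self.mismatch_rate, self.offset_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("rates must be probabilities")


@dataclass(frozen=True)
class TruthRead:
    """Generator-side record of one simulated read.

    ``blocks`` are the final aligned genomic blocks after contamination;
    ``crossed`` are the labels of the source-transcript junctions the read
    spanned before contamination was applied.
    """

    read_id: str
    transcript_id: str
    blocks: tuple[tuple[int, int], ...]
    clip_left: int
    clip_right: int
    nm: int
    crossed: tuple[str, ...]

    @property
    def softclip_total(self) -> int:
        return self.clip_left + self.clip_right

    @property
    def seq_len(self) -> int:
        return self.softclip_total + sum(e - s + 1 for s, e in self.blocks)


def truth_rule_verdict(
    read: TruthRead,
    junction,
    min_flank: int = 10,
    max_softclip_fraction: float = 0.5,
) -> tuple[bool, str | None]:
    """Literal junction-read rule applied to a truth record.

    Independent of the counting module: works on the generator's block lists,
    not on CIGAR strings.  Returns (qualifies, reason-if-not).
    """
    gaps = [
        (a[1], b[0], i) for i, (a, b) in enumerate(zip(read.blocks, read.blocks[1:]))
    ]
    if not gaps:
        return False, "no_splice"
    hit = [i for d, a, i in gaps if d == junction.donor_end and a == junction.acceptor_start]
    if not hit:
        return False, "breakpoint_mismatch"
    if read.softclip_total > max_softclip_fraction * read.seq_len:
        return False, "excess_softclip"
    if read.nm > 0:
        return False, "has_mismatch"
    i = hit[0]
    left = read.blocks[i][1] - read.blocks[i][0] + 1
    right = read.blocks[i + 1][1] - read.blocks[i + 1][0] + 1
    if left < min_flank or right < min_flank:
        return False, "short_flank"
    return True, None


def truth_counts(
    truths: Sequence[TruthRead],
    catalog: JunctionCatalog,
    min_flank: int = 10,
    max_softclip_fraction: float = 0.5,
) -> dict[str, int]:
    """Oracle junction counts: the literal rule summed over the truth table."""
    counts = {lab: 0 for lab in catalog.labels()}
    by_label = catalog.by_label
    for read in truths:
        for lab in read.crossed:
            ok, _ = truth_rule_verdict(read, by_label[lab], min_flank, max_softclip_fraction)
            if ok:
                counts[lab] += 1
    return counts


def _transcript_blocks(
    exons_genomic: Sequence, offset: int, length: int
) -> list[list[int]]:
    """Genomic blocks of a read starting at 0-based ``offset`` of the
    genomic-order exon concatenation."""
    blocks: list[list[int]] = []
    remaining = length
    pos = offset
    for ex in exons_genomic:
        elen = ex.end - ex.start + 1
        if pos >= elen:
            pos -= elen
            continue
        take = min(elen - pos, remaining)
        blocks.append([ex.start + pos, ex.start + pos + take - 1])
        remaining -= take
        pos = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read extends past transcript end")
    return blocks


def simulate_alignments(
    locus: ToyLocus,
    mixture: MixtureConfig,
    sam_path: str | Path,
    truth_path: str | Path | None = None,
) -> list[TruthRead]:
    """Draw reads from the isoform mixture and write a SAM file plus truth table.

    Reads start uniformly along their source transcript; reads crossing a
    splice get an N CIGAR operator at the true boundary, except the
    ``offset_error_rate`` fraction whose boundary is shifted by one base.
    Soft-clip contamination trims terminal aligned bases into clips (so clip
    length and flank support interact realistically); mismatch contamination
    substitutes one aligned base and is reflected in the NM tag.
    """
    rng = np.random.default_rng(mixture.seed)
    catalog = locus.catalog()
    by_coords = catalog.by_coords
    tids = sorted(mixture.proportions)
    probs = np.array([mixture.proportions[t] for t in tids])
    exon_sets = {t: locus.transcript(t).exons_genomic() for t in tids}
    tlens = {t: sum(e.length for e in exon_sets[t]) for t in tids}
    L = mixture.read_length
    for t in tids:
        if probs[tids.index(t)] > 0 and tlens[t] < L:
            raise ConfigurationError(f"transcript {t} shorter than read length")

    seq = locus.sequence
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": locus.chrom, "LN": len(seq)}],
    }
    truths: list[TruthRead] = []
    choices = rng.choice(len(tids), size=mixture.n_reads, p=probs)
    sam_path = Path(sam_path)
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for i in range(mixture.n_reads):
            tid = tids[int(choices[i])]
            u = int(rng.integers(0, tlens[tid] - L + 1))
            blocks = _transcript_blocks(exon_sets[tid], u, L)
            crossed = tuple(
                by_coords[(locus.chrom, a[1], b[0])].label
                for a, b in zip(blocks, blocks[1:])
                if (locus.chrom, a[1], b[0]) in by_coords
            )

            # splice-boundary offset contamination
            if len(blocks) > 1 and rng.random() < mixture.offset_error_rate:
                k = int(rng.integers(0, len(blocks) - 1))
                right_ok = blocks[k + 1][1] - blocks[k + 1][0] >= 1
                left_ok = blocks[k][1] - blocks[k][0] >= 1
                if (rng.random() < 0.5 and right_ok) or not left_ok:
                    blocks[k][1] += 1  # move one base from the right block's start
                    blocks[k + 1][0] += 1
                else:
                    blocks[k][1] -= 1  # move one base onto the intron's 3' end
                    blocks[k + 1][0] -= 1

            # soft-clip contamination: convert terminal aligned bases to clips
            clip_left = clip_right = 0
            if mixture.softclip_rate and rng.random() < mixture.softclip_rate:
                lo, hi = mixture.softclip_len_range
                k = int(rng.integers(lo, hi + 1))
                k = min(k, L - 1)  # keep at least one aligned base
                if rng.random() < 0.5:
                    clip_left = k
                    blocks = _trim_blocks(blocks, k, from_left=True)
                else:
                    clip_right = k
                    blocks = _trim_blocks(blocks, k, from_left=False)

            # read sequence from the reference over the aligned blocks
            aligned_seq = "".join(seq[s - 1 : e] for s, e in blocks)
            nm = 0
            if mixture.mismatch_rate and rng.random() < mixture.mismatch_rate:
                j = int(rng.integers(0, len(aligned_seq)))
                old = aligned_seq[j]
                new = "ACGT"[(("ACGT".index(old) + 1 + int(rng.integers(0, 3))) % 4)]
                aligned_seq = aligned_seq[:j] + new + aligned_seq[j + 1 :]
                nm = 1
            left_seq = _BASES[rng.integers(0, 4, size=clip_left)].tobytes().decode()
            right_seq = _BASES[rng.integers(0, 4, size=clip_right)].tobytes().decode()
            full_seq = left_seq + aligned_seq + right_seq

            read_id = f"r{i:06d}_{tid}"
            rec = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
            rec.query_name = read_id
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = blocks[0][0] - 1
            rec.mapping_quality = 60
            cig: list[tuple[int, int]] = []
            if clip_left:
                cig.append((4, clip_left))
            for k, (s, e) in enumerate(blocks):
                if k:
                    cig.append((3, blocks[k][0] - blocks[k - 1][1] - 1))
                cig.append((0, e - s + 1))
            if clip_right:
                cig.append((4, clip_right))
            rec.cigartuples = cig
            rec.query_sequence = full_seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(full_seq))
            rec.set_tag("NM", nm, "i")
            out.write(rec)

            truths.append(
                TruthRead(
                    read_id=read_id,
                    transcript_id=tid,
                    blocks=tuple((s, e) for s, e in blocks),
                    clip_left=clip_left,
                    clip_right=clip_right,
                    nm=nm,
                    crossed=crossed,
                )
            )
    if truth_path is not None:
        write_truth_tsv(truths, catalog, truth_path)
    return truths


def _trim_blocks(blocks: list[list[int]], k: int, from_left: bool) -> list[list[int]]:
    """Remove ``k`` aligned bases from one end, dropping exhausted blocks."""
    blocks = [list(b) for b in blocks]
    seq_order = blocks if from_left else blocks[::-1]
    remaining = k
    kept: list[list[int]] = []
    for b in seq_order:
        blen = b[1] - b[0] + 1
        if remaining >= blen:
            remaining -= blen
            continue
        if remaining:
            if from_left:
                b = [b[0] + remaining, b[1]]
            else:
                b = [b[0], b[1] - remaining]
            remaining = 0
        kept.append(b)
    if not kept:
        raise ValueError("soft clip would consume the whole read")
    return kept if from_left else kept[::-1]


def write_truth_tsv(
    truths: Sequence[TruthRead], catalog: JunctionCatalog, path: str | Path
) -> None:
    import pandas as pd

    by_label = catalog.by_label
    rows = []
    for r in truths:
        qualified = [
            lab for lab in r.crossed if truth_rule_verdict(r, by_label[lab])[0]
        ]
        rows.append(
            {
                "read_id": r.read_id,
                "transcript_id": r.transcript_id,
                "blocks": ";".join(f"{s}-{e}" for s, e in r.blocks),
                "softclip_total": r.softclip_total,
                "nm": r.nm,
                "crossed": ";".join(r.crossed),
                "qualifies": ";".join(qualified),
            }
        )
    pd.DataFrame(
        rows,
        columns=["read_id", "transcript_id", "blocks", "softclip_total", "nm", "crossed", "qualifies"],
    ).to_csv(path, sep="\t", index=False)


def expected_junction_coverage(
    locus: ToyLocus, mixture: MixtureConfig, min_flank: int | None = None
) -> dict[str, float]:
    """Expected junction-read counts implied by a noise-free mixture.

    A transcript contributes reads to a junction in proportion to its molar
    weight divided by the number of admissible start positions; a read crosses
    a junction from L-1 start offsets (L - 2*min_flank + 1 offsets when the
    flank requirement is imposed).  Useful as the analytic reference for
    goodness-of-fit and recovery checks.
    """
    catalog = locus.catalog()
    L = mixture.read_length
    span = L - 1 if min_flank is None else L - 2 * min_flank + 1
    if span <= 0:
        return {lab: 0.0 for lab in catalog.labels()}
    expected = {lab: 0.0 for lab in catalog.labels()}
    for tid, p in mixture.proportions.items():
        if p == 0:
            continue
        t = locus.transcript(tid)
        tlen = t.length
        n_starts = tlen - L + 1
        if n_starts <= 0:
            continue
        gx = t.exons_genomic()
        cum = 0
        for a, b in zip(gx, gx[1:]):
            cum += a.length
            # transcript-coordinate position of this junction is `cum`; clip
            # the crossing window to the transcript
            lo = max(0, cum - (L - 1) if min_flank is None else cum - L + min_flank)
            hi = min(n_starts - 1, cum - 1 if min_flank is None else cum - min_flank)
            n_cross = max(0, hi - lo + 1)
            lab = junction_label(locus.chrom, a.end, b.start)
            if lab in expected:
                expected[lab] += mixture.n_reads * p * n_cross / n_starts
    return expected


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortSimConfig:
    """Statistical structure of a simulated comparison cohort.

    Per-sample junction counts are binomial at the stated sequencing depth
    around group-specific true fractions: the truncating group carries a
    +0.02 shift over the 0.01 baseline by default, mirroring the magnitude of
    aberrant-splicing effects seen in tumor cohorts, while missense tumors sit
    at baseline.  ``n_pairs`` appends WT tumor / adjacent-normal pairs.
    """

    strata: tuple[str, ...] = ("stratum_a",)
    n_per_group: int | Mapping[str, int] = 50
    baseline_fraction: float = 0.01
    group_effect: Mapping[str, float] = field(default_factory=lambda: {"truncating": 0.02})
    utr5_baseline: float = 0.01
    depth: int = 5000
    n_pairs: int = 0
    pair_tumor_effect: float = 0.0
    pair_normal_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        for g, eff in self.group_effect.items():
            if not 0.0 <= self.baseline_fraction + eff <= 1.0:
                raise ConfigurationError(f"baseline + effect for {g} outside [0, 1]")

    def n_for(self, group: str) -> int:
        if isinstance(self.n_per_group, int):
            return self.n_per_group
        return self.n_per_group.get(group, 0)


@dataclass(frozen=True)
class SimulatedCohort:
    samples: tuple[SampleAnnotation, ...]
    counts: tuple[JunctionCounts, ...]
    truth: "object"  # pandas DataFrame: sample_id, stratum, group, true_cterm, true_utr5


_GROUPS = ("WT", "missense", "truncating")


def _binomial_counts(
    rng: np.random.Generator,
    catalog: JunctionCatalog,
    sample_id: str,
    depth: int,
    f_cterm: float,
    f_utr5: float,
) -> JunctionCounts:
    d1, d2 = catalog.cterm_pair
    counts = {lab: 0 for lab in catalog.labels()}
    counts[d1] = int(rng.binomial(depth, f_cterm))
    counts[d2] = int(rng.binomial(depth, f_cterm))
    counts[catalog.cterm_main] = int(rng.binomial(depth, 1.0 - f_cterm))
    counts[catalog.utr5_distinct] = int(rng.binomial(depth, f_utr5))
    counts[catalog.utr5_main] = int(rng.binomial(depth, 1.0 - f_utr5))
    return JunctionCounts(sample_id=sample_id, counts=counts, total_reads_scanned=0)


def simulate_cohort(
    config: CohortSimConfig | None = None,
    catalog: JunctionCatalog | None = None,
) -> SimulatedCohort:
    """Generate annotations plus binomial junction counts with known truth.

    Mutation calls, copy-number ratios and expression values are constructed
    so that classification reproduces the intended group labels exactly
    (WT samples pass both gate thresholds; truncating samples cycle through
    the three truncating classes so per-class subtests are populated).
    """
    import pandas as pd

    config = config or CohortSimConfig()
    if catalog is None:
        catalog = make_toy_locus(ToyLocusConfig(seed=0)).catalog()
    if catalog.cterm_pair is None or catalog.utr5_distinct is None:
        raise ConfigurationError("cohort simulation needs a catalog with cterm and utr5 junctions")
    rng = np.random.default_rng(config.seed)

    samples: list[SampleAnnotation] = []
    counts: list[JunctionCounts] = []
    truth_rows: list[dict] = []

    def add(sample: SampleAnnotation, group: str, f_cterm: float, f_utr5: float) -> None:
        samples.append(sample)
        counts.append(
            _binomial_counts(rng, catalog, sample.sample_id, config.depth, f_cterm, f_utr5)
        )
        truth_rows.append(
            {
                "sample_id": sample.sample_id,
                "stratum": sample.stratum,
                "group": group,
                "true_cterm": f_cterm,
                "true_utr5": f_utr5,
            }
        )

    for stratum in config.strata:
        for group in _GROUPS:
            n = config.n_for(group)
            f = config.baseline_fraction + config.group_effect.get(group, 0.0)
            for i in range(n):
                sid = f"{stratum}_{group}_{i:03d}"
                if group == "WT":
                    calls: tuple[MutationCall, ...] = ()
                elif group == "missense":
                    calls = (MutationCall("missense", "p.R175H"),)
                else:
                    klass = TRUNCATING_CLASSES[i % len(TRUNCATING_CLASSES)]
                    calls = (MutationCall(klass, f"{klass} alteration"),)
                add(
                    SampleAnnotation(
                        sample_id=sid,
                        cohort=COHORT_TUMOR,
                        stratum=stratum,
                        mutation_calls=calls,
                        log2_cn_ratio=0.0,
                        expression_rsem=1000.0,
                    ),
                    group, f, config.utr5_baseline,
                )

    for j in range(config.n_pairs):
        pid = f"pair{j:03d}"
        add(
            SampleAnnotation(
                sample_id=f"{pid}_tumor",
                cohort=COHORT_TUMOR,
                stratum="paired",
                log2_cn_ratio=0.0,
                expression_rsem=1000.0,
                pair_id=pid,
            ),
            "WT",
            config.baseline_fraction + config.pair_tumor_effect,
            config.utr5_baseline,
        )
        add(
            SampleAnnotation(
                sample_id=f"{pid}_normal",
                cohort=COHORT_NORMAL,
                stratum="paired",
                pair_id=pid,
            ),
            "normal",
            config.baseline_fraction + config.pair_normal_effect,
            config.utr5_baseline,
        )

    return SimulatedCohort(
        samples=tuple(samples),
        counts=tuple(counts),
        truth=pd.DataFrame(truth_rows),
    )
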