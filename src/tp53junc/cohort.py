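"""TP53 status classification and cohort construction.

A tumor or cell-line sample is wild type (WT) only when it carries no TP53
mutation call, its log2 copy-number ratio exceeds -0.9, and its normalized
RSEM expression exceeds 300 (both strict inequalities).  Samples with any
frameshift, nonsense or splice-site call form the *truncating* group
(dominating coexisting missense calls, which is flagged); samples with only
missense calls form the *missense* group.  The copy-number/expression gate
applies to the WT definition only.  Normal-tissue samples are never
status-classified; they enter only paired tumor-normal analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, InputDataError

logger = logging.getLogger(__name__)

MUTATION_CLASSES = ("missense", "nonsense", "frameshift", "splice_site")
TRUNCATING_CLASSES = ("nonsense", "splice_site", "frameshift")

GROUP_WT = "WT"
GROUP_MISSENSE = "missense"
GROUP_TRUNCATING = "truncating"
GROUP_EXCLUDED = "excluded"

EXCL_LOW_CN = "low_cn"
EXCL_LOW_EXPRESSION = "low_expression"
EXCL_MISSING_DATA = "missing_data"
FLAG_MIXED_CLASSES = "mixed_classes_policy"

COHORT_TUMOR = "tumor"
COHORT_NORMAL = "normal"
COHORT_CELL_LINE = "cell_line"


@dataclass(frozen=True)
class MutationCall:
    klass: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.klass not in MUTATION_CLASSES:
            raise InputDataError(f"unknown mutation class {self.klass!r}")


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    cohort: str = COHORT_TUMOR
    stratum: str = ""
    mutation_calls: tuple[MutationCall, ...] = ()
    log2_cn_ratio: float | None = None
    expression_rsem: float | None = None
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.cohort not in (COHORT_TUMOR, COHORT_NORMAL, COHORT_CELL_LINE):
            raise InputDataError(f"unknown cohort {self.cohort!r}")
        if self.expression_rsem is not None and self.expression_rsem < 0:
            raise InputDataError(f"{self.sample_id}: negative expression")


@dataclass(frozen=True)
class ClassificationThresholds:
    """WT gate: both thresholds are exclusive lower bounds."""

    min_log2_cn_ratio: float = -0.9
    min_expression: float = 300.0


@dataclass(frozen=True)
class TP53Status:
    group: str
    exclusion_reason: str | None = None
    flag: str | None = None  # e.g. mixed_classes_policy


def classify_tp53_status(
    sample: SampleAnnotation,
    thresholds: ClassificationThresholds | None = None,
) -> TP53Status:
    """Map one sample to {WT, missense, truncating, excluded}.

    Pure function of the sample and thresholds; unknown mutation classes have
    already been rejected when the annotation was constructed.
    """
    thresholds = thresholds or ClassificationThresholds()
    classes = {c.klass for c in sample.mutation_calls}
    truncating = classes & set(TRUNCATING_CLASSES)
    if truncating:
        flag = FLAG_MIXED_CLASSES if "missense" in classes else None
        return TP53Status(GROUP_TRUNCATING, flag=flag)
    if "missense" in classes:
        return TP53Status(GROUP_MISSENSE)
    # no mutations: apply the WT copy-number / expression gate
    cn, expr = sample.log2_cn_ratio, sample.expression_rsem
    if cn is None or (isinstance(cn, float) and math.isnan(cn)) or expr is None or (
        isinstance(expr, float) and math.isnan(expr)
    ):
        return TP53Status(GROUP_EXCLUDED, exclusion_reason=EXCL_MISSING_DATA)
    if not cn > thresholds.min_log2_cn_ratio:
        return TP53Status(GROUP_EXCLUDED, exclusion_reason=EXCL_LOW_CN)
    if not expr > thresholds.min_expression:
        return TP53Status(GROUP_EXCLUDED, exclusion_reason=EXCL_LOW_EXPRESSION)
    return TP53Status(GROUP_WT)


def classify_samples(
    samples: Sequence[SampleAnnotation],
    thresholds: ClassificationThresholds | None = None,
) -> dict[str, TP53Status]:
    """Statuses for all non-normal samples, keyed by sample_id."""
    return {
        s.sample_id: classify_tp53_status(s, thresholds)
        for s in samples
        if s.cohort != COHORT_NORMAL
    }


@dataclass(frozen=True)
class CohortContrast:
    """One per-stratum two-group comparison cohort."""

    stratum: str
    group_b: str  # GROUP_MISSENSE or GROUP_TRUNCATING; group_a is always WT
    wt_ids: tuple[str, ...]
    other_ids: tuple[str, ...]
    #: for the truncating contrast, sample ids per mutation class (a sample
    #: with several truncating calls appears under each of its classes)
    other_by_class: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


def build_cohorts(
    samples: Sequence[SampleAnnotation],
    statuses: Mapping[str, TP53Status],
    min_group_size: int = 5,
) -> list[CohortContrast]:
    """Per-stratum WT-vs-missense and WT-vs-truncating cohorts.

    A contrast is emitted only when both groups reach ``min_group_size``
    members; skipped strata are logged.
    """
    by_stratum: dict[str, list[SampleAnnotation]] = {}
    for s in samples:
        if s.cohort == COHORT_NORMAL:
            continue
        by_stratum.setdefault(s.stratum, []).append(s)

    out: list[CohortContrast] = []
    for stratum in sorted(by_stratum):
        members = by_stratum[stratum]
        wt = tuple(s.sample_id for s in members if statuses[s.sample_id].group == GROUP_WT)
        for group in (GROUP_MISSENSE, GROUP_TRUNCATING):
            other = tuple(
                s.sample_id for s in members if statuses[s.sample_id].group == group
            )
            if len(wt) >= min_group_size and len(other) >= min_group_size:
                by_class: dict[str, tuple[str, ...]] = {}
                if group == GROUP_TRUNCATING:
                    for klass in TRUNCATING_CLASSES:
                        by_class[klass] = tuple(
                            s.sample_id
                            for s in members
                            if statuses[s.sample_id].group == group
                            and any(c.klass == klass for c in s.mutation_calls)
                        )
                out.append(CohortContrast(stratum, group, wt, other, by_class))
            else:
                logger.info(
                    "stratum %s: WT vs %s skipped (n=%d vs %d, need >= %d each)",
                    stratum, group, len(wt), len(other), min_group_size,
                )
    return out


def build_pairs(
    samples: Sequence[SampleAnnotation],
    statuses: Mapping[str, TP53Status] | None = None,
    status_filter: str | None = None,
) -> list[tuple[SampleAnnotation, SampleAnnotation]]:
    """Tumor-normal pairs sharing a pair_id, optionally filtered on the
    tumor member's TP53 status group."""
    by_pair: dict[str, dict[str, SampleAnnotation]] = {}
    for s in samples:
        if s.pair_id is None:
            continue
        slot = by_pair.setdefault(s.pair_id, {})
        key = "normal" if s.cohort == COHORT_NORMAL else "tumor"
        if key in slot:
            raise InputDataError(f"pair_id {s.pair_id!r} maps to two {key} samples")
        slot[key] = s
    pairs = []
    for pid in sorted(by_pair):
        slot = by_pair[pid]
        if "tumor" not in slot or "normal" not in slot:
            logger.info("pair_id %s: unpaired sample dropped", pid)
            continue
        tumor = slot["tumor"]
        if status_filter is not None:
            if statuses is None:
                raise ConfigurationError("status_filter requires statuses")
            if statuses[tumor.sample_id].group != status_filter:
                logger.info(
                    "pair_id %s dropped: tumor status %s != %s",
                    pid, statuses[tumor.sample_id].group, status_filter,
                )
                continue
        pairs.append((tumor, slot["normal"]))
    return pairs


# ---------------------------------------------------------------------------
# tabular interchange

ANNOTATION_COLUMNS = [
    "sample_id", "cohort", "stratum", "mutation_class",
    "log2_cn_ratio", "expression_rsem", "pair_id",
]


def annotations_to_frame(samples: Iterable[SampleAnnotation]) -> pd.DataFrame:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "cohort": s.cohort,
                "stratum": s.stratum,
                "mutation_class": ";".join(c.klass for c in s.mutation_calls),
                "log2_cn_ratio": s.log2_cn_ratio,
                "expression_rsem": s.expression_rsem,
                "pair_id": s.pair_id or "",
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotations_tsv(samples: Iterable[SampleAnnotation], path: str | Path) -> None:
    annotations_to_frame(samples).to_csv(path, sep="\t", index=False)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_annotations_tsv(path: str | Path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "stratum": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns) - {"pair_id"}
    if missing:
        raise InputDataError(f"{path}: annotation TSV missing column(s) {sorted(missing)}")
    samples = []
    for r in df.itertuples():
        raw = getattr(r, "mutation_class", "")
        raw = "" if (raw is None or (isinstance(raw, float) and math.isnan(raw))) else str(raw)
        calls = tuple(MutationCall(k.strip()) for k in raw.split(";") if k.strip())
        pid = getattr(r, "pair_id", None)
        if pid is not None and (pid == "" or (isinstance(pid, float) and math.isnan(pid))):
            pid = None
        samples.append(
            SampleAnnotation(
                sample_id=str(r.sample_id),
                cohort=str(r.cohort),
                stratum="" if str(r.stratum) == "nan" else str(r.stratum),
                mutation_calls=calls,
                log2_cn_ratio=_opt_float(r.log2_cn_ratio),
                expression_rsem=_opt_float(r.expression_rsem),
                pair_id=None if pid is None else str(pid),
            )
        )
    return samples


def statuses_to_frame(statuses: Mapping[str, TP53Status]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": sid,
                "group": st.group,
                "exclusion_reason": st.exclusion_reason or "",
                "flag": st.flag or "",
            }
            for sid, st in sorted(statuses.items())
        ],
        columns=["sample_id", "group", "exclusion_reason", "flag"],
    )
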