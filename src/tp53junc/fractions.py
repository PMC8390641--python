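"""Per-sample exonic fractions of junctions distinct from the main isoform.

The statistic is junction-local: distinct-junction reads divided by
(main-junction reads + distinct-junction reads) at the same splice choice.
For the C-terminal alternative isoforms the two distinct junctions flanking
the extra exon are averaged (arithmetic mean, kept real-valued) before
entering the ratio; the 5'UTR variant uses a single distinct junction.  A
sample whose denominator is zero yields a *missing* fraction — never 0 — and
is excluded from downstream statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .counting import JunctionCounts
from .errors import ConfigurationError, InputDataError
from .model import JunctionCatalog

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FractionResult:
    """Exonic fractions of one sample; ``None`` marks an undefined (0/0) ratio."""

    sample_id: str
    D1: int | None = None
    D2: int | None = None
    D_bar: float | None = None
    M_cterm: int | None = None
    cterm_fraction: float | None = None
    D_utr5: int | None = None
    M_utr5: int | None = None
    utr5_fraction: float | None = None


def junction_fraction(distinct_counts: Sequence[int], main_count: int) -> float | None:
    """Generic ratio distinct / (main + distinct), with the distinct counts
    averaged; ``None`` when the denominator is zero."""
    if any(c < 0 for c in distinct_counts) or main_count < 0:
        raise ValueError("negative junction count")
    d_bar = sum(distinct_counts) / len(distinct_counts)
    denom = main_count + d_bar
    if denom == 0:
        return None
    return d_bar / denom


def cterm_fraction(counts: JunctionCounts, catalog: JunctionCatalog) -> FractionResult:
    """C-terminal alternative-isoform fraction: mean of the two distinct
    junction counts over (main competitor + that mean)."""
    if catalog.cterm_pair is None or catalog.cterm_main is None:
        raise ConfigurationError(
            "catalog does not define the C-terminal junction pair and its main competitor"
        )
    d1 = counts.counts.get(catalog.cterm_pair[0], 0)
    d2 = counts.counts.get(catalog.cterm_pair[1], 0)
    m = counts.counts.get(catalog.cterm_main, 0)
    d_bar = (d1 + d2) / 2.0
    frac = junction_fraction((d1, d2), m)
    if frac is None:
        logger.info("sample %s: zero C-terminal denominator; fraction missing", counts.sample_id)
    return FractionResult(
        sample_id=counts.sample_id, D1=d1, D2=d2, D_bar=d_bar, M_cterm=m, cterm_fraction=frac
    )


def utr5_fraction(counts: JunctionCounts, catalog: JunctionCatalog) -> FractionResult:
    """Fraction of the 3-bp-shifted 5'UTR acceptor junction."""
    if catalog.utr5_distinct is None or catalog.utr5_main is None:
        raise ConfigurationError(
            "catalog does not define the 5'UTR distinct junction and its main competitor"
        )
    d = counts.counts.get(catalog.utr5_distinct, 0)
    m = counts.counts.get(catalog.utr5_main, 0)
    frac = junction_fraction((d,), m)
    if frac is None:
        logger.info("sample %s: zero 5'UTR denominator; fraction missing", counts.sample_id)
    return FractionResult(sample_id=counts.sample_id, D_utr5=d, M_utr5=m, utr5_fraction=frac)


def sample_fractions(counts: JunctionCounts, catalog: JunctionCatalog) -> FractionResult:
    """Both fractions for one sample in a single record."""
    c = cterm_fraction(counts, catalog)
    u = utr5_fraction(counts, catalog)
    return replace(c, D_utr5=u.D_utr5, M_utr5=u.M_utr5, utr5_fraction=u.utr5_fraction)


_COLUMNS = [
    "sample_id", "D1", "D2", "D_bar", "M_cterm", "cterm_fraction",
    "D_utr5", "M_utr5", "utr5_fraction",
]


def fractions_table(
    counts_list: Iterable[JunctionCounts], catalog: JunctionCatalog
) -> pd.DataFrame:
    """One row per sample; missing fractions are NaN (serialized as empty)."""
    counts_list = list(counts_list)
    ids = [c.sample_id for c in counts_list]
    if len(ids) != len(set(ids)):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise InputDataError(f"duplicate sample_id(s) in counts: {dupes}")
    rows = []
    for c in counts_list:
        r = sample_fractions(c, catalog)
        rows.append(
            {
                "sample_id": r.sample_id,
                "D1": r.D1,
                "D2": r.D2,
                "D_bar": r.D_bar,
                "M_cterm": r.M_cterm,
                "cterm_fraction": math.nan if r.cterm_fraction is None else r.cterm_fraction,
                "D_utr5": r.D_utr5,
                "M_utr5": r.M_utr5,
                "utr5_fraction": math.nan if r.utr5_fraction is None else r.utr5_fraction,
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_fractions_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_fractions_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ConfigurationError(f"{path}: fractions TSV must have a sample_id column")
    return df
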