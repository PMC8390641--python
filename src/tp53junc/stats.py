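"""Group summaries, Welch and paired t-tests, Bonferroni-adjusted significance.

All unpaired comparisons are two-tailed Welch (unequal-variance) t-tests;
paired comparisons are one-sample t-tests on the within-pair differences.
The family-wise significance level is ``family_alpha / m_tests`` where
``m_tests`` counts the tests actually executed (a fixed override is available
to mirror an externally defined family), and a result is called significant
when ``p <= adjusted_alpha``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import (
    GROUP_TRUNCATING,
    GROUP_WT,
    CohortContrast,
    TP53Status,
)
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

WELCH = "welch_two_tailed"
PAIRED = "paired_two_tailed"


@dataclass(frozen=True)
class GroupSummary:
    stratum: str
    group: str
    n: int
    mean: float
    median: float


@dataclass(frozen=True)
class ComparisonResult:
    stratum: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    test_kind: str


@dataclass(frozen=True)
class FamilyCorrection:
    family_alpha: float
    m_tests: int
    adjusted_alpha: float


def bonferroni_alpha(family_alpha: float, m_tests: int) -> FamilyCorrection:
    """Adjusted significance level family_alpha / m_tests (exact division)."""
    if m_tests < 1:
        raise ConfigurationError("m_tests must be >= 1")
    if not 0 < family_alpha <= 1:
        raise ConfigurationError("family_alpha must be in (0, 1]")
    return FamilyCorrection(family_alpha, m_tests, family_alpha / m_tests)


def _finite(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    return arr[~np.isnan(arr)]


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Welch t-test with Welch-Satterthwaite degrees of freedom.

    Degenerate zero-variance-in-both-groups inputs get the limiting
    convention: p = 1 for equal means, p = 0 otherwise.
    """
    x, y = _finite(x), _finite(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t_test requires >= 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            logger.info("welch_t_test: both groups constant and equal; p = 1")
            return 0.0, 1.0
        logger.info("welch_t_test: both groups constant, different means; p = 0 limit")
        return math.copysign(math.inf, np.mean(x) - np.mean(y)), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def paired_t_test(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Two-tailed one-sample t-test of the differences a - b against 0.

    Pairs with a missing member are dropped first; constant differences get
    the limiting conventions (p = 1 for all-zero, p = 0 otherwise).
    """
    diffs = np.array(
        [a - b for a, b in pairs if not (math.isnan(a) or math.isnan(b))], dtype=float
    )
    if len(diffs) < 2:
        raise ValueError("paired_t_test requires >= 2 complete pairs")
    if np.var(diffs, ddof=1) == 0:
        if diffs[0] == 0:
            logger.info("paired_t_test: all differences zero; p = 1")
            return 0.0, 1.0
        logger.info("paired_t_test: constant nonzero differences; p = 0 limit")
        return math.copysign(math.inf, diffs[0]), 0.0
    t, p = sps.ttest_1samp(diffs, 0.0)
    return float(t), float(p)


def group_summaries(
    fractions: pd.DataFrame,
    annotations: pd.DataFrame,
    by: str = "stratum",
    column: str = "cterm_fraction",
) -> pd.DataFrame:
    """Per-group n / mean / median over non-missing fractions, sorted by
    descending median then group name (the tissue-table ordering)."""
    merged = fractions.merge(annotations[["sample_id", by]], on="sample_id", how="inner")
    rows = []
    for name, grp in merged.groupby(by, sort=True):
        vals = grp[column].dropna()
        if len(vals) == 0:
            logger.info("group %s omitted from summaries: no non-missing fractions", name)
            continue
        rows.append(
            {by: name, "n": int(len(vals)), "mean": float(vals.mean()), "median": float(vals.median())}
        )
    df = pd.DataFrame(rows, columns=[by, "n", "mean", "median"])
    if len(df):
        df = df.sort_values(["median", by], ascending=[False, True], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def _values_for(fractions: pd.DataFrame, ids: Sequence[str], column: str) -> np.ndarray:
    sub = fractions[fractions["sample_id"].isin(set(ids))]
    return _finite(sub[column].to_numpy(dtype=float))


def run_comparison_suite(
    fractions: pd.DataFrame,
    statuses: Mapping[str, TP53Status],
    cohorts: Sequence[CohortContrast],
    family_alpha: float = 0.05,
    column: str = "cterm_fraction",
    include_truncating_classes: bool = True,
    fixed_m: int | None = None,
) -> tuple[pd.DataFrame, FamilyCorrection | None]:
    """Welch tests for every cohort contrast (WT vs missense, WT vs truncating,
    and per truncating mutation class) plus the Bonferroni correction over the
    tests actually run.

    Returns a result table with a ``significant`` flag (p <= adjusted alpha)
    and the :class:`FamilyCorrection`; both are empty/None when no test ran.
    """
    results: list[ComparisonResult] = []
    for contrast in cohorts:
        subtests: list[tuple[str, Sequence[str]]] = [(contrast.group_b, contrast.other_ids)]
        if contrast.group_b == GROUP_TRUNCATING and include_truncating_classes:
            for klass, ids in contrast.other_by_class.items():
                subtests.append((f"{GROUP_TRUNCATING}:{klass}", ids))
        x = _values_for(fractions, contrast.wt_ids, column)
        for label, ids in subtests:
            y = _values_for(fractions, ids, column)
            if len(x) < 2 or len(y) < 2:
                logger.info(
                    "stratum %s: WT vs %s not tested (n=%d vs %d non-missing)",
                    contrast.stratum, label, len(x), len(y),
                )
                continue
            t, p = welch_t_test(x, y)
            results.append(
                ComparisonResult(
                    stratum=contrast.stratum,
                    group_a=GROUP_WT,
                    group_b=label,
                    n_a=len(x),
                    n_b=len(y),
                    mean_a=float(np.mean(x)),
                    mean_b=float(np.mean(y)),
                    t_statistic=t,
                    p_value=p,
                    test_kind=WELCH,
                )
            )
    return _finalize(results, family_alpha, fixed_m)


def run_paired_suite(
    fractions: pd.DataFrame,
    pairs: Sequence[tuple],
    family_alpha: float = 0.05,
    columns: Sequence[str] = ("cterm_fraction", "utr5_fraction"),
    stratum: str = "all",
    fixed_m: int | None = None,
) -> tuple[pd.DataFrame, FamilyCorrection | None]:
    """Paired tumor-vs-normal t-tests, one per fraction column."""
    lookup = fractions.set_index("sample_id")
    results: list[ComparisonResult] = []
    for column in columns:
        vals = []
        for tumor, normal in pairs:
            try:
                a = float(lookup.at[tumor.sample_id, column])
                b = float(lookup.at[normal.sample_id, column])
            except KeyError:
                continue
            if math.isnan(a) or math.isnan(b):
                continue
            vals.append((a, b))
        if len(vals) < 2:
            logger.info("paired %s: skipped (%d complete pairs)", column, len(vals))
            continue
        t, p = paired_t_test(vals)
        a_vals = [a for a, _ in vals]
        b_vals = [b for _, b in vals]
        results.append(
            ComparisonResult(
                stratum=stratum,
                group_a=f"tumor:{column}",
                group_b=f"normal:{column}",
                n_a=len(vals),
                n_b=len(vals),
                mean_a=float(np.mean(a_vals)),
                mean_b=float(np.mean(b_vals)),
                t_statistic=t,
                p_value=p,
                test_kind=PAIRED,
            )
        )
    return _finalize(results, family_alpha, fixed_m)


_RESULT_COLUMNS = [
    "stratum", "group_a", "group_b", "n_a", "n_b", "mean_a", "mean_b",
    "t", "p", "test_kind", "adjusted_alpha", "significant",
]


def _finalize(
    results: list[ComparisonResult], family_alpha: float, fixed_m: int | None
) -> tuple[pd.DataFrame, FamilyCorrection | None]:
    if not results:
        return pd.DataFrame(columns=_RESULT_COLUMNS), None
    correction = bonferroni_alpha(family_alpha, fixed_m if fixed_m else len(results))
    df = pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "t": r.t_statistic,
                "p": r.p_value,
                "test_kind": r.test_kind,
                "adjusted_alpha": correction.adjusted_alpha,
                "significant": r.p_value <= correction.adjusted_alpha,
            }
            for r in results
        ],
        columns=_RESULT_COLUMNS,
    )
    return df, correction
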