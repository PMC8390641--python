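"""Welch/paired t-tests against closed-form oracles, Bonferroni arithmetic,
group summaries and the comparison suite."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tp53junc as tj
from tp53junc.cohort import annotations_to_frame
from tp53junc.errors import ConfigurationError


def welch_oracle(x, y):
    """Textbook Welch statistic with Welch-Satterthwaite df, written out."""
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


def paired_oracle(pairs):
    d = [a - b for a, b in pairs]
    n = len(d)
    md = sum(d) / n
    sd = math.sqrt(sum((v - md) ** 2 for v in d) / (n - 1))
    t = md / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return t, p


class TestWelch:
    def test_matches_closed_form_to_1e10(self):
        x = [0.1, 0.2, 0.3, 0.4]
        y = [0.5, 0.6, 0.7, 0.8]
        t, p = tj.welch_t_test(x, y)
        t0, p0 = welch_oracle(x, y)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_closed_form_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.02, 0.01, size=rng.integers(3, 30)).tolist()
        y = rng.normal(0.025, 0.02, size=rng.integers(3, 30)).tolist()
        t, p = tj.welch_t_test(x, y)
        t0, p0 = welch_oracle(x, y)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_identical_groups(self):
        t, p = tj.welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_swap_negates_t_preserves_p(self):
        x, y = [0.1, 0.2, 0.35], [0.5, 0.61, 0.7, 0.8]
        t1, p1 = tj.welch_t_test(x, y)
        t2, p2 = tj.welch_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_zero_variance_conventions(self):
        assert tj.welch_t_test([1, 1], [1, 1]) == (0.0, 1.0)
        t, p = tj.welch_t_test([2, 2], [1, 1])
        assert math.isinf(t) and t > 0 and p == 0.0


class TestPaired:
    def test_matches_closed_form(self):
        rng = np.random.default_rng(7)
        pairs = [(a, b) for a, b in rng.normal(0.01, 0.004, size=(5, 2))]
        t, p = tj.paired_t_test(pairs)
        t0, p0 = paired_oracle(pairs)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_equal_members_give_p_one(self):
        assert tj.paired_t_test([(1, 1), (2, 2), (3, 3)]) == (0.0, 1.0)

    def test_constant_nonzero_differences_degenerate(self):
        t, p = tj.paired_t_test([(1, 0), (2, 1), (3, 2)])
        assert math.isinf(t) and p == 0.0

    def test_pairs_with_missing_member_dropped(self):
        pairs = [(1.0, 0.5), (math.nan, 0.4), (2.0, 1.1), (0.9, math.nan), (1.4, 0.2)]
        kept = [(1.0, 0.5), (2.0, 1.1), (1.4, 0.2)]
        assert tj.paired_t_test(pairs) == pytest.approx(paired_oracle(kept), abs=1e-10)


class TestBonferroni:
    @pytest.mark.parametrize(
        "m,expected_repr",
        [(79, "6.33e-04"), (76, "6.58e-04"), (10, "5.00e-03"), (1, "5.00e-02")],
    )
    def test_adjusted_levels(self, m, expected_repr):
        corr = tj.bonferroni_alpha(0.05, m)
        assert f"{corr.adjusted_alpha:.2e}" == expected_repr
        assert corr.adjusted_alpha * corr.m_tests == pytest.approx(0.05, rel=1e-15)

    def test_zero_tests_rejected(self):
        with pytest.raises(ConfigurationError):
            tj.bonferroni_alpha(0.05, 0)


class TestGroupSummaries:
    def _tables(self, groups):
        frac_rows, ann_rows = [], []
        for name, values in groups.items():
            for i, v in enumerate(values):
                sid = f"{name}{i}"
                frac_rows.append({"sample_id": sid, "cterm_fraction": v})
                ann_rows.append({"sample_id": sid, "stratum": name})
        return pd.DataFrame(frac_rows), pd.DataFrame(ann_rows)

    def test_mean_median_and_ordering(self):
        frac, ann = self._tables(
            {"flat": [0.042, 0.042, 0.042], "skew": [0, 0, 0.03]}
        )
        df = tj.group_summaries(frac, ann)
        assert list(df["stratum"]) == ["flat", "skew"]  # descending median
        flat = df.set_index("stratum").loc["flat"]
        assert flat["median"] == pytest.approx(0.042)
        assert flat["mean"] == pytest.approx(0.042)
        skew = df.set_index("stratum").loc["skew"]
        assert skew["median"] == 0.0 and skew["mean"] == pytest.approx(0.01)

    def test_invariant_to_sample_order(self):
        frac, ann = self._tables({"a": [0.01, 0.04, 0.02], "b": [0.0, 0.05]})
        shuffled = frac.sample(frac=1.0, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            tj.group_summaries(frac, ann), tj.group_summaries(shuffled, ann)
        )

    def test_group_with_only_missing_fractions_omitted(self):
        frac, ann = self._tables({"ok": [0.01, 0.02], "void": [math.nan, math.nan]})
        df = tj.group_summaries(frac, ann)
        assert list(df["stratum"]) == ["ok"]


class TestComparisonSuite:
    def test_injected_effect_is_flagged_significant(self, toy_catalog):
        sim = tj.simulate_cohort(
            tj.CohortSimConfig(seed=42, n_per_group=50, depth=5000,
                               group_effect={"truncating": 0.02}),
            toy_catalog,
        )
        frac = tj.fractions_table(sim.counts, toy_catalog)
        statuses = tj.classify_samples(sim.samples)
        cohorts = tj.build_cohorts(sim.samples, statuses)
        res, corr = tj.run_comparison_suite(frac, statuses, cohorts)
        assert corr.m_tests == len(res)
        trunc = res[res.group_b == "truncating"].iloc[0]
        assert trunc["significant"]
        assert trunc["p"] <= corr.adjusted_alpha

    def test_single_test_family_keeps_family_alpha(self, toy_catalog):
        sim = tj.simulate_cohort(
            tj.CohortSimConfig(seed=1, n_per_group={"WT": 10, "missense": 10, "truncating": 0}),
            toy_catalog,
        )
        frac = tj.fractions_table(sim.counts, toy_catalog)
        statuses = tj.classify_samples(sim.samples)
        cohorts = tj.build_cohorts(sim.samples, statuses)
        res, corr = tj.run_comparison_suite(frac, statuses, cohorts)
        assert corr.m_tests == 1
        assert corr.adjusted_alpha == 0.05

    def test_empty_cohorts_yield_empty_result(self):
        res, corr = tj.run_comparison_suite(
            pd.DataFrame(columns=["sample_id", "cterm_fraction"]), {}, []
        )
        assert len(res) == 0 and corr is None

    def test_fixed_m_override(self, toy_catalog):
        sim = tj.simulate_cohort(
            tj.CohortSimConfig(seed=1, n_per_group={"WT": 10, "missense": 10, "truncating": 0}),
            toy_catalog,
        )
        frac = tj.fractions_table(sim.counts, toy_catalog)
        statuses = tj.classify_samples(sim.samples)
        cohorts = tj.build_cohorts(sim.samples, statuses)
        _, corr = tj.run_comparison_suite(frac, statuses, cohorts, fixed_m=79)
        assert corr.adjusted_alpha == pytest.approx(0.05 / 79)

    def test_paired_suite_recovers_pair_means(self, toy_catalog):
        sim = tj.simulate_cohort(
            tj.CohortSimConfig(seed=9, n_per_group=0, n_pairs=15, depth=20000),
            toy_catalog,
        )
        frac = tj.fractions_table(sim.counts, toy_catalog)
        statuses = tj.classify_samples(sim.samples)
        pairs = tj.build_pairs(sim.samples, statuses, status_filter="WT")
        assert len(pairs) == 15
        res, corr = tj.run_paired_suite(frac, pairs)
        assert set(res["test_kind"]) == {"paired_two_tailed"}
        assert corr.m_tests == 2  # cterm + utr5
        cterm = res[res.group_a == "tumor:cterm_fraction"].iloc[0]
        assert cterm["mean_a"] == pytest.approx(0.01, abs=0.005)
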