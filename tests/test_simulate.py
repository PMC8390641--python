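"""Synthetic-data generators: determinism, structural fidelity, and the
central oracle-equivalence property against the counting module."""

import numpy as np
import pytest
from scipy import stats as sps

import tp53junc as tj
from tp53junc.model import KLASS_CTERM
from tp53junc.simulate import CTERM_ID, GAMMA_ID, MAIN_ID, UTR5_ID, ToyLocusConfig


class TestToyLocus:
    def test_structure_mirrors_the_real_locus(self, toy_locus, toy_catalog):
        main = toy_locus.transcript(MAIN_ID)
        assert main.role == "main"
        assert len(main.exons) >= 10
        assert sum(1 for j in toy_catalog.junctions if j.klass == KLASS_CTERM) == 2
        assert toy_catalog.cterm_pair is not None and toy_catalog.utr5_distinct is not None

    def test_utr5_acceptor_shifted_exactly_three_bases(self, toy_catalog):
        d = toy_catalog.by_label[toy_catalog.utr5_distinct]
        m = toy_catalog.by_label[toy_catalog.utr5_main]
        assert d.donor_end == m.donor_end
        assert abs(d.acceptor_start - m.acceptor_start) == 3

    def test_same_seed_is_byte_identical(self, tmp_path):
        a = tj.make_toy_locus(ToyLocusConfig(seed=5))
        b = tj.make_toy_locus(ToyLocusConfig(seed=5))
        assert a.sequence == b.sequence and a.transcripts == b.transcripts
        pa, pb = tmp_path / "a", tmp_path / "b"
        tj.write_locus(a, pa)
        tj.write_locus(b, pb)
        assert (pa / "locus.fa").read_bytes() == (pb / "locus.fa").read_bytes()
        assert (pa / "model.json").read_bytes() == (pb / "model.json").read_bytes()

    def test_minus_strand_variant_yields_same_genomic_catalog(self, toy_catalog):
        minus = tj.make_toy_locus(ToyLocusConfig(strand="-"))
        cat = minus.catalog()
        assert {j.coords for j in cat.junctions} == {j.coords for j in toy_catalog.junctions}
        assert cat.cterm_pair == toy_catalog.cterm_pair


class TestSimulateAlignments:
    def test_same_seed_reproduces_sam_and_truth(self, tmp_path, toy_locus):
        mix = tj.MixtureConfig(n_reads=500, seed=8, softclip_rate=0.2, mismatch_rate=0.1)
        t1 = tj.simulate_alignments(toy_locus, mix, tmp_path / "a.sam")
        t2 = tj.simulate_alignments(toy_locus, mix, tmp_path / "b.sam")
        assert t1 == t2
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()

    def test_pure_main_mixture_yields_no_distinct_counts(self, tmp_path, toy_locus, toy_catalog):
        mix = tj.MixtureConfig(proportions={MAIN_ID: 1.0}, n_reads=2000, seed=2)
        truths = tj.simulate_alignments(toy_locus, mix, tmp_path / "m.sam")
        counts = tj.count_junction_reads(tmp_path / "m.sam", toy_catalog)
        for j in toy_catalog.junctions:
            if j.klass != "main":
                assert counts.counts[j.label] == 0
        # every crossed junction on a clean read qualifies
        for tr in truths:
            for lab in tr.crossed:
                ok, _ = tj.truth_rule_verdict(tr, toy_catalog.by_label[lab])
                flanks_possible = tr.seq_len >= 20
                if flanks_possible and len(tr.blocks) > 1:
                    assert ok or _ == "short_flank"

    def test_full_offset_error_rejects_every_spliced_read(self, tmp_path, toy_locus, toy_catalog):
        mix = tj.MixtureConfig(n_reads=1500, seed=3, offset_error_rate=1.0)
        truths = tj.simulate_alignments(toy_locus, mix, tmp_path / "o.sam")
        counts = tj.count_junction_reads(tmp_path / "o.sam", toy_catalog)
        assert set(counts.counts.values()) == {0}
        spliced = [t for t in truths if t.crossed]
        assert spliced
        for tr in spliced:
            for lab in tr.crossed:
                ok, reason = tj.truth_rule_verdict(tr, toy_catalog.by_label[lab])
                assert not ok
                if len(tr.blocks) == 2:  # single skip: necessarily shifted
                    assert reason == "breakpoint_mismatch"

    def test_junction_read_counts_match_implied_proportions(self, tmp_path, toy_locus, toy_catalog):
        """Chi-square goodness of fit of crossing reads vs the analytic expectation."""
        mix = tj.MixtureConfig(n_reads=20000, seed=13)
        truths = tj.simulate_alignments(toy_locus, mix, tmp_path / "gof.sam")
        observed = {lab: 0 for lab in toy_catalog.labels()}
        for tr in truths:
            for lab in tr.crossed:
                observed[lab] += 1
        expected = tj.expected_junction_coverage(toy_locus, mix)
        labels = [lab for lab, e in expected.items() if e >= 5]
        obs = np.array([observed[lab] for lab in labels], dtype=float)
        exp = np.array([expected[lab] for lab in labels])
        exp *= obs.sum() / exp.sum()
        stat, p = sps.chisquare(obs, exp)
        assert p > 0.001

    @pytest.mark.parametrize(
        "noise",
        [
            {},
            {"softclip_rate": 0.3, "softclip_len_range": (10, 45)},
            {"mismatch_rate": 0.2},
            {"offset_error_rate": 0.3},
            {"softclip_rate": 0.2, "mismatch_rate": 0.1, "offset_error_rate": 0.1},
        ],
    )
    def test_oracle_equivalence_under_noise(self, tmp_path, toy_locus, toy_catalog, noise):
        """Counting-module verdicts equal the literal truth-table rule read-for-read."""
        mix = tj.MixtureConfig(n_reads=2000, seed=17, **noise)
        truths = tj.simulate_alignments(toy_locus, mix, tmp_path / "x.sam")
        counts, audit = tj.count_junction_reads(tmp_path / "x.sam", toy_catalog, collect_audit=True)
        assert counts.counts == tj.truth_counts(truths, toy_catalog)
        accepted = {(v.read_id, v.junction_label) for v in audit if v.accepted}
        oracle_accepted = {
            (tr.read_id, lab)
            for tr in truths
            for lab in tr.crossed
            if tj.truth_rule_verdict(tr, toy_catalog.by_label[lab])[0]
        }
        assert accepted == oracle_accepted

    def test_truth_table_written_as_tsv(self, tmp_path, toy_locus):
        mix = tj.MixtureConfig(n_reads=50, seed=1)
        tj.simulate_alignments(toy_locus, mix, tmp_path / "t.sam", tmp_path / "truth.tsv")
        header = (tmp_path / "truth.tsv").read_text().splitlines()[0]
        assert header.split("\t")[:3] == ["read_id", "transcript_id", "blocks"]


class TestSimulateCohort:
    def test_classification_reproduces_intended_groups(self, toy_catalog):
        sim = tj.simulate_cohort(tj.CohortSimConfig(seed=4, n_per_group=10), toy_catalog)
        statuses = tj.classify_samples(sim.samples)
        truth = sim.truth.set_index("sample_id")
        for sid, status in statuses.items():
            assert status.group == truth.loc[sid, "group"]

    def test_small_groups_are_skipped_downstream(self, toy_catalog):
        sim = tj.simulate_cohort(tj.CohortSimConfig(seed=4, n_per_group=4), toy_catalog)
        statuses = tj.classify_samples(sim.samples)
        assert tj.build_cohorts(sim.samples, statuses) == []

    def test_deterministic_given_seed(self, toy_catalog):
        a = tj.simulate_cohort(tj.CohortSimConfig(seed=11), toy_catalog)
        b = tj.simulate_cohort(tj.CohortSimConfig(seed=11), toy_catalog)
        assert a.samples == b.samples
        assert all(x.counts == y.counts for x, y in zip(a.counts, b.counts))

    def test_counts_center_on_true_fractions(self, toy_catalog):
        sim = tj.simulate_cohort(
            tj.CohortSimConfig(seed=21, n_per_group={"WT": 40, "missense": 0, "truncating": 0},
                               depth=20000),
            toy_catalog,
        )
        frac = tj.fractions_table(sim.counts, toy_catalog)
        assert frac["cterm_fraction"].mean() == pytest.approx(0.01, abs=0.002)

    def test_null_effect_gives_uniform_p_values(self, toy_catalog):
        """Kolmogorov-Smirnov check of Welch p-values across null replicates."""
        pvals = []
        for seed in range(120):
            sim = tj.simulate_cohort(
                tj.CohortSimConfig(
                    seed=seed, n_per_group={"WT": 8, "missense": 8, "truncating": 0},
                    group_effect={},
                ),
                toy_catalog,
            )
            frac = tj.fractions_table(sim.counts, toy_catalog)
            statuses = tj.classify_samples(sim.samples)
            cohorts = tj.build_cohorts(sim.samples, statuses)
            res, _ = tj.run_comparison_suite(frac, statuses, cohorts)
            pvals.append(res["p"].iloc[0])
        stat, p = sps.kstest(pvals, "uniform")
        assert p > 0.001
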