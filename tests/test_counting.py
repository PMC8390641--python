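"""CIGAR decomposition and the strict junction-read rule."""

import random

import pytest

import tp53junc as tj
from tp53junc.counting import (
    REJECT_BREAKPOINT,
    REJECT_FLANK,
    REJECT_INDEL,
    REJECT_MISMATCH,
    REJECT_NO_SPLICE,
    REJECT_SOFTCLIP,
    read_blocks,
)
from tp53junc.model import Junction, junction_label


def J(donor, acceptor, chrom="toy1"):
    return Junction(
        chrom=chrom,
        donor_end=donor,
        acceptor_start=acceptor,
        label=junction_label(chrom, donor, acceptor),
        origin=frozenset({"t"}),
        klass="main",
    )


class TestReadBlocks:
    def test_spliced_cigar_splits_into_two_blocks(self, make_record):
        info = read_blocks(make_record("50M600N51M", pos=1000))
        assert [(b.ref_start, b.ref_end, b.aligned_bases) for b in info.blocks] == [
            (1000, 1049, 50),
            (1650, 1700, 51),
        ]
        assert info.softclip_total == 0 and not info.has_indel

    def test_softclip_counted_outside_blocks(self, make_record):
        info = read_blocks(make_record("30S40M600N31M", pos=1000))
        assert [b.aligned_bases for b in info.blocks] == [40, 31]
        assert info.softclip_total == 30

    def test_insertion_stays_in_one_block_as_indel_evidence(self, make_record):
        info = read_blocks(make_record("50M1I50M", pos=1000))
        assert len(info.blocks) == 1
        assert info.blocks[0].aligned_bases == 100
        assert info.has_indel

    def test_hard_clips_ignored(self, make_record):
        info = read_blocks(make_record("10H50M600N50M10H", pos=1000))
        assert info.softclip_total == 0
        assert len(info.blocks) == 2


class TestClassifyRead:
    """The rule: exact breakpoint, >=10 nt flanks, <= half soft-clipped, zero mismatches."""

    JUNC = J(1049, 1650)

    def test_exact_boundary_clean_read_accepted(self, make_record):
        v = tj.classify_read(make_record("50M600N50M", pos=1000), self.JUNC)
        assert v.accepted and v.reject_reason is None

    def test_nine_base_flank_rejected(self, make_record):
        v = tj.classify_read(make_record("95M600N5M", pos=955), self.JUNC)
        assert v.reject_reason == REJECT_FLANK

    def test_excess_softclip_rejected(self, make_record):
        v = tj.classify_read(make_record("60S20M600N20M", pos=1030), self.JUNC)
        assert v.reject_reason == REJECT_SOFTCLIP

    def test_exactly_half_softclip_passes(self, make_record):
        v = tj.classify_read(make_record("50S25M600N25M", pos=1025), self.JUNC)
        assert v.accepted

    def test_single_mismatch_rejected(self, make_record):
        v = tj.classify_read(make_record("50M600N50M", pos=1000, nm=1), self.JUNC)
        assert v.reject_reason == REJECT_MISMATCH

    def test_indel_rejected_even_with_nm_zero_for_mismatches(self, make_record):
        v = tj.classify_read(make_record("30M1D20M600N50M", pos=999, nm=1), self.JUNC)
        assert v.reject_reason == REJECT_INDEL

    def test_offset_breakpoint_rejected(self, make_record):
        v = tj.classify_read(make_record("50M600N50M", pos=1001), self.JUNC)
        assert v.reject_reason == REJECT_BREAKPOINT

    def test_unspliced_read_rejected_as_no_splice(self, make_record):
        v = tj.classify_read(make_record("100M", pos=1000), self.JUNC)
        assert v.reject_reason == REJECT_NO_SPLICE

    def test_missing_nm_tag_strict_vs_permissive(self, make_record):
        rec = make_record("50M600N50M", pos=1000, nm=None, md="100")
        strict = tj.classify_read(rec, self.JUNC, tj.CountingParams(nm_tag_policy="strict"))
        assert strict.reject_reason == REJECT_MISMATCH
        permissive = tj.classify_read(
            rec, self.JUNC, tj.CountingParams(nm_tag_policy="permissive")
        )
        assert permissive.accepted
        mismatched = make_record("50M600N50M", pos=1000, nm=None, md="40A59")
        v = tj.classify_read(mismatched, self.JUNC, tj.CountingParams(nm_tag_policy="permissive"))
        assert v.reject_reason == REJECT_MISMATCH

    def test_flanks_counted_within_adjacent_block_only(self, make_record):
        # 9 aligned bases in the block left of the second skip: short flank for
        # the downstream junction even though total upstream support is larger
        junc = J(1066, 1708)
        rec = make_record("50M8N9M641N50M", pos=1000)
        v = tj.classify_read(rec, junc, tj.CountingParams())
        assert v.reject_reason == REJECT_FLANK


class TestCountJunctionReads:
    def _fixture_records(self, make_record, toy_catalog):
        """3 qualifying main-junction reads, 1 qualifying beta read, 1 near-miss."""
        main = toy_catalog.by_label[toy_catalog.cterm_main]  # (5071, 5972)
        beta1 = toy_catalog.by_label[toy_catalog.cterm_pair[0]]  # (5071, 5152)
        gap_main = main.acceptor_start - main.donor_end - 1
        gap_b = beta1.acceptor_start - beta1.donor_end - 1
        recs = [
            make_record(f"38M{gap_main}N38M", pos=main.donor_end - 37, name=f"m{i}")
            for i in range(3)
        ]
        recs.append(make_record(f"38M{gap_b}N38M", pos=beta1.donor_end - 37, name="b0"))
        recs.append(  # 9 nt flank on the left: near miss
            make_record(f"9M{gap_main}N67M", pos=main.donor_end - 8, name="nearmiss")
        )
        return recs, main.label, beta1.label

    def test_counts_and_audit_on_known_fixture(self, make_record, write_sam, toy_catalog):
        recs, main_label, beta_label, = self._fixture_records(make_record, toy_catalog)
        path = write_sam(recs)
        counts, audit = tj.count_junction_reads(path, toy_catalog, collect_audit=True)
        assert counts.counts[main_label] == 3
        assert counts.counts[beta_label] == 1
        assert sum(counts.counts.values()) == 4
        rejected = [v for v in audit if not v.accepted]
        assert [v.reject_reason for v in rejected] == [REJECT_FLANK]
        assert rejected[0].read_id == "nearmiss"

    def test_read_order_does_not_matter(self, make_record, write_sam, toy_catalog):
        recs, *_ = self._fixture_records(make_record, toy_catalog)
        shuffled = list(recs)
        random.Random(5).shuffle(shuffled)
        c1 = tj.count_junction_reads(write_sam(recs, "a.sam"), toy_catalog)
        c2 = tj.count_junction_reads(write_sam(shuffled, "b.sam"), toy_catalog)
        assert c1.counts == c2.counts

    def test_empty_alignment_file(self, write_sam, toy_catalog):
        counts = tj.count_junction_reads(write_sam([]), toy_catalog)
        assert counts.total_reads_scanned == 0
        assert set(counts.counts.values()) == {0}

    def test_multi_skip_read_counts_each_matched_junction_once(
        self, make_record, write_sam, toy_catalog
    ):
        b1 = toy_catalog.by_label[toy_catalog.cterm_pair[0]]
        b2 = toy_catalog.by_label[toy_catalog.cterm_pair[1]]
        exon_len = b2.donor_end - b1.acceptor_start + 1  # the inserted exon
        gap1 = b1.acceptor_start - b1.donor_end - 1
        gap2 = b2.acceptor_start - b2.donor_end - 1
        rec = make_record(
            f"20M{gap1}N{exon_len}M{gap2}N20M", pos=b1.donor_end - 19, name="double"
        )
        counts = tj.count_junction_reads(write_sam([rec]), toy_catalog)
        assert counts.counts[b1.label] == 1
        assert counts.counts[b2.label] == 1

    def test_secondary_and_unmapped_records_excluded(self, make_record, write_sam, toy_catalog):
        main = toy_catalog.by_label[toy_catalog.cterm_main]
        gap = main.acceptor_start - main.donor_end - 1
        good = make_record(f"38M{gap}N38M", pos=main.donor_end - 37, name="ok")
        secondary = make_record(
            f"38M{gap}N38M", pos=main.donor_end - 37, name="sec", flag=256
        )
        counts = tj.count_junction_reads(write_sam([good, secondary]), toy_catalog)
        assert counts.counts[main.label] == 1

    def test_wrong_chromosome_yields_zero_counts(self, make_record, write_sam, toy_catalog):
        rec = make_record("38M900N38M", pos=5034, chrom="chrOther")
        path = write_sam([rec], chrom="chrOther", length=10_000_000)
        counts = tj.count_junction_reads(path, toy_catalog)
        assert set(counts.counts.values()) == {0}


class TestMonotonicity:
    """Relaxing min_flank or the soft-clip budget never decreases any count."""

    @pytest.mark.parametrize("seed", [11, 12])
    def test_relaxed_parameters_dominate(self, tmp_path, toy_locus, toy_catalog, seed):
        mix = tj.MixtureConfig(
            n_reads=2000, seed=seed, softclip_rate=0.3, mismatch_rate=0.1,
            offset_error_rate=0.05, softclip_len_range=(20, 45),
        )
        sam = tmp_path / "reads.sam"
        tj.simulate_alignments(toy_locus, mix, sam)
        strict = tj.count_junction_reads(sam, toy_catalog, tj.CountingParams())
        relaxed = tj.count_junction_reads(
            sam, toy_catalog,
            tj.CountingParams(min_flank=5, max_softclip_fraction=0.9),
        )
        for lab in toy_catalog.labels():
            assert relaxed.counts[lab] >= strict.counts[lab]
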