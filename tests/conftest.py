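import pysam
import pytest

import tp53junc as tj


@pytest.fixture(scope="session")
def toy_locus():
    return tj.make_toy_locus()


@pytest.fixture(scope="session")
def toy_catalog(toy_locus):
    return toy_locus.catalog()


@pytest.fixture(scope="session")
def tp53_catalog():
    return tj.builtin_tp53_catalog()


_HEADER = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "toy1", "LN": 50000}]}


def _make_record(cigar, pos, chrom="toy1", name="read", nm=0, flag=0, md=None):
    """Build an in-memory alignment record; ``pos`` is 1-based."""
    header = dict(_HEADER)
    if chrom != "toy1":
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": 10_000_000}]}
    rec = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
    rec.query_name = name
    rec.flag = flag
    rec.reference_id = 0
    rec.reference_start = pos - 1
    rec.mapping_quality = 60
    rec.cigarstring = cigar
    qlen = sum(
        length for op, length in rec.cigartuples if op in (0, 1, 4, 7, 8)
    )
    rec.query_sequence = "A" * qlen
    rec.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    if nm is not None:
        rec.set_tag("NM", nm, "i")
    if md is not None:
        rec.set_tag("MD", md, "Z")
    return rec


@pytest.fixture
def make_record():
    return _make_record


@pytest.fixture
def write_sam(tmp_path):
    """Write records to a SAM file and return its path."""

    def _write(records, name="reads.sam", chrom="toy1", length=50000):
        path = tmp_path / name
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": length}]}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for rec in records:
                out.write(rec)
        return path

    return _write
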