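import pysam
import pytest

from cqscreen import load_bundled_primers, make_marker_fixture


@pytest.fixture(scope="session")
def mar28():
    """The published Mar28 primer pair (Chr8 insertion-junction marker)."""
    return load_bundled_primers()["Mar28"]


@pytest.fixture(scope="session")
def marker_genome(mar28):
    """Fixture genome with a 305-bp Y-specific insertion strictly between
    the Mar28 primer sites of a 509-bp X-haplotype amplicon."""
    return make_marker_fixture(mar28.forward, mar28.reverse, x_amplicon_length=509, insertion_length=305)


def make_header(contigs):
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": n, "LN": l} for n, l in contigs]}
    )


def make_read(header, contig, pos, length=100, mapq=60, flag=0, name="r"):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_id = header.get_tid(contig)
    a.reference_start = pos
    a.mapping_quality = mapq
    a.cigarstring = f"{length}M"
    a.query_sequence = "A" * length
    return a


def brute_force_counts(reads, windows, filters):
    """Independent read x window double loop used as the counting oracle."""
    out = []
    for w in windows:
        c = 0
        for r in reads:
            if r.is_unmapped:
                continue
            if "secondary" in filters.exclude and r.is_secondary:
                continue
            if "supplementary" in filters.exclude and r.is_supplementary:
                continue
            if "duplicate" in filters.exclude and r.is_duplicate:
                continue
            if r.mapping_quality < filters.min_mapq:
                continue
            if r.reference_name != w.contig:
                continue
            if filters.assignment_mode == "start":
                if w.start <= r.reference_start < w.end:
                    c += 1
            else:
                if r.reference_start < w.end and r.reference_end > w.start:
                    c += 1
        out.append(c)
    return out
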