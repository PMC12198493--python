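import pysam
import pytest

from htkit.barcodes import default_lookup_tables
from htkit.layout import default_layout
from htkit.schema import SampleSchema
from htkit.simulate import random_reference


@pytest.fixture(scope="session")
def lookups():
    return default_lookup_tables()


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def schema4():
    return SampleSchema(
        id_segment="C",
        assignments={1: "sampleA", 2: "sampleB", 3: "sampleC", 4: "sampleD"},
    )


@pytest.fixture(scope="session")
def reference():
    # two contigs, big enough for tens of ~30 kb molecules
    return random_reference({"chr1": 700_000, "chr2": 500_000}, seed=101)


SAM_HEADER = {
    "HD": {"VN": "1.6", "SO": "coordinate"},
    "SQ": [{"SN": "chr1", "LN": 10_000_000}, {"SN": "chr2", "LN": 10_000_000}],
}


def make_record(
    header,
    name,
    contig,
    pos,
    bx=None,
    vx=None,
    flag=0,
    length=100,
    qual=30,
    cigar=None,
    mate_pos=None,
):
    """Build one aligned record for synthetic SAM files."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_id = header.references.index(contig)
    a.reference_start = pos
    a.flag = flag
    a.mapping_quality = 60
    a.query_sequence = "A" * length
    a.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * length)
    a.cigartuples = cigar or [(0, length)]
    if mate_pos is not None:
        a.next_reference_id = a.reference_id
        a.next_reference_start = mate_pos
    if bx is not None:
        a.set_tag("BX", bx, value_type="Z")
    if vx is not None:
        a.set_tag("VX", vx, value_type="i")
    return a


def write_sam(path, records):
    with pysam.AlignmentFile(str(path), "w", header=pysam.AlignmentHeader.from_dict(SAM_HEADER)) as out:
        for r in records:
            out.write(r)
    return path


@pytest.fixture()
def sam_header():
    return pysam.AlignmentHeader.from_dict(SAM_HEADER)
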