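import pytest

from tishunt.alignment_io import AlignedRecord, ReferenceSet, SaEntry, parse_cigar


@pytest.fixture
def refset() -> ReferenceSet:
    """Tiny joint reference: two host chromosomes plus a construct."""
    return ReferenceSet(
        sequences={
            "chr1": "ACGT" * 2500,  # 10 kb
            "chr2": "TTGCA" * 2000,  # 10 kb
            "tgx": "GATTACA" * 200,  # 1.4 kb construct
        },
        construct_name="tgx",
    )


def make_record(
    qname="r1",
    flag=0,
    rname="chr1",
    pos=100,
    mapq=60,
    cigar="100M",
    rnext="*",
    pnext=0,
    tlen=0,
    seq=None,
    sa=None,
):
    """Build an AlignedRecord from SAM-ish shorthand.

    ``sa`` is a list of (rname, pos, strand, cigar, mapq) tuples.
    """
    parsed = tuple(parse_cigar(cigar)) if cigar != "*" else ()
    if seq is None:
        qlen = sum(c.length for c in parsed if c.op in "MIS=X")
        seq = "A" * qlen if qlen else "*"
    entries = tuple(
        SaEntry(r, p, s, tuple(parse_cigar(c)), q) for (r, p, s, c, q) in (sa or [])
    )
    return AlignedRecord(
        qname=qname,
        flag=flag,
        rname=rname,
        pos=pos,
        mapq=mapq,
        cigar=parsed,
        rnext=rnext,
        pnext=pnext,
        tlen=tlen,
        seq=seq,
        sa=entries,
    )
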