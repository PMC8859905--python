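"""Discordant read-pair extraction.

A pair is discordant, in the transgene sense, when its two mates map to
different sides of the host/construct divide: the sequenced fragment
must then straddle an insertion junction.  Discordance is decided by
reference identity, not by insert size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .alignment_io import AlignedRecord, ReferenceSet, write_sam

logger = logging.getLogger("tishunt")

DEFAULT_MIN_MAPQ = 30


@dataclass(frozen=True, slots=True)
class DiscordantPair:
    """A read pair with one mate on the host and one on the construct."""

    qname: str
    host_chrom: str
    host_pos: int
    host_strand: str
    construct_pos: int
    construct_strand: str
    host_mapq: int
    construct_mapq: int


def _usable(rec: AlignedRecord) -> bool:
    return (
        rec.is_primary
        and rec.is_paired
        and not rec.is_unmapped
        and not rec.is_duplicate
        and not rec.is_qcfail
    )


def is_discordant(
    pair: tuple[AlignedRecord, AlignedRecord],
    refset: ReferenceSet,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> Optional[DiscordantPair]:
    """Classify a mate pair; returns evidence only when the mates straddle
    the host/construct divide and both meet the MAPQ threshold."""
    a, b = pair
    if a.qname != b.qname:
        raise ValueError(f"mates with mismatched qnames: {a.qname!r} vs {b.qname!r}")
    if not (_usable(a) and _usable(b)):
        return None
    if a.mapq < min_mapq or b.mapq < min_mapq:
        return None
    a_con = refset.is_construct(a.rname)
    b_con = refset.is_construct(b.rname)
    if a_con == b_con:  # both host or both construct
        return None
    host, con = (b, a) if a_con else (a, b)
    if not refset.is_host(host.rname):
        return None
    return DiscordantPair(
        qname=host.qname,
        host_chrom=host.rname,
        host_pos=host.pos,
        host_strand=host.strand,
        construct_pos=con.pos,
        construct_strand=con.strand,
        host_mapq=host.mapq,
        construct_mapq=con.mapq,
    )


def scan_discordant(
    alignments: Iterable[AlignedRecord],
    refset: ReferenceSet,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    out_sam: str | Path | None = None,
) -> list[DiscordantPair]:
    """Assemble discordant pairs from an alignment stream in one pass.

    Mates are paired by qname (mate-rank aware), so the result is
    invariant to record order.  Only records whose rname/rnext already
    straddle the divide are buffered, which bounds memory to the
    discordant candidates.  Orphan mates are counted and logged, never
    emitted.  When *out_sam* is given both mates of every emitted pair
    are written as a valid SAM file.
    """
    pairs: list[DiscordantPair] = []
    kept_records: list[AlignedRecord] = []
    waiting: dict[tuple[str, int], AlignedRecord] = {}
    for rec in alignments:
        if not _usable(rec):
            continue
        rnext = rec.rname if rec.rnext == "=" else rec.rnext
        if rnext == "*" or rec.rname not in refset.sequences:
            continue
        if refset.is_construct(rec.rname) == refset.is_construct(rnext):
            continue  # pair internal to one side; never discordant evidence
        mate_key = (rec.qname, 3 - rec.mate_index if rec.mate_index else 0)
        mate = waiting.pop(mate_key, None)
        if mate is None:
            waiting[(rec.qname, rec.mate_index)] = rec
            continue
        dp = is_discordant((mate, rec), refset, min_mapq)
        if dp is not None:
            pairs.append(dp)
            if out_sam is not None:
                kept_records.extend((mate, rec))
    if waiting:
        logger.info("discordant scan: %d orphan mates ignored", len(waiting))
    logger.info("discordant scan: %d discordant pairs", len(pairs))
    if out_sam is not None:
        kept_records.sort(key=lambda r: (r.rname, r.pos))
        write_sam(kept_records, out_sam, refset.sam_header())
    return pairs
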