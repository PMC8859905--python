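"""Chimeric (split) read extraction.

A chimeric read aligns partly to a host chromosome and partly to the
construct: the aligner emits a soft-clipped primary alignment on one
side plus a supplementary alignment on the other, cross-referenced
through the SA tag.  The clipped end of each alignment points at the
junction, so the first/last aligned base of the clipped record is the
breakpoint coordinate on that reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .alignment_io import (
    AlignedRecord,
    CigarOp,
    CLIP_OPS,
    ReferenceSet,
    SaEntry,
    reference_span,
)

logger = logging.getLogger("tishunt")

DEFAULT_MIN_MAPQ = 30  # mapping-quality threshold for chimeric extraction
DEFAULT_MIN_CLIP = 10  # minimum clip length considered junction evidence

CHIMERIC_COLUMNS = (
    "qname",
    "host_chrom",
    "host_junction",
    "host_strand",
    "construct_junction",
    "construct_strand",
    "clip_side",
)


@dataclass(frozen=True, slots=True)
class ChimericEvidence:
    """A split read linking a host coordinate to a construct coordinate."""

    qname: str
    host_chrom: str
    host_junction: int
    host_strand: str
    construct_junction: int
    construct_strand: str
    clip_side_on_host: str  # "left" | "right"
    mapq_host: int
    mapq_construct: int


def _clip_lengths(cigar: tuple[CigarOp, ...]) -> tuple[int, int]:
    left = cigar[0].length if cigar and cigar[0].op in CLIP_OPS else 0
    right = cigar[-1].length if len(cigar) > 1 and cigar[-1].op in CLIP_OPS else 0
    return left, right


def junction_from_cigar(
    pos: int, cigar: tuple[CigarOp, ...], min_clip: int = 1
) -> Optional[tuple[int, str]]:
    """Junction coordinate implied by the clipped end of an alignment.

    A left clip puts the junction at the first aligned base (``pos``); a
    right clip at the last (``pos + reference_span - 1``).  When both
    ends are clipped the longer clip decides, ties going left.  Returns
    ``None`` when no clip reaches *min_clip* — a not-chimeric signal.
    """
    left, right = _clip_lengths(cigar)
    if max(left, right) < min_clip:
        return None
    if left >= right:
        return pos, "left"
    return pos + reference_span(cigar) - 1, "right"


def _sa_junction(entry: SaEntry) -> Optional[tuple[int, str]]:
    return junction_from_cigar(entry.pos, entry.cigar, min_clip=1)


def is_chimeric(
    record: AlignedRecord,
    refset: ReferenceSet,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_clip: int = DEFAULT_MIN_CLIP,
) -> Optional[ChimericEvidence]:
    """Evaluate one primary alignment as transgene-junction evidence.

    Evidence requires (a) a clip of at least *min_clip* bases, (b) an SA
    partner on the other side of the host/construct divide, and (c)
    mapping quality of at least *min_mapq* on both the record and the
    partner.  Anything else returns ``None``.
    """
    if not record.is_primary or record.is_unmapped:
        return None
    if record.is_duplicate or record.is_qcfail:
        return None
    if record.rname not in refset.sequences:
        return None
    j = junction_from_cigar(record.pos, record.cigar, min_clip)
    if j is None:
        return None
    if record.mapq < min_mapq:
        return None
    record_on_construct = refset.is_construct(record.rname)
    partners = [
        e
        for e in record.sa
        if (refset.is_host(e.rname) if record_on_construct else refset.is_construct(e.rname))
    ]
    partners = [e for e in partners if e.mapq >= min_mapq]
    if not partners:
        return None
    partner = max(partners, key=lambda e: e.mapq)
    pj = _sa_junction(partner)
    if pj is None:
        return None
    coord, side = j
    p_coord, p_side = pj
    if record_on_construct:
        return ChimericEvidence(
            qname=record.qname,
            host_chrom=partner.rname,
            host_junction=p_coord,
            host_strand=partner.strand,
            construct_junction=coord,
            construct_strand=record.strand,
            clip_side_on_host=p_side,
            mapq_host=partner.mapq,
            mapq_construct=record.mapq,
        )
    return ChimericEvidence(
        qname=record.qname,
        host_chrom=record.rname,
        host_junction=coord,
        host_strand=record.strand,
        construct_junction=p_coord,
        construct_strand=partner.strand,
        clip_side_on_host=side,
        mapq_host=record.mapq,
        mapq_construct=partner.mapq,
    )


def _fallback_join(
    primaries: list[AlignedRecord],
    supplementaries: dict[tuple[str, int], list[AlignedRecord]],
) -> Iterable[AlignedRecord]:
    """Synthesize SA tags for primaries by joining supplementary lines on qname.

    Fallback for SAM files whose aligner did not emit SA tags; the
    supplementary partner is described exactly as an SA entry would.
    """
    for rec in primaries:
        partners = supplementaries.get((rec.qname, rec.mate_index), [])
        if not partners:
            continue
        sa = tuple(
            SaEntry(p.rname, p.pos, p.strand, p.cigar, p.mapq) for p in partners
        )
        yield AlignedRecord(
            qname=rec.qname,
            flag=rec.flag,
            rname=rec.rname,
            pos=rec.pos,
            mapq=rec.mapq,
            cigar=rec.cigar,
            rnext=rec.rnext,
            pnext=rec.pnext,
            tlen=rec.tlen,
            seq=rec.seq,
            qual=rec.qual,
            sa=sa,
        )


def scan_chimeric(
    alignments: Iterable[AlignedRecord],
    refset: ReferenceSet,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_clip: int = DEFAULT_MIN_CLIP,
    out_tsv: str | Path | None = None,
    sa_fallback: bool = True,
) -> list[ChimericEvidence]:
    """Collect chimeric evidence from an alignment stream over the joint reference.

    One evidence entry per qualifying primary record.  When *out_tsv* is
    given the evidence table is written tab-separated with a header line.
    """
    evidence: list[ChimericEvidence] = []
    pending: list[AlignedRecord] = []  # clipped primaries lacking SA
    supp: dict[tuple[str, int], list[AlignedRecord]] = {}
    n_low_mapq = 0
    for rec in alignments:
        if rec.is_unmapped or rec.is_duplicate or rec.is_qcfail:
            continue
        if rec.is_supplementary:
            if sa_fallback and not rec.is_secondary:
                supp.setdefault((rec.qname, rec.mate_index), []).append(rec)
            continue
        if not rec.is_primary:
            continue
        if rec.sa:
            ev = is_chimeric(rec, refset, min_mapq, min_clip)
            if ev is not None:
                evidence.append(ev)
            elif rec.mapq < min_mapq and junction_from_cigar(rec.pos, rec.cigar, min_clip):
                n_low_mapq += 1
        elif sa_fallback and junction_from_cigar(rec.pos, rec.cigar, min_clip):
            pending.append(rec)
    for rec in _fallback_join(pending, supp):
        ev = is_chimeric(rec, refset, min_mapq, min_clip)
        if ev is not None:
            evidence.append(ev)
    if n_low_mapq:
        logger.info("chimera scan: %d clipped reads skipped below MAPQ %d", n_low_mapq, min_mapq)
    logger.info("chimera scan: %d chimeric reads", len(evidence))
    if out_tsv is not None:
        write_chimeric_tsv(evidence, out_tsv)
    return evidence


def write_chimeric_tsv(evidence: Iterable[ChimericEvidence], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(CHIMERIC_COLUMNS) + "\n")
        for ev in evidence:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        ev.qname,
                        ev.host_chrom,
                        ev.host_junction,
                        ev.host_strand,
                        ev.construct_junction,
                        ev.construct_strand,
                        ev.clip_side_on_host,
                    )
                )
                + "\n"
            )
    return path
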