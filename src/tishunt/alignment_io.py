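"""Reference, annotation and alignment I/O.

All coordinates handled here are SAM-style 1-based inclusive unless a
function explicitly deals with BED input, which is converted at the
boundary.  The joint reference is the host genome with the transgene
construct appended as one extra sequence, so a single alignment pass
places reads on both sides of the host/construct divide.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("tishunt")

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class FormatError(ValueError):
    """A file violates its declared format (FASTA/BED/SAM/CIGAR)."""


class ConfigError(ValueError):
    """Inconsistent or incomplete run configuration."""


class UsabilityError(RuntimeError):
    """A usable input exists but needs a preparatory step (e.g. indexing)."""


# ---------------------------------------------------------------------------
# SAM flag bits
# ---------------------------------------------------------------------------

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800

# CIGAR operation classes (SAM v1.6)
CIGAR_OPS = "MIDNSHP=X"
QUERY_OPS = frozenset("MIS=X")  # consume read bases
REF_OPS = frozenset("MDN=X")  # consume reference bases
CLIP_OPS = frozenset("SH")
ALIGNED_OPS = frozenset("MD=X")  # bases counted for depth (N excluded)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_DNA_RE = re.compile(r"^[ACGTNacgtn]+$")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class CigarOp:
    length: int
    op: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise FormatError(f"CIGAR op with non-positive length: {self.length}{self.op}")
        if self.op not in CIGAR_OPS:
            raise FormatError(f"unknown CIGAR operation {self.op!r}")


def parse_cigar(text: str) -> list[CigarOp]:
    """Parse a CIGAR string; ``"*"`` yields an empty list."""
    if text == "*":
        return []
    ops: list[CigarOp] = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise FormatError(f"malformed CIGAR {text!r} at offset {pos}")
        ops.append(CigarOp(int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(text) or not ops:
        raise FormatError(f"malformed CIGAR {text!r}")
    return ops


def cigar_to_string(cigar: Sequence[CigarOp]) -> str:
    if not cigar:
        return "*"
    return "".join(f"{c.length}{c.op}" for c in cigar)


def reference_span(cigar: Sequence[CigarOp]) -> int:
    """Bases consumed on the reference (M/D/N/=/X)."""
    return sum(c.length for c in cigar if c.op in REF_OPS)


def query_length(cigar: Sequence[CigarOp]) -> int:
    """Bases consumed from the read sequence (M/I/S/=/X)."""
    return sum(c.length for c in cigar if c.op in QUERY_OPS)


def aligned_bases(cigar: Sequence[CigarOp]) -> int:
    """Reference bases counted toward depth (M/D/=/X; N skipped)."""
    return sum(c.length for c in cigar if c.op in ALIGNED_OPS)


@dataclass(frozen=True, slots=True)
class SaEntry:
    """One supplementary-alignment descriptor from an SA tag."""

    rname: str
    pos: int
    strand: str
    cigar: tuple[CigarOp, ...]
    mapq: int
    nm: int = 0

    def to_text(self) -> str:
        return f"{self.rname},{self.pos},{self.strand},{cigar_to_string(self.cigar)},{self.mapq},{self.nm}"


def parse_sa_tag(text: str) -> tuple[SaEntry, ...]:
    """Parse the semicolon-separated SA optional field."""
    entries = []
    for chunk in text.rstrip(";").split(";"):
        if not chunk:
            continue
        parts = chunk.split(",")
        if len(parts) < 5:
            raise FormatError(f"malformed SA descriptor {chunk!r}")
        nm = int(parts[5]) if len(parts) > 5 else 0
        entries.append(
            SaEntry(parts[0], int(parts[1]), parts[2], tuple(parse_cigar(parts[3])), int(parts[4]), nm)
        )
    return tuple(entries)


@dataclass(slots=True)
class AlignedRecord:
    """One SAM alignment line with parsed CIGAR, flags and SA tag."""

    qname: str
    flag: int
    rname: str
    pos: int  # 1-based leftmost mapped base; 0 for unmapped
    mapq: int
    cigar: tuple[CigarOp, ...]
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    sa: tuple[SaEntry, ...] = ()

    def __post_init__(self) -> None:
        if self.seq != "*" and self.cigar:
            qlen = query_length(self.cigar)
            if qlen != len(self.seq):
                raise FormatError(
                    f"read {self.qname}: CIGAR query length {qlen} != sequence length {len(self.seq)}"
                )
        if not self.is_unmapped and self.pos < 1:
            raise FormatError(f"read {self.qname}: mapped record with pos {self.pos}")

    # flag helpers ---------------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUP)

    @property
    def is_qcfail(self) -> bool:
        return bool(self.flag & FLAG_QCFAIL)

    @property
    def is_primary(self) -> bool:
        return not (self.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY))

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    @property
    def mate_index(self) -> int:
        """1 for first-in-pair, 2 for second, 0 for unpaired."""
        if self.flag & FLAG_READ1:
            return 1
        if self.flag & FLAG_READ2:
            return 2
        return 0

    @property
    def reference_end(self) -> int:
        """1-based inclusive rightmost mapped base."""
        return self.pos + reference_span(self.cigar) - 1

    def to_sam_line(self) -> str:
        rnext = "=" if (self.rnext == self.rname and self.rnext != "*") else self.rnext
        fields = [
            self.qname,
            str(self.flag),
            self.rname,
            str(self.pos),
            str(self.mapq),
            cigar_to_string(self.cigar),
            rnext,
            str(self.pnext),
            str(self.tlen),
            self.seq,
            self.qual,
        ]
        if self.sa:
            fields.append("SA:Z:" + "".join(e.to_text() + ";" for e in self.sa))
        return "\t".join(fields)


@dataclass(frozen=True)
class ReferenceSet:
    """Host sequences plus the construct, with the construct singled out."""

    sequences: dict[str, str]
    construct_name: str

    def __post_init__(self) -> None:
        if self.construct_name not in self.sequences:
            raise ConfigError(f"construct {self.construct_name!r} not among sequences")
        if len(self.sequences) < 2:
            raise ConfigError("reference set needs at least one host sequence")
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence {name!r}")
            if not _DNA_RE.match(seq):
                raise FormatError(f"sequence {name!r} contains non-ACGTN characters")

    @property
    def host_names(self) -> list[str]:
        return [n for n in self.sequences if n != self.construct_name]

    @property
    def construct_sequence(self) -> str:
        return self.sequences[self.construct_name]

    @property
    def construct_length(self) -> int:
        return len(self.construct_sequence)

    def is_construct(self, rname: str) -> bool:
        return rname == self.construct_name

    def is_host(self, rname: str) -> bool:
        return rname in self.sequences and rname != self.construct_name

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.sequences.items()}

    def sam_header(self) -> str:
        lines = ["@HD\tVN:1.6\tSO:coordinate"]
        for name, seq in self.sequences.items():
            lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
        return "\n".join(lines)


@dataclass(frozen=True)
class Feature:
    name: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive


@dataclass(frozen=True)
class ConstructAnnotation:
    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise FormatError("construct feature names are not unique")


# ---------------------------------------------------------------------------
# FASTA / BED
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence map.

    Names are taken from the header up to the first whitespace.  A file
    with sequence data before any header, or a record with an empty
    sequence, raises :class:`FormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
    if head and head != ">" and not head.isspace():
        raise FormatError(f"{path}: not FASTA (first character {head!r}, expected '>')")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in out:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        out[rec.id] = seq
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
    return path


def build_joint_reference(
    host_fasta: str | Path,
    construct_fasta: str | Path,
    out_fasta: str | Path | None = None,
) -> ReferenceSet:
    """Append the construct to the host genome as one extra sequence.

    Host sequence order is preserved; the construct comes last.  When
    *out_fasta* is given the joint FASTA is written to disk together with
    a ``<out>.construct.txt`` sidecar naming the construct sequence.
    """
    host = read_fasta(host_fasta)
    construct = read_fasta(construct_fasta)
    if len(construct) != 1:
        raise ConfigError(
            f"construct FASTA must hold exactly one sequence, found {len(construct)}"
        )
    (cname, cseq), = construct.items()
    if cname in host:
        raise ConfigError(f"construct name {cname!r} collides with a host sequence name")
    joint = dict(host)
    joint[cname] = cseq
    refset = ReferenceSet(sequences=joint, construct_name=cname)
    if out_fasta is not None:
        out_fasta = Path(out_fasta)
        write_fasta(joint, out_fasta)
        sidecar = out_fasta.with_suffix(out_fasta.suffix + ".construct.txt")
        sidecar.write_text(cname + "\n")
    return refset


def read_construct_bed(path: str | Path, construct_length: int) -> ConstructAnnotation:
    """Read BED3+name construct features, validated against the construct length.

    BED half-open 0-based intervals are preserved as-is in the annotation.
    """
    path = Path(path)
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: need chrom/start/end/name columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
            if end > construct_length:
                raise FormatError(
                    f"{path}:{lineno}: interval end {end} beyond construct length {construct_length}"
                )
            feats.append(Feature(parts[3], start, end))
    return ConstructAnnotation(features=tuple(feats))


# ---------------------------------------------------------------------------
# SAM / BAM streaming
# ---------------------------------------------------------------------------


def _from_pysam(seg: pysam.AlignedSegment) -> AlignedRecord:
    sa: tuple[SaEntry, ...] = ()
    if seg.has_tag("SA"):
        sa = parse_sa_tag(seg.get_tag("SA"))
    return AlignedRecord(
        qname=seg.query_name or "*",
        flag=seg.flag,
        rname=seg.reference_name or "*",
        pos=(seg.reference_start + 1) if seg.reference_start is not None and not seg.is_unmapped else 0,
        mapq=seg.mapping_quality,
        cigar=tuple(parse_cigar(seg.cigarstring)) if seg.cigarstring else (),
        rnext=seg.next_reference_name or "*",
        pnext=(seg.next_reference_start + 1) if seg.next_reference_start is not None and seg.next_reference_start >= 0 else 0,
        tlen=seg.template_length,
        seq=seg.query_sequence or "*",
        qual="*",
        sa=sa,
    )


def stream_alignments(
    path: str | Path, region: str | None = None
) -> Iterator[AlignedRecord]:
    """Stream SAM/BAM records as :class:`AlignedRecord`.

    Secondary alignments (flag 0x100) are dropped at read time — only
    primary alignments are considered as evidence; supplementary lines
    (0x800) pass through for SA cross-checking.  A *region* query
    (``chrom:start-end``, 1-based) requires a coordinate-sorted, indexed
    BAM and raises :class:`UsabilityError` if the index is missing.
    """
    path = str(path)
    mode = "rb" if path.endswith((".bam", ".cram")) else "r"
    save = pysam.set_verbosity(0)
    try:
        afile = pysam.AlignmentFile(path, mode, check_sq=False)
    finally:
        pysam.set_verbosity(save)
    with afile:
        known = set(afile.references or ())
        if region is not None:
            try:
                it = afile.fetch(region=region)
            except ValueError as exc:
                raise UsabilityError(
                    f"{path}: region queries need a coordinate-sorted, indexed BAM "
                    f"(samtools sort && samtools index): {exc}"
                ) from exc
        else:
            it = afile.fetch(until_eof=True)
        try:
            for seg in it:
                if seg.flag & FLAG_SECONDARY:
                    continue
                # htslib downgrades an unknown rname to unmapped (setting 0x4);
                # a CIGAR-bearing "unmapped" record with no resolvable
                # reference is a header/body mismatch, not a real unmapped read
                if seg.reference_id < 0 and seg.cigarstring:
                    raise FormatError(
                        f"{path}: record {seg.query_name} names a reference "
                        f"absent from the header"
                    )
                if not seg.is_unmapped and seg.reference_name not in known:
                    raise FormatError(
                        f"{path}: record {seg.query_name} names reference "
                        f"{seg.reference_name!r} absent from header"
                    )
                yield _from_pysam(seg)
        except ValueError as exc:  # pysam parse failure mid-stream
            raise FormatError(f"{path}: {exc}") from exc


def alignment_references(path: str | Path) -> list[str]:
    """Reference names declared in a SAM/BAM header."""
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as afile:
        return list(afile.references or ())


def write_sam(records: Iterable[AlignedRecord], path: str | Path, header: str) -> Path:
    """Write records as SAM text under the given header block."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header.rstrip("\n") + "\n")
        for rec in records:
            fh.write(rec.to_sam_line() + "\n")
    return path
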