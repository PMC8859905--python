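"""Ground-truth transgenesis simulator.

Generates everything the detection pipeline consumes, with the truth
recorded: random host chromosomes and a construct, a donor genome with
the construct planted at known positions (forward or reverse, optional
tandem copies, optional host deletion at the junction), paired-end reads
at a chosen coverage, and the ideal alignments a local aligner would
produce against the joint reference — soft-clipped primaries with SA
tags for junction-spanning reads and correctly discordant mate fields
for junction-straddling pairs.

Because the donor-to-reference coordinate map is known exactly, the
alignments are computed rather than inferred, which makes breakpoint
recovery testable at single-base resolution without an external aligner.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alignment_io import (
    AlignedRecord,
    CigarOp,
    ConfigError,
    ReferenceSet,
    SaEntry,
    write_sam,
)

logger = logging.getLogger("tishunt")

DEFAULT_CONSTRUCT_LEN = 9389
DEFAULT_CHROM_LEN = 100_000
DEFAULT_N_CHROM = 2
DEFAULT_COVERAGE = 50.0
DEFAULT_READ_LEN = 150
DEFAULT_INSERT_MEAN = 400
DEFAULT_INSERT_SD = 50
DEFAULT_MIN_ANCHOR = 10  # aligned bases needed for a split segment to be reported
BASE_QUALITY_CHAR = "F"  # constant Q37

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

TRUTH_COLUMNS = (
    "chrom",
    "bp1",
    "bp2",
    "orientation",
    "n_tandem",
    "host_deletion",
    "fragment_start",
    "fragment_end",
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Specs and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class InsertionSpec:
    """One planted insertion: the construct (or a fragment of it) goes in
    after ``host_pos``, optionally deleting host bases at the junction."""

    chrom: str
    host_pos: int  # 1-based host base after which the insert begins
    orientation: str = "forward"  # forward | reverse
    n_tandem: int = 1
    host_deletion: int = 0
    fragment: Optional[tuple[int, int]] = None  # 1-based inclusive construct interval

    def resolved_fragment(self, construct_len: int) -> tuple[int, int]:
        frag = self.fragment or (1, construct_len)
        lo, hi = frag
        if not (1 <= lo <= hi <= construct_len):
            raise ConfigError(f"fragment {frag} outside construct 1..{construct_len}")
        return lo, hi


@dataclass(frozen=True, slots=True)
class SimTruth:
    """Ground truth implied by one insertion spec."""

    spec: InsertionSpec
    expected_breakpoints: tuple[int, int]  # host coordinates flanking the insert
    expected_transgene_region: tuple[int, int]  # construct coord at left/right junction
    donor_length: int


@dataclass(slots=True)
class ReadPairSim:
    """One simulated fragment with both mates as sequenced."""

    qname: str
    chrom: str  # donor chromosome of origin
    frag_start: int  # 1-based donor coordinate of the fragment
    frag_len: int
    seq1: str
    seq2: str

    @property
    def read_len(self) -> int:
        return len(self.seq1)

    def mate_interval(self, mate: int) -> tuple[int, int, str]:
        """Donor interval (1-based inclusive) and strand of a mate."""
        if mate == 1:
            return self.frag_start, self.frag_start + self.read_len - 1, "+"
        end = self.frag_start + self.frag_len - 1
        return end - self.read_len + 1, end, "-"


@dataclass(frozen=True, slots=True)
class _Segment:
    """Maps donor interval [d_start, d_end] onto reference coordinates.

    For strand '+', donor base d maps to r_start + (d - d_start); for
    '-', to r_end - (d - d_start).
    """

    d_start: int
    d_end: int
    ref: str
    r_start: int
    r_end: int
    strand: str

    def ref_at(self, d: int) -> int:
        if self.strand == "+":
            return self.r_start + (d - self.d_start)
        return self.r_end - (d - self.d_start)


@dataclass(slots=True)
class DonorGenome:
    """A modified host genome with its truth set and coordinate map."""

    sequences: dict[str, str]
    truths: list[SimTruth]
    segments: dict[str, list[_Segment]]  # per donor chromosome, sorted

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------


def random_references(
    seed: int,
    n_chrom: int = DEFAULT_N_CHROM,
    chrom_len: int = DEFAULT_CHROM_LEN,
    construct_len: int = DEFAULT_CONSTRUCT_LEN,
    gc: float = 0.5,
    construct_name: str = "construct",
    repeat_block_len: int = 0,
) -> ReferenceSet:
    """Random host chromosomes plus a construct, deterministic per seed.

    Sequences are i.i.d. with the given GC fraction — repeat-free by
    default.  ``repeat_block_len`` > 0 embeds a copy of the construct
    prefix into the middle of chr1, recreating the shared-sequence
    situation that makes real aligners multimap.
    """
    if chrom_len < 1000 or construct_len < 1000:
        raise ConfigError("sequences must be at least 1000 bp for meaningful junction reads")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"AGCT", dtype="S1")

    def draw(n: int) -> str:
        return rng.choice(alphabet, size=n, p=p).tobytes().decode()

    seqs = {f"chr{i + 1}": draw(chrom_len) for i in range(n_chrom)}
    construct = draw(construct_len)
    if repeat_block_len > 0:
        block = construct[:repeat_block_len]
        mid = chrom_len // 2
        chr1 = seqs["chr1"]
        seqs["chr1"] = chr1[:mid] + block + chr1[mid + len(block):]
    seqs[construct_name] = construct
    return ReferenceSet(sequences=seqs, construct_name=construct_name)


# ---------------------------------------------------------------------------
# Insertion planting
# ---------------------------------------------------------------------------


def _validate_spec(spec: InsertionSpec, refset: ReferenceSet) -> None:
    if not refset.is_host(spec.chrom):
        raise ConfigError(f"insertion chromosome {spec.chrom!r} is not a host sequence")
    clen = len(refset.sequences[spec.chrom])
    if not (1 <= spec.host_pos < clen):
        raise ConfigError(f"host_pos {spec.host_pos} outside {spec.chrom} (1..{clen - 1})")
    if spec.host_deletion < 0 or spec.host_pos + spec.host_deletion >= clen:
        raise ConfigError("host deletion runs past the chromosome end")
    if spec.n_tandem < 1:
        raise ConfigError("n_tandem must be >= 1")
    if spec.orientation not in ("forward", "reverse"):
        raise ConfigError(f"unknown orientation {spec.orientation!r}")
    spec.resolved_fragment(refset.construct_length)


def plant_insertions(refset: ReferenceSet, specs: Sequence[InsertionSpec]) -> DonorGenome:
    """Build the donor genome for any number of insertions.

    Insertions on the same chromosome must not overlap (position plus
    deletion).  Returns the donor sequences, one :class:`SimTruth` per
    spec, and the donor-to-reference segment map used by
    :func:`ideal_alignments`.
    """
    for spec in specs:
        _validate_spec(spec, refset)
    by_chrom: dict[str, list[InsertionSpec]] = {}
    for spec in specs:
        by_chrom.setdefault(spec.chrom, []).append(spec)
    for chrom, chrom_specs in by_chrom.items():
        chrom_specs.sort(key=lambda s: s.host_pos)
        for a, b in zip(chrom_specs, chrom_specs[1:]):
            if a.host_pos + a.host_deletion >= b.host_pos:
                raise ConfigError(f"overlapping insertions on {chrom}")

    donor_seqs: dict[str, str] = {}
    segments: dict[str, list[_Segment]] = {}
    truths: list[SimTruth] = []
    cseq = refset.construct_sequence
    cname = refset.construct_name

    for chrom in refset.host_names:
        host = refset.sequences[chrom]
        chrom_specs = by_chrom.get(chrom, [])
        parts: list[str] = []
        segs: list[_Segment] = []
        d_cursor = 1  # next donor coordinate
        h_cursor = 1  # next unconsumed host coordinate

        def emit_host(h_from: int, h_to: int) -> None:
            nonlocal d_cursor
            if h_to < h_from:
                return
            n = h_to - h_from + 1
            parts.append(host[h_from - 1 : h_to])
            segs.append(_Segment(d_cursor, d_cursor + n - 1, chrom, h_from, h_to, "+"))
            d_cursor += n

        for spec in chrom_specs:
            emit_host(h_cursor, spec.host_pos)
            lo, hi = spec.resolved_fragment(refset.construct_length)
            frag = cseq[lo - 1 : hi]
            ins = frag if spec.orientation == "forward" else revcomp(frag)
            strand = "+" if spec.orientation == "forward" else "-"
            for _ in range(spec.n_tandem):
                parts.append(ins)
                segs.append(_Segment(d_cursor, d_cursor + len(ins) - 1, cname, lo, hi, strand))
                d_cursor += len(ins)
            h_cursor = spec.host_pos + spec.host_deletion + 1
            bp = (spec.host_pos, spec.host_pos + spec.host_deletion + 1)
            tg = (lo, hi) if spec.orientation == "forward" else (hi, lo)
            truths.append(SimTruth(spec, bp, tg, 0))
        emit_host(h_cursor, len(host))
        donor_seqs[chrom] = "".join(parts)
        segments[chrom] = segs

    total = sum(len(s) for s in donor_seqs.values())
    truths = [replace(t, donor_length=total) for t in truths]
    return DonorGenome(sequences=donor_seqs, truths=truths, segments=segments)


def plant_insertion(refset: ReferenceSet, spec: InsertionSpec) -> tuple[DonorGenome, SimTruth]:
    """Single-insertion convenience wrapper around :func:`plant_insertions`."""
    donor = plant_insertions(refset, [spec])
    return donor, donor.truths[0]


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def expected_pair_count(coverage: float, genome_len: int, read_len: int) -> int:
    return int(round(coverage * genome_len / (2 * read_len)))


def simulate_pairs(
    donor: DonorGenome | dict[str, str],
    coverage: float = DEFAULT_COVERAGE,
    read_len: int = DEFAULT_READ_LEN,
    insert_mean: float = DEFAULT_INSERT_MEAN,
    insert_sd: float = DEFAULT_INSERT_SD,
    error_rate: float = 0.0,
    seed: int = 0,
    fastq_prefix: str | Path | None = None,
) -> list[ReadPairSim]:
    """Draw paired-end fragments uniformly from the donor genome.

    Fragment count per chromosome is coverage × length / (2 × read
    length); fragment lengths are normal(insert_mean, insert_sd)
    truncated below at the read length; mate 2 is the reverse complement
    of the fragment end.  Substitution errors are i.i.d. per base at
    *error_rate*.  Deterministic per seed.  When *fastq_prefix* is given,
    ``<prefix>_1.fastq`` / ``<prefix>_2.fastq`` are written.
    """
    if insert_mean < read_len:
        raise ConfigError("insert_mean must be at least read_len")
    if coverage <= 0:
        raise ConfigError("coverage must be positive")
    seqs = donor.sequences if isinstance(donor, DonorGenome) else donor
    rng = np.random.default_rng(seed)
    pairs: list[ReadPairSim] = []
    for chrom, seq in seqs.items():
        clen = len(seq)
        n = expected_pair_count(coverage, clen, read_len)
        if n == 0:
            continue
        lengths = rng.normal(insert_mean, insert_sd, size=n)
        lengths = np.clip(np.rint(lengths), read_len, clen).astype(np.int64)
        starts = rng.integers(1, clen - lengths + 2)  # 1-based inclusive
        for i in range(n):
            s, fl = int(starts[i]), int(lengths[i])
            frag = seq[s - 1 : s - 1 + fl]
            seq1 = frag[:read_len]
            seq2 = revcomp(frag[-read_len:])
            pairs.append(ReadPairSim(f"sim:{chrom}:{i}", chrom, s, fl, seq1, seq2))
    if error_rate > 0:
        _apply_errors(pairs, error_rate, rng)
    if fastq_prefix is not None:
        write_fastq(pairs, fastq_prefix)
    logger.info("simulated %d read pairs at %.1fX", len(pairs), coverage)
    return pairs


def _apply_errors(pairs: list[ReadPairSim], rate: float, rng: np.random.Generator) -> None:
    bases = "ACGT"
    for pair in pairs:
        for attr in ("seq1", "seq2"):
            seq = getattr(pair, attr)
            n_err = rng.binomial(len(seq), rate)
            if n_err == 0:
                continue
            positions = rng.choice(len(seq), size=n_err, replace=False)
            chars = list(seq)
            for p in positions:
                choices = bases.replace(chars[p], "") or bases
                chars[p] = choices[rng.integers(len(choices))]
            setattr(pair, attr, "".join(chars))


def write_fastq(pairs: Sequence[ReadPairSim], prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    p1 = prefix.parent / (prefix.name + "_1.fastq")
    p2 = prefix.parent / (prefix.name + "_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for pair in pairs:
            q1 = BASE_QUALITY_CHAR * len(pair.seq1)
            q2 = BASE_QUALITY_CHAR * len(pair.seq2)
            f1.write(f"@{pair.qname}/1\n{pair.seq1}\n+\n{q1}\n")
            f2.write(f"@{pair.qname}/2\n{pair.seq2}\n+\n{q2}\n")
    return p1, p2


# ---------------------------------------------------------------------------
# Ideal alignments
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class _Run:
    """A maximal read stretch mapping contiguously to one reference."""

    read_a: int  # 0-based inclusive, in sequencing orientation
    read_b: int
    ref: str
    r_lo: int  # smallest reference coordinate covered
    strand: str  # combined read×segment strand

    @property
    def length(self) -> int:
        return self.read_b - self.read_a + 1


def _map_mate(
    segments: list[_Segment],
    seg_starts: list[int],
    d_start: int,
    d_end: int,
    read_strand: str,
) -> list[_Run]:
    """Partition a mate's donor interval into per-reference runs."""
    runs: list[_Run] = []
    idx = bisect.bisect_right(seg_starts, d_start) - 1
    d = d_start
    while d <= d_end:
        seg = segments[idx]
        lo = max(d, seg.d_start)
        hi = min(d_end, seg.d_end)
        if read_strand == "+":
            a, b = lo - d_start, hi - d_start
        else:
            a, b = d_end - hi, d_end - lo
        strand = "+" if (read_strand == "+") == (seg.strand == "+") else "-"
        r1, r2 = seg.ref_at(lo), seg.ref_at(hi)
        runs.append(_Run(a, b, seg.ref, min(r1, r2), strand))
        d = hi + 1
        idx += 1
    runs.sort(key=lambda r: r.read_a)
    return runs


def _run_record(
    run: _Run,
    seq: str,
    qname: str,
    mate: int,
    primary: bool,
) -> AlignedRecord:
    L = len(seq)
    a, b = run.read_a, run.read_b
    if run.strand == "+":
        pre, post = a, L - 1 - b
        stored = seq
    else:
        pre, post = L - 1 - b, a
        stored = revcomp(seq)
    cigar: list[CigarOp] = []
    if pre:
        cigar.append(CigarOp(pre, "S"))
    cigar.append(CigarOp(b - a + 1, "M"))
    if post:
        cigar.append(CigarOp(post, "S"))
    flag = 0x1 | (0x40 if mate == 1 else 0x80)
    if run.strand == "-":
        flag |= 0x10
    if not primary:
        flag |= 0x800
    return AlignedRecord(
        qname=qname,
        flag=flag,
        rname=run.ref,
        pos=run.r_lo,
        mapq=60,
        cigar=tuple(cigar),
        seq=stored,
        qual=BASE_QUALITY_CHAR * L,
    )


def ideal_alignments(
    pairs: Sequence[ReadPairSim],
    refset: ReferenceSet,
    donor: DonorGenome,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    out_sam: str | Path | None = None,
) -> list[AlignedRecord]:
    """Alignments a local aligner would ideally produce on the joint reference.

    Each mate is mapped through the known donor coordinate map.  A mate
    spanning a junction becomes a soft-clipped primary alignment on its
    longest segment plus supplementary alignments for the others, all
    cross-referenced via SA tags; segments shorter than *min_anchor*
    aligned bases are dropped, leaving a plain unannotated clip.  Mates
    straddling a junction make the pair's rname/rnext discordant.  MAPQ
    is fixed at 60 and flags, tlen and mate fields are kept consistent.
    """
    seg_starts = {c: [s.d_start for s in segs] for c, segs in donor.segments.items()}
    records: list[AlignedRecord] = []
    for pair in pairs:
        mate_records: list[list[AlignedRecord]] = []
        for mate in (1, 2):
            s, e, strand = pair.mate_interval(mate)
            seq = pair.seq1 if mate == 1 else pair.seq2
            runs = _map_mate(donor.segments[pair.chrom], seg_starts[pair.chrom], s, e, strand)
            runs = [r for r in runs if r.length >= min_anchor]
            if not runs:
                mate_records.append([])
                continue
            primary_idx = max(range(len(runs)), key=lambda i: runs[i].length)
            recs = [
                _run_record(run, seq, pair.qname, mate, i == primary_idx)
                for i, run in enumerate(runs)
            ]
            if len(recs) > 1:
                sa_entries = [
                    SaEntry(r.rname, r.pos, "-" if r.is_reverse else "+", r.cigar, r.mapq)
                    for r in recs
                ]
                for i, r in enumerate(recs):
                    r.sa = tuple(e for j, e in enumerate(sa_entries) if j != i)
            # put the primary first for mate-field lookup
            recs.insert(0, recs.pop(primary_idx))
            mate_records.append(recs)
        p1 = mate_records[0][0] if mate_records[0] else None
        p2 = mate_records[1][0] if mate_records[1] else None
        for my, other in ((p1, p2), (p2, p1)):
            if my is None:
                continue
            group = mate_records[0] if my is p1 else mate_records[1]
            for rec in group:
                if other is not None:
                    rec.rnext = other.rname
                    rec.pnext = other.pos
                    if other.is_reverse:
                        rec.flag |= 0x20
                    if my.rname == other.rname:
                        rec.flag |= 0x2
                        left = min(my.pos, other.pos)
                        right = max(my.reference_end, other.reference_end)
                        tlen = right - left + 1
                        rec.tlen = tlen if rec.pos == left else -tlen
                else:
                    rec.flag |= 0x8
        for group in mate_records:
            records.extend(group)
    order = {name: i for i, name in enumerate(refset.sequences)}
    records.sort(key=lambda r: (order.get(r.rname, len(order)), r.pos))
    if out_sam is not None:
        write_sam(records, out_sam, refset.sam_header())
    return records


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------


def write_truth(truths: Sequence[SimTruth], path: str | Path) -> Path:
    if not truths:
        raise ConfigError("no truth records to write")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.spec.chrom,
                        t.expected_breakpoints[0],
                        t.expected_breakpoints[1],
                        t.spec.orientation,
                        t.spec.n_tandem,
                        t.spec.host_deletion,
                        min(t.expected_transgene_region),
                        max(t.expected_transgene_region),
                    )
                )
                + "\n"
            )
    return path


def read_truth(path: str | Path) -> list[dict]:
    """Round-trip reader for the truth table (values as ints/strings)."""
    rows: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(header, vals))
            for k in ("bp1", "bp2", "n_tandem", "host_deletion", "fragment_start", "fragment_end"):
                row[k] = int(row[k])
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# One-call dataset builder
# ---------------------------------------------------------------------------


def simulate_dataset(
    seed: int,
    specs: Sequence[InsertionSpec] | None = None,
    n_chrom: int = DEFAULT_N_CHROM,
    chrom_len: int = DEFAULT_CHROM_LEN,
    construct_len: int = DEFAULT_CONSTRUCT_LEN,
    coverage: float = DEFAULT_COVERAGE,
    read_len: int = DEFAULT_READ_LEN,
    insert_mean: float = DEFAULT_INSERT_MEAN,
    insert_sd: float = DEFAULT_INSERT_SD,
    error_rate: float = 0.0,
    repeat_block_len: int = 0,
) -> tuple[ReferenceSet, DonorGenome, list[AlignedRecord]]:
    """References, donor and ideal alignments in one deterministic call.

    Without explicit *specs*, one full-length forward insertion is
    planted mid-chr1.
    """
    refset = random_references(
        seed, n_chrom=n_chrom, chrom_len=chrom_len, construct_len=construct_len,
        repeat_block_len=repeat_block_len,
    )
    if specs is None:
        specs = [InsertionSpec(chrom="chr1", host_pos=chrom_len // 2)]
    donor = plant_insertions(refset, specs)
    pairs = simulate_pairs(
        donor,
        coverage=coverage,
        read_len=read_len,
        insert_mean=insert_mean,
        insert_sd=insert_sd,
        error_rate=error_rate,
        seed=seed + 1,
    )
    records = ideal_alignments(pairs, refset, donor)
    return refset, donor, records
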