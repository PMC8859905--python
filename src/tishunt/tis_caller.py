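"""Transgene insertion-site calling.

Turns chimeric and discordant evidence into ranked candidates.  Every
host chromosome carrying at least one chimeric read becomes exactly one
candidate whose region is delimited by the outermost chimeric junctions;
split-read junctions are collapsed into at most two breakpoints; the
candidate is scored as

    prediction score = n_chimeric + n_discordant / 1000

so split-read evidence outranks pair evidence a thousandfold and, for
fewer than 1000 discordant pairs, the integer part of the score reads
off the chimeric count directly.  Multiple insertions on one chromosome
are deliberately not split apart.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .alignment_io import ReferenceSet
from .chimera_scan import ChimericEvidence
from .discordant_scan import DiscordantPair

logger = logging.getLogger("tishunt")

DEFAULT_COLLAPSE_WINDOW = 10  # bp; junction-jitter clustering
DEFAULT_DISCORDANT_WINDOW = 5000  # bp around breakpoints for pair support

UNKNOWN = "Unk"

CANDIDATE_COLUMNS = (
    "chrom",
    "region_start",
    "region_end",
    "span",
    "n_chimeric",
    "n_discordant",
    "score",
    "orientation",
    "transgene_start",
    "transgene_end",
)


@dataclass(frozen=True, slots=True)
class Breakpoint:
    chrom: str
    pos: int
    n_chimeric_support: int
    construct_pos: Optional[int]  # None when the construct side is unknown


@dataclass(slots=True)
class TisCandidate:
    chrom: str
    region_start: int
    region_end: int
    breakpoints: list[Breakpoint]
    n_chimeric: int
    n_discordant: int
    score: float
    orientation: str  # forward | reverse | unknown
    transgene_start: Optional[int]
    transgene_end: Optional[int]

    @property
    def span(self) -> int:
        return self.region_end - self.region_start


def prediction_score(n_chimeric: int, n_discordant: int) -> float:
    """Ranking statistic: chimeric reads + discordant pairs / 1000."""
    if n_chimeric < 0 or n_discordant < 0:
        raise ValueError("support counts must be non-negative")
    return n_chimeric + n_discordant / 1000


def format_score(score: float) -> str:
    return f"{score:.3f}"


def delimit_candidates(
    chimeric: Sequence[ChimericEvidence],
) -> list[tuple[str, int, int, list[ChimericEvidence]]]:
    """One candidate region per host chromosome bearing chimeric evidence.

    The outermost chimeric host junctions delimit the region.
    """
    by_chrom: dict[str, list[ChimericEvidence]] = {}
    for ev in chimeric:
        by_chrom.setdefault(ev.host_chrom, []).append(ev)
    out = []
    for chrom in sorted(by_chrom):
        subset = by_chrom[chrom]
        positions = [e.host_junction for e in subset]
        out.append((chrom, min(positions), max(positions), subset))
    return out


def _cluster_positions(positions: Sequence[int], window: int) -> list[list[int]]:
    """Single-linkage clustering of sorted positions: a gap > window splits."""
    if not positions:
        return []
    ordered = sorted(positions)
    clusters = [[ordered[0]]]
    for p in ordered[1:]:
        if p - clusters[-1][-1] <= window:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def _mode(values: Iterable[int]) -> int:
    """Most common value; ties broken toward the smallest."""
    counts = Counter(values)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def call_breakpoints(
    evidence: Sequence[ChimericEvidence],
    collapse_window: int = DEFAULT_COLLAPSE_WINDOW,
) -> list[Breakpoint]:
    """Collapse host junctions into at most two breakpoint clusters.

    Junctions within *collapse_window* bp are merged to absorb alignment
    jitter at microhomology, but only within the same host clip side: a
    right-clipped host alignment sits on the left flank of the insertion
    and a left-clipped one on the right flank, so the two true junctions
    of a clean insertion — adjacent or even overlapping host positions —
    are never merged into one.  When both flanks carry evidence the
    best-supported cluster on each is reported; otherwise the two
    best-supported clusters overall.  Each breakpoint reports the modal
    host position and the modal construct coordinate of its members.
    Returned sorted by host position.
    """
    if not evidence:
        return []
    chrom = evidence[0].host_chrom
    sided: list[tuple[str, list[Breakpoint]]] = []
    for side in ("right", "left"):  # right clip = left flank first
        side_ev = [e for e in evidence if e.clip_side_on_host == side]
        if not side_ev:
            continue
        by_junction: dict[int, list[ChimericEvidence]] = {}
        for ev in side_ev:
            by_junction.setdefault(ev.host_junction, []).append(ev)
        clusters = _cluster_positions([e.host_junction for e in side_ev], collapse_window)
        bps = []
        for cluster in clusters:
            members = [ev for p in set(cluster) for ev in by_junction[p]]
            pos = _mode(cluster)
            construct_pos = _mode(e.construct_junction for e in members)
            bps.append(Breakpoint(chrom, pos, len(members), construct_pos))
        bps.sort(key=lambda b: (-b.n_chimeric_support, b.pos))
        sided.append((side, bps))
    if len(sided) == 2:
        chosen = [sided[0][1][0], sided[1][1][0]]
    else:
        chosen = sided[0][1][:2]
    return sorted(chosen, key=lambda b: b.pos)


def count_discordant_support(
    chrom: str,
    breakpoints: Sequence[Breakpoint],
    pairs: Sequence[DiscordantPair],
    window: int = DEFAULT_DISCORDANT_WINDOW,
) -> int:
    """Discordant pairs whose host mate lies within *window* bp of any
    breakpoint on this chromosome; each pair counted once."""
    n = 0
    for p in pairs:
        if p.host_chrom != chrom:
            continue
        if any(abs(p.host_pos - bp.pos) <= window for bp in breakpoints):
            n += 1
    return n


def infer_orientation(evidence: Sequence[ChimericEvidence]) -> str:
    """Majority vote over strand concordance of the split alignments.

    A split read whose host and construct segments align to the same
    strand votes forward; opposite strands vote reverse.  Ties and empty
    evidence give ``unknown``.
    """
    forward = sum(1 for e in evidence if e.host_strand == e.construct_strand)
    reverse = len(evidence) - forward
    if forward > reverse:
        return "forward"
    if reverse > forward:
        return "reverse"
    return "unknown"


def transgene_region(
    breakpoints: Sequence[Breakpoint],
) -> tuple[Optional[int], Optional[int]]:
    """Construct coordinates paired with the left and right host breakpoints.

    A missing second junction leaves its side unknown (reported ``Unk``).
    """
    if not breakpoints:
        return None, None
    ordered = sorted(breakpoints, key=lambda b: b.pos)
    if len(ordered) == 1:
        return ordered[0].construct_pos, None
    return ordered[0].construct_pos, ordered[-1].construct_pos


def rank_candidates(candidates: list[TisCandidate]) -> list[TisCandidate]:
    """Highest score first; ties by chimeric support, then chromosome and
    position for determinism."""
    return sorted(
        candidates,
        key=lambda c: (-c.score, -c.n_chimeric, c.chrom, c.region_start),
    )


def call_tis(
    chimeric: Sequence[ChimericEvidence],
    discordant: Sequence[DiscordantPair],
    refset: ReferenceSet | None = None,
    collapse_window: int = DEFAULT_COLLAPSE_WINDOW,
    discordant_window: int = DEFAULT_DISCORDANT_WINDOW,
    min_score: float = 0.0,
) -> list[TisCandidate]:
    """Full candidate pipeline: delimit, collapse breakpoints, count
    support, score, orient, locate the transgene region, rank.

    Candidates are never auto-filtered by default (*min_score* = 0):
    low-scoring sites are still reported for human inspection.
    """
    candidates: list[TisCandidate] = []
    for chrom, start, end, subset in delimit_candidates(chimeric):
        if refset is not None and not refset.is_host(chrom):
            continue
        bps = call_breakpoints(subset, collapse_window)
        n_disc = count_discordant_support(chrom, bps, discordant, discordant_window)
        tg_start, tg_end = transgene_region(bps)
        cand = TisCandidate(
            chrom=chrom,
            region_start=start,
            region_end=end,
            breakpoints=bps,
            n_chimeric=len(subset),
            n_discordant=n_disc,
            score=prediction_score(len(subset), n_disc),
            orientation=infer_orientation(subset),
            transgene_start=tg_start,
            transgene_end=tg_end,
        )
        if cand.score >= min_score:
            candidates.append(cand)
    ranked = rank_candidates(candidates)
    logger.info("tis caller: %d candidate(s)", len(ranked))
    return ranked


def write_candidates_tsv(candidates: Sequence[TisCandidate], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        c.chrom,
                        c.region_start,
                        c.region_end,
                        c.span,
                        c.n_chimeric,
                        c.n_discordant,
                        format_score(c.score),
                        c.orientation,
                        c.transgene_start if c.transgene_start is not None else UNKNOWN,
                        c.transgene_end if c.transgene_end is not None else UNKNOWN,
                    )
                )
                + "\n"
            )
    return path
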