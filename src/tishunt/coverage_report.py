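"""Coverage extraction and the report bundle.

Produces everything a reviewer looks at: binned read-depth tracks over
the candidate region and the construct, the circular-plot data files
(karyotype + histogram, a stable tab-separated schema since they are a
public interface here), a native two-semicircle circular figure (host on
the bottom, construct on top, chimeric links black, discordant links
red), IGV batch scripts for snapshot automation, and the joint HTML
summary.
"""

from __future__ import annotations

import html as _html
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .alignment_io import ALIGNED_OPS, AlignedRecord, ConstructAnnotation
from .chimera_scan import ChimericEvidence
from .discordant_scan import DiscordantPair
from .tis_caller import DEFAULT_DISCORDANT_WINDOW, TisCandidate, format_score

logger = logging.getLogger("tishunt")

DEFAULT_BIN_SIZE = 100  # bp
IGV_ZOOM = 4600  # bp either side of a breakpoint in the zoom snapshot

KARYOTYPE_COLUMNS = (
    "record_type",
    "name",
    "seq",
    "start",
    "end",
    "partner_seq",
    "partner_start",
    "partner_end",
)
HISTOGRAM_COLUMNS = ("seq", "bin_start", "bin_end", "depth")


@dataclass(slots=True)
class CoverageTrack:
    """Mean per-bin read depth over a 1-based inclusive window."""

    chrom: str
    start: int
    end: int
    bin_size: int
    depths: np.ndarray

    @property
    def n_bins(self) -> int:
        return math.ceil((self.end - self.start + 1) / self.bin_size)

    def bin_bounds(self, i: int) -> tuple[int, int]:
        lo = self.start + i * self.bin_size
        return lo, min(lo + self.bin_size - 1, self.end)


@dataclass
class ReportBundle:
    """Everything produced for one sample."""

    sample: str
    candidates: list[TisCandidate]
    tracks: dict[int, tuple[CoverageTrack, CoverageTrack]] = field(default_factory=dict)
    annotation: Optional[ConstructAnnotation] = None
    artifacts: dict[str, Path] = field(default_factory=dict)
    error: Optional[str] = None
    host_coverage: float = 0.0
    construct_coverage: float = 0.0


# ---------------------------------------------------------------------------
# Depth
# ---------------------------------------------------------------------------


def _add_depth(depth: np.ndarray, rec: AlignedRecord, start: int, end: int) -> int:
    """Accumulate aligned (M/=/X/D) reference bases of one record; returns
    the number of bases that fell inside [start, end]."""
    ref = rec.pos
    added = 0
    for op in rec.cigar:
        if op.op in ALIGNED_OPS:
            lo = max(ref, start)
            hi = min(ref + op.length - 1, end)
            if hi >= lo:
                depth[lo - start : hi - start + 1] += 1
                added += hi - lo + 1
            ref += op.length
        elif op.op == "N":
            ref += op.length
    return added


def _depth_usable(rec: AlignedRecord) -> bool:
    return rec.is_primary and not rec.is_unmapped and not rec.is_duplicate and not rec.is_qcfail


def depth_track(
    alignments: Iterable[AlignedRecord],
    chrom: str,
    start: int,
    end: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_length: Optional[int] = None,
) -> CoverageTrack:
    """Per-bin mean depth over ``chrom:start-end`` (1-based inclusive).

    Counts aligned reference bases (M/=/X/D) of primary, non-duplicate
    records.  The last bin may be partial; its mean is over its actual
    width.
    """
    if start < 1 or end < start:
        raise ValueError(f"invalid region {chrom}:{start}-{end}")
    if chrom_length is not None and end > chrom_length:
        raise ValueError(f"region {chrom}:{start}-{end} beyond chromosome length {chrom_length}")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    per_base = np.zeros(end - start + 1, dtype=np.int64)
    for rec in alignments:
        if rec.rname != chrom or not _depth_usable(rec):
            continue
        _add_depth(per_base, rec, start, end)
    n_bins = math.ceil(len(per_base) / bin_size)
    depths = np.empty(n_bins, dtype=float)
    for i in range(n_bins):
        chunk = per_base[i * bin_size : (i + 1) * bin_size]
        depths[i] = chunk.mean()
    return CoverageTrack(chrom, start, end, bin_size, depths)


def mean_coverage(
    alignments: Iterable[AlignedRecord],
    sequence_lengths: dict[str, int],
) -> float:
    """Total aligned bases over the given sequences / total sequence length."""
    if not sequence_lengths:
        raise ValueError("sequence set must be non-empty")
    total = 0
    for rec in alignments:
        if rec.rname in sequence_lengths and _depth_usable(rec):
            total += sum(op.length for op in rec.cigar if op.op in ALIGNED_OPS)
    return total / sum(sequence_lengths.values())


# ---------------------------------------------------------------------------
# Circular-plot data files
# ---------------------------------------------------------------------------


def emit_circular_data(
    candidate: TisCandidate,
    host_track: CoverageTrack,
    construct_track: CoverageTrack,
    annotation: ConstructAnnotation,
    chimeric: Sequence[ChimericEvidence],
    discordant: Sequence[DiscordantPair],
    karyotype_path: str | Path,
    histogram_path: str | Path,
    construct_name: str = "construct",
    window: int = DEFAULT_DISCORDANT_WINDOW,
) -> tuple[Path, Path]:
    """Write the two circular-plot data files for one candidate.

    The karyotype file carries the host region, the full construct with
    its features, and one link record per chimeric read plus one per
    discordant pair whose host mate lies within *window* bp of a
    breakpoint.  The histogram file carries the binned depths of both
    tracks.  Both are deterministic functions of their inputs.
    """
    karyotype_path, histogram_path = Path(karyotype_path), Path(histogram_path)
    rows: list[tuple] = []
    rows.append(("sequence", candidate.chrom, candidate.chrom, host_track.start, host_track.end, "", "", ""))
    rows.append(("sequence", construct_name, construct_name, construct_track.start, construct_track.end, "", "", ""))
    for feat in annotation.features:
        rows.append(("feature", feat.name, construct_name, feat.start + 1, feat.end, "", "", ""))
    for ev in chimeric:
        if ev.host_chrom != candidate.chrom:
            continue
        rows.append(
            ("link_chimeric", ev.qname, ev.host_chrom, ev.host_junction, ev.host_junction,
             construct_name, ev.construct_junction, ev.construct_junction)
        )
    for dp in discordant:
        if dp.host_chrom != candidate.chrom:
            continue
        if not any(abs(dp.host_pos - bp.pos) <= window for bp in candidate.breakpoints):
            continue
        rows.append(
            ("link_discordant", dp.qname, dp.host_chrom, dp.host_pos, dp.host_pos,
             construct_name, dp.construct_pos, dp.construct_pos)
        )
    with open(karyotype_path, "w") as fh:
        fh.write("\t".join(KARYOTYPE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(histogram_path, "w") as fh:
        fh.write("\t".join(HISTOGRAM_COLUMNS) + "\n")
        for track in (host_track, construct_track):
            for i, d in enumerate(track.depths):
                lo, hi = track.bin_bounds(i)
                fh.write(f"{track.chrom}\t{lo}\t{hi}\t{d:.4f}\n")
    return karyotype_path, histogram_path


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [dict(zip(header, line.rstrip("\n").split("\t"))) for line in fh if line.strip()]


def render_circular(
    karyotype_path: str | Path,
    histogram_path: str | Path,
    out_path: str | Path,
    title: str = "",
) -> Path:
    """Draw the circular TIS figure from the emitted data files.

    Host region on the bottom semicircle (gray), construct on the top
    (red), construct features as labelled boxes, depth as radial bars,
    chimeric links black and discordant links red.
    """
    kary = _read_tsv(Path(karyotype_path))
    hist = _read_tsv(Path(histogram_path))
    seqs = [r for r in kary if r["record_type"] == "sequence"]
    feats = [r for r in kary if r["record_type"] == "feature"]
    links = [r for r in kary if r["record_type"].startswith("link_")]
    if len(seqs) != 2:
        raise ValueError("karyotype must define exactly two sequence rows")
    host_row, con_row = seqs

    def span(row: dict[str, str]) -> tuple[int, int]:
        return int(row["start"]), int(row["end"])

    # host occupies angles 200..340 deg, construct 20..160 deg (gaps between)
    def mapper(row: dict[str, str], a0: float, a1: float):
        lo, hi = span(row)
        width = max(hi - lo, 1)

        def to_angle(pos: float) -> float:
            return a0 + (pos - lo) / width * (a1 - a0)

        return to_angle

    host_angle = mapper(host_row, 340.0, 200.0)
    con_angle = mapper(con_row, 20.0, 160.0)

    fig, ax = plt.subplots(figsize=(7, 7), subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("E")
    ax.set_ylim(0, 1.35)
    ax.axis("off")
    theta_host = np.radians(np.linspace(200, 340, 200))
    theta_con = np.radians(np.linspace(20, 160, 200))
    ax.plot(theta_host, np.full_like(theta_host, 1.0), color="gray", lw=8, solid_capstyle="butt")
    ax.plot(theta_con, np.full_like(theta_con, 1.0), color="firebrick", lw=8, solid_capstyle="butt")

    depth_rows = {host_row["seq"]: [], con_row["seq"]: []}
    for r in hist:
        depth_rows.setdefault(r["seq"], []).append(r)
    max_depth = max((float(r["depth"]) for r in hist), default=1.0) or 1.0
    for row, angle_of in ((host_row, host_angle), (con_row, con_angle)):
        for r in depth_rows.get(row["seq"], []):
            mid = (int(r["bin_start"]) + int(r["bin_end"])) / 2
            h = 0.25 * float(r["depth"]) / max_depth
            ax.plot(
                [np.radians(angle_of(mid))] * 2,
                [1.04, 1.04 + h],
                color="darkgray",
                lw=1.0,
            )
    for f in feats:
        a = np.radians(
            np.linspace(con_angle(int(f["start"])), con_angle(int(f["end"])), 20)
        )
        ax.plot(a, np.full_like(a, 0.96), color="black", lw=5, solid_capstyle="butt")
        ax.text(
            a.mean(), 0.87, f["name"], ha="center", va="center", fontsize=7, rotation=0
        )
    for link in links:
        color = "black" if link["record_type"] == "link_chimeric" else "red"
        a0 = np.radians(host_angle(int(link["start"])))
        a1 = np.radians(con_angle(int(link["partner_start"])))
        # straight chord through the disc interior
        x0, y0 = np.cos(a0) * 0.93, np.sin(a0) * 0.93
        x1, y1 = np.cos(a1) * 0.93, np.sin(a1) * 0.93
        xs = np.linspace(x0, x1, 30)
        ys = np.linspace(y0, y1, 30)
        ax.plot(np.arctan2(ys, xs), np.hypot(xs, ys), color=color, lw=0.6, alpha=0.6)
    if title:
        ax.set_title(title, fontsize=11)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


# ---------------------------------------------------------------------------
# IGV batch scripts
# ---------------------------------------------------------------------------


def emit_igv_batch(
    candidate: TisCandidate,
    bam_path: str | Path,
    out_path: str | Path,
    genome_path: str | Path = "joint_reference.fa",
    snapshot_dir: str | Path = ".",
    zoom: int = IGV_ZOOM,
) -> Path:
    """IGV batch script: one snapshot of the full TIS region and one
    zoomed ±*zoom* bp view per breakpoint."""
    out_path = Path(out_path)
    lines = [
        "new",
        f"genome {genome_path}",
        f"load {bam_path}",
        f"snapshotDirectory {snapshot_dir}",
        f"goto {candidate.chrom}:{candidate.region_start}-{candidate.region_end}",
        f"snapshot {candidate.chrom}_{candidate.region_start}_{candidate.region_end}_full.png",
    ]
    for bp in candidate.breakpoints:
        lo = max(1, bp.pos - zoom)
        hi = bp.pos + zoom
        lines.append(f"goto {candidate.chrom}:{lo}-{hi}")
        lines.append(f"snapshot {candidate.chrom}_{bp.pos}_zoom.png")
    lines.append("exit")
    out_path.write_text("\n".join(lines) + "\n")
    return out_path


# ---------------------------------------------------------------------------
# HTML summary
# ---------------------------------------------------------------------------

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Transgene insertion-site report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin: 0.8em 0; }}
td, th {{ border: 1px solid #999; padding: 0.3em 0.7em; }}
h2 {{ border-bottom: 2px solid #833; padding-bottom: 0.2em; }}
.error {{ color: #a00; }}
img {{ max-width: 520px; }}
</style></head><body>
<h1>Transgene insertion-site report</h1>
{sections}
</body></html>
"""

_CAND_HEADER = (
    "<tr><th>rank</th><th>chrom</th><th>region</th><th>span</th>"
    "<th>chimeric</th><th>discordant pairs</th><th>score</th>"
    "<th>orientation (inferred)</th><th>transgene region</th></tr>"
)


def _candidate_row(rank: int, c: TisCandidate) -> str:
    tg = (
        f"{c.transgene_start if c.transgene_start is not None else 'Unk'}"
        f"&ndash;{c.transgene_end if c.transgene_end is not None else 'Unk'}"
    )
    return (
        f"<tr><td>{rank}</td><td>{_html.escape(c.chrom)}</td>"
        f"<td>{c.region_start:,}&ndash;{c.region_end:,}</td><td>{c.span:,}</td>"
        f"<td>{c.n_chimeric}</td><td>{c.n_discordant}</td>"
        f"<td>{format_score(c.score)}</td><td>{c.orientation}</td><td>{tg}</td></tr>"
    )


def render_html(bundles: Sequence[ReportBundle], out_path: str | Path) -> Path:
    """Render the joint report: one section per sample, candidates in
    rank order, circular figures embedded by relative path."""
    sections: list[str] = []
    for bundle in bundles:
        parts = [f"<h2>Sample {_html.escape(bundle.sample)}</h2>"]
        if bundle.error:
            parts.append(f'<p class="error">Sample failed: {_html.escape(bundle.error)}</p>')
        elif not bundle.candidates:
            parts.append("<p>No transgene insertion site found.</p>")
        else:
            parts.append(
                f"<p>Host coverage {bundle.host_coverage:.2f}X, "
                f"construct coverage {bundle.construct_coverage:.2f}X.</p>"
            )
            parts.append("<table>" + _CAND_HEADER)
            for rank, c in enumerate(bundle.candidates, 1):
                parts.append(_candidate_row(rank, c))
            parts.append("</table>")
            for rank, c in enumerate(bundle.candidates, 1):
                key = f"circular_{rank}"
                if key in bundle.artifacts:
                    rel = bundle.artifacts[key].name
                    parts.append(
                        f'<div class="candidate"><h3>Candidate {rank}: '
                        f"{_html.escape(c.chrom)}:{c.region_start:,}&ndash;{c.region_end:,}</h3>"
                        f'<img src="{rel}" alt="circular plot candidate {rank}"></div>'
                    )
        sections.append("\n".join(parts))
    out_path = Path(out_path)
    out_path.write_text(_PAGE.format(sections="\n".join(sections)))
    return out_path
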