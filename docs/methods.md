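# Methods

## The detection model

`tishunt` locates where a known transgene construct has integrated into a
host genome from paired-end whole-genome sequencing.  The reads are assumed
to be aligned with a local aligner (e.g. `bwa mem`) against a *joint
reference*: the host genome with the construct appended as one extra
sequence.  Two evidence classes then betray an insertion junction:

- **Chimeric (split) reads.**  A read spanning a host–construct junction is
  reported as a soft-clipped primary alignment on one side plus a
  supplementary alignment on the other, cross-referenced through the SA
  optional field.  The clipped end points at the junction: a left clip puts
  the breakpoint at the first aligned base (`pos`), a right clip at the
  last (`pos + reference_span(CIGAR) − 1`, where the span counts M/D/N/=/X
  operations).  Split reads localise the breakpoint to the base.
- **Discordant read pairs.**  A fragment straddling the junction has one
  mate on a host chromosome and one on the construct.  Discordance is
  decided purely by reference identity, never by insert size; pairs
  internal to the host or to the construct are not insertion evidence.

Every host chromosome with at least one chimeric read becomes exactly one
candidate; multiple insertions on one chromosome are deliberately not split
apart (the method cannot distinguish them, and pretending otherwise would
manufacture precision).  The candidate region is delimited by the
outermost chimeric junctions, and the candidate is scored

    prediction score = n_chimeric + n_discordant / 1000,

which ranks split-read evidence a thousandfold above pair evidence: pairs
are more abundant but only bracket the junction, while split reads pin it.
For fewer than 1000 discordant pairs the integer part of the score is the
chimeric count.  Candidates are reported highest score first and are never
auto-filtered by default — low-scoring candidates are flagged for human
inspection rather than silently removed, because the top-scoring candidate
is not always the true one.

### Breakpoint collapsing

Chimeric host junctions are clustered with single-linkage within
`collapse_window` (default 10 bp) to absorb alignment jitter at
microhomology.  Clustering is done **separately per host clip side**: a
right-clipped host alignment flanks the insertion on the left and a
left-clipped one on the right, so the two true junctions of a clean
insertion — which sit 1 bp apart in host coordinates, or closer under
microhomology — are never merged.  When both flanks carry evidence the
best-supported cluster of each is reported (at most two breakpoints);
otherwise the two best-supported clusters.  A cluster reports its modal
position, its read support, and the modal construct coordinate of its
members (ties broken toward the smaller value for determinism).

### Discordant support and orientation

Discordant pairs support a candidate when the host mate lies within
`discordant_window` (default 5,000 bp) of any breakpoint; each **pair**
counts once.  The score's discordant term uses this same 5,000 bp window
as the visualization, the only window the method defines.

Orientation is inferred by majority vote over strand concordance of the
split alignments: host and construct segments on the same strand vote
forward, opposite strands vote reverse; ties give `unknown`.  This is a
computable proxy for the visual "discordant links crossing chimeric links"
pattern in the circular plot, and the report labels it as inferred.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_mapq` | 30 | MAPQ threshold for chimeric extraction, applied to both the record and its SA partner (the stricter reading of a single-threshold rule); also applied to both mates of a discordant pair for symmetry. |
| `min_clip` | 10 bp | minimum soft/hard clip treated as junction evidence; suppresses adapter/error clips while keeping short-overhang junction reads. |
| `collapse_window` | 10 bp | junction-jitter clustering window (per clip side). |
| `discordant_window` | 5,000 bp | breakpoint window for counting pair support and for plot links. |
| `bin_size` | 100 bp | coverage histogram bin. |
| `min_score` | 0 | candidate filter; off by default by design. |

Secondary alignments (0x100) are dropped at read time — only primary
alignments are evidence; supplementary lines (0x800) are kept for SA
cross-checking and for the qname-join fallback used when a SAM lacks SA
tags.  Duplicate (0x400) and QC-fail (0x200) records are excluded
everywhere.  Coverage counts M/=/X/D reference bases (deletions included,
as common depth tools do; N skipped).

## The simulator

The simulator emulates a transgenesis experiment end to end: i.i.d.
uniform-GC host chromosomes and construct (defaults 2 × 100 kb host,
9,389 bp construct — the scale of a typical promoter/cDNA/marker
construct); an insertion planted after a chosen base in forward or reverse
orientation, with optional tandem copies and an optional host deletion at
the junction (deletions are known to co-occur with integration); paired-end
reads (defaults 2 × 150 bp, insert 400 ± 50 bp truncated-normal, constant
Q37, substitution-only errors) at a chosen coverage, with pair count
`coverage × genome / (2 × read_len)`; and **ideal alignments** computed
through the known donor→reference coordinate map — junction-spanning mates
become soft-clipped records with SA tags (segments under `min_anchor` =
10 bp are left as plain clips, mirroring `min_clip`), junction-straddling
pairs become discordant, MAPQ is fixed at 60.

Truth bookkeeping: for an insertion after host base `p` with deletion `d`,
the expected breakpoints are `(p, p + d + 1)`; donor length obeys
`len(host) + n_tandem × len(fragment) − d`.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: repeat-induced multimapping and MAPQ ambiguity
(a repeat-block injection option exists to build such references, but the
ideal-alignment oracle always places reads at their true origin), indels
and structured error profiles, PCR duplicates, chimera artefacts, and
reference/donor divergence beyond the planted insertion.  Results on real
alignments depend on the external aligner's clipping and SA behaviour.

## Evaluation design at desk scale

Recovery is measured on seeded synthetic datasets rather than the
multi-gigabase genomes of a real experiment: 20 scenarios at 50X
(both orientations, junction deletions 0–500 bp, error-free reads) must
recover both breakpoints at ±0 bp with correct orientation, and a
35-dataset grid over {5, 10, 30, 50}X with 60 planted insertions measures
sensitivity (perfect at ≥30X is required; low-coverage misses are
expected and tolerated, as dropout of junction-spanning reads is a
Poisson sampling fact, not an algorithmic defect).  Problem sizes
(2 × 100 kb hosts) were chosen so the full grid runs in about a minute on
one core while keeping ≥650 read pairs per chromosome at the lowest
coverage.

## Numerical and formatting choices

- All internal coordinates are SAM-style 1-based inclusive; BED input is
  converted at the boundary; reported breakpoints are 1-based.
- Scores are exact rationals in floating point (`n + d/1000` is exact for
  the supported count ranges) and are printed with exactly 3 decimals.
- Single-junction candidates report `region_start == region_end` and an
  `Unk` second transgene coordinate.
- Tie-breaks are deterministic everywhere: longer clip wins (left on tie),
  modal positions break toward the smaller value, ranking ties break by
  chimeric count, then chromosome name, then position.
- The karyotype/histogram data files are tab-separated with fixed headers
  and no timestamps, so identical inputs reproduce identical bytes; the
  PNG is excluded from byte-stability guarantees.

## Known limitations

- One candidate per chromosome: co-located independent insertions merge.
- Orientation is a majority vote; mixed-orientation tandem arrays yield
  `unknown` or the dominant direction.
- Copy number is not estimated automatically; the construct/host coverage
  ratio reported per sample is the manual starting point.
- Alignment is out of scope: FASTQ-only samples produce the documented
  `bwa index` / `bwa mem -T 30` recipe (minimum output alignment score 30)
  and an error section until an alignment is provided.
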