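"""Simulator: determinism, donor construction, read drawing, ideal alignments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tishunt.alignment_io import ConfigError
from tishunt.chimera_scan import junction_from_cigar, scan_chimeric
from tishunt.simulator import (
    InsertionSpec,
    expected_pair_count,
    ideal_alignments,
    plant_insertion,
    plant_insertions,
    random_references,
    read_truth,
    revcomp,
    simulate_pairs,
    write_truth,
)


# ---------------------------------------------------------------------------
# random_references
# ---------------------------------------------------------------------------


def test_references_deterministic_per_seed():
    a = random_references(1, chrom_len=5000, construct_len=1500)
    b = random_references(1, chrom_len=5000, construct_len=1500)
    assert a.sequences == b.sequences
    assert random_references(2, chrom_len=5000, construct_len=1500).sequences != a.sequences


def test_references_shapes():
    rs = random_references(3, n_chrom=2, chrom_len=100_000, construct_len=9389)
    assert rs.host_names == ["chr1", "chr2"]
    assert all(len(rs.sequences[c]) == 100_000 for c in rs.host_names)
    assert rs.construct_length == 9389


def test_references_gc_fraction():
    rs = random_references(4, n_chrom=1, chrom_len=100_000, construct_len=1000, gc=0.5)
    seq = rs.sequences["chr1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.5) < 0.02  # binomial concentration at n = 1e5


def test_repeat_block_injection():
    rs = random_references(5, n_chrom=1, chrom_len=20000, construct_len=2000,
                           repeat_block_len=500)
    assert rs.construct_sequence[:500] in rs.sequences["chr1"]


# ---------------------------------------------------------------------------
# plant_insertion(s)
# ---------------------------------------------------------------------------


def test_plant_forward_donor_length():
    rs = random_references(6, n_chrom=1, chrom_len=20000, construct_len=9389)
    donor, truth = plant_insertion(rs, InsertionSpec(chrom="chr1", host_pos=10000))
    assert len(donor.sequences["chr1"]) == 20000 + 9389
    assert truth.expected_breakpoints == (10000, 10001)
    assert truth.expected_transgene_region == (1, 9389)


def test_plant_reverse_junction_sequence():
    """The donor bases after the junction equal the reverse complement of
    the construct end."""
    rs = random_references(7, n_chrom=1, chrom_len=20000, construct_len=2000)
    donor, _ = plant_insertion(
        rs, InsertionSpec(chrom="chr1", host_pos=5000, orientation="reverse")
    )
    d = donor.sequences["chr1"]
    assert d[5000:5000 + 2000] == revcomp(rs.construct_sequence)


@given(
    st.integers(1000, 19000),
    st.sampled_from(["forward", "reverse"]),
    st.integers(1, 3),
    st.integers(0, 500),
)
@settings(max_examples=30, deadline=None)
def test_donor_length_conservation(host_pos, orientation, n_tandem, deletion):
    """len(donor) = len(host) + n_tandem * len(fragment) - host_deletion."""
    rs = random_references(8, n_chrom=1, chrom_len=20000, construct_len=1500)
    donor, truth = plant_insertion(
        rs,
        InsertionSpec(chrom="chr1", host_pos=host_pos, orientation=orientation,
                      n_tandem=n_tandem, host_deletion=deletion),
    )
    assert len(donor.sequences["chr1"]) == 20000 + n_tandem * 1500 - deletion
    assert truth.expected_breakpoints == (host_pos, host_pos + deletion + 1)


@pytest.mark.parametrize(
    "spec",
    [
        InsertionSpec(chrom="chrX", host_pos=100),
        InsertionSpec(chrom="chr1", host_pos=0),
        InsertionSpec(chrom="chr1", host_pos=19990, host_deletion=100),
        InsertionSpec(chrom="chr1", host_pos=100, fragment=(0, 10)),
        InsertionSpec(chrom="chr1", host_pos=100, n_tandem=0),
    ],
)
def test_plant_rejects_bad_specs(spec):
    rs = random_references(9, n_chrom=1, chrom_len=20000, construct_len=1500)
    with pytest.raises(ConfigError):
        plant_insertions(rs, [spec])


# ---------------------------------------------------------------------------
# simulate_pairs
# ---------------------------------------------------------------------------


def test_pair_count_closed_form():
    assert expected_pair_count(50, 200_000, 100) == 50_000


def test_pairs_error_free_are_substrings():
    rs = random_references(10, n_chrom=1, chrom_len=20000, construct_len=1500)
    donor, _ = plant_insertion(rs, InsertionSpec(chrom="chr1", host_pos=10000))
    pairs = simulate_pairs(donor, coverage=2, seed=3)
    d = donor.sequences["chr1"]
    for p in pairs[:200]:
        assert p.seq1 in d
        assert revcomp(p.seq2) in d


def test_fastq_deterministic_per_seed(tmp_path):
    rs = random_references(11, n_chrom=1, chrom_len=20000, construct_len=1500)
    donor, _ = plant_insertion(rs, InsertionSpec(chrom="chr1", host_pos=9000))
    for sub in ("a", "b"):
        (tmp_path / sub).mkdir()
        simulate_pairs(donor, coverage=2, seed=42, fastq_prefix=tmp_path / sub / "reads")
    assert (tmp_path / "a" / "reads_1.fastq").read_bytes() == (tmp_path / "b" / "reads_1.fastq").read_bytes()
    assert (tmp_path / "a" / "reads_2.fastq").read_bytes() == (tmp_path / "b" / "reads_2.fastq").read_bytes()


def test_error_rate_introduces_mismatches():
    rs = random_references(12, n_chrom=1, chrom_len=20000, construct_len=1500)
    donor, _ = plant_insertion(rs, InsertionSpec(chrom="chr1", host_pos=9000))
    pairs = simulate_pairs(donor, coverage=2, error_rate=0.05, seed=3)
    d = donor.sequences["chr1"]
    mismatched = sum(1 for p in pairs if p.seq1 not in d)
    assert mismatched > len(pairs) // 2  # P(read error-free) = .95^150 ~ 4e-4


# ---------------------------------------------------------------------------
# ideal_alignments
# ---------------------------------------------------------------------------


def _one_junction_setup(orientation="forward", seed=13):
    rs = random_references(seed, n_chrom=1, chrom_len=20000, construct_len=1500)
    donor, truth = plant_insertion(
        rs, InsertionSpec(chrom="chr1", host_pos=10000, orientation=orientation)
    )
    return rs, donor, truth


def test_mate_inside_construct_maps_to_construct_coordinates():
    rs, donor, _ = _one_junction_setup()
    from tishunt.simulator import ReadPairSim

    # fragment entirely inside the planted construct copy (donor 10001..11500)
    frag = donor.sequences["chr1"][10100:10500]
    pair = ReadPairSim("q", "chr1", 10101, 400, frag[:150], revcomp(frag[-150:]))
    recs = ideal_alignments([pair], rs, donor)
    primaries = [r for r in recs if r.is_primary]
    assert all(r.rname == rs.construct_name for r in primaries)
    assert primaries[0].pos == 101  # donor offset mapped into construct coordinates


def test_junction_spanning_mate_split_matches_truth():
    """A mate spanning the junction 60/90 yields a clipped primary whose
    CIGAR junction equals the planted breakpoint, on both sides."""
    rs, donor, truth = _one_junction_setup()
    from tishunt.simulator import ReadPairSim

    start = 10000 - 59  # 60 host bases, 90 construct bases
    frag = donor.sequences["chr1"][start - 1 : start - 1 + 400]
    pair = ReadPairSim("q", "chr1", start, 400, frag[:150], revcomp(frag[-150:]))
    recs = ideal_alignments([pair], rs, donor)
    m1 = [r for r in recs if r.mate_index == 1]
    assert len(m1) == 2  # primary + supplementary
    by_ref = {r.rname: r for r in m1}
    host_j = junction_from_cigar(by_ref["chr1"].pos, by_ref["chr1"].cigar)
    con_j = junction_from_cigar(by_ref[rs.construct_name].pos, by_ref[rs.construct_name].cigar)
    assert host_j[0] == truth.expected_breakpoints[0]
    assert con_j[0] == truth.expected_transgene_region[0]
    assert all(r.sa for r in m1)  # SA tags cross-reference the two segments


def test_reverse_orientation_flips_sa_strand():
    rs, donor, truth = _one_junction_setup(orientation="reverse")
    pairs = simulate_pairs(donor, coverage=30, seed=5)
    recs = ideal_alignments(pairs, rs, donor)
    evs = scan_chimeric(recs, rs)
    assert evs
    assert all(e.host_strand != e.construct_strand for e in evs)


def test_short_anchor_becomes_plain_clip():
    """A junction segment below min_anchor is dropped: plain soft clip, no SA."""
    rs, donor, _ = _one_junction_setup()
    from tishunt.simulator import ReadPairSim

    start = 10000 - 144  # 145 host bases, 5 construct bases in mate 1
    frag = donor.sequences["chr1"][start - 1 : start - 1 + 400]
    pair = ReadPairSim("q", "chr1", start, 400, frag[:150], revcomp(frag[-150:]))
    recs = ideal_alignments([pair], rs, donor, min_anchor=10)
    m1 = [r for r in recs if r.mate_index == 1]
    assert len(m1) == 1
    assert m1[0].rname == "chr1" and not m1[0].sa
    assert m1[0].cigar[-1].op == "S" and m1[0].cigar[-1].length == 5


def test_tandem_internal_junctions_are_not_chimeric():
    """Construct-construct junctions of a tandem insertion split reads,
    but both sides are the construct, so the chimera scan ignores them."""
    rs = random_references(14, n_chrom=1, chrom_len=30000, construct_len=1500)
    donor, truth = plant_insertion(
        rs, InsertionSpec(chrom="chr1", host_pos=15000, n_tandem=3)
    )
    pairs = simulate_pairs(donor, coverage=40, seed=6)
    recs = ideal_alignments(pairs, rs, donor)
    evs = scan_chimeric(recs, rs)
    assert {e.host_junction for e in evs} == set(truth.expected_breakpoints)


def test_sam_output_deterministic(tmp_path):
    rs, donor, _ = _one_junction_setup()
    for sub in ("a", "b"):
        (tmp_path / sub).mkdir()
        pairs = simulate_pairs(donor, coverage=3, seed=77)
        ideal_alignments(pairs, rs, donor, out_sam=tmp_path / sub / "ideal.sam")
    assert (tmp_path / "a" / "ideal.sam").read_bytes() == (tmp_path / "b" / "ideal.sam").read_bytes()


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------


def test_truth_round_trip(tmp_path):
    rs = random_references(15, n_chrom=2, chrom_len=20000, construct_len=1500)
    specs = [
        InsertionSpec(chrom="chr1", host_pos=4000),
        InsertionSpec(chrom="chr1", host_pos=12000, orientation="reverse", host_deletion=100),
        InsertionSpec(chrom="chr2", host_pos=8000, n_tandem=2),
    ]
    donor = plant_insertions(rs, specs)
    path = write_truth(donor.truths, tmp_path / "truth.tsv")
    rows = read_truth(path)
    assert len(rows) == 3
    for row, truth in zip(rows, donor.truths):
        assert (row["bp1"], row["bp2"]) == truth.expected_breakpoints
        assert row["orientation"] == truth.spec.orientation
        assert row["host_deletion"] == truth.spec.host_deletion
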