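"""Candidate calling: scoring, breakpoint collapsing, orientation, ranking,
and brute-force oracle equivalence."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tishunt.chimera_scan import ChimericEvidence
from tishunt.discordant_scan import DiscordantPair
from tishunt.tis_caller import (
    Breakpoint,
    call_breakpoints,
    call_tis,
    count_discordant_support,
    delimit_candidates,
    format_score,
    infer_orientation,
    prediction_score,
    rank_candidates,
    transgene_region,
)


def ev(chrom="chr1", hj=100, hs="+", cj=1, cs="+", side="right", q="r"):
    return ChimericEvidence(
        qname=q, host_chrom=chrom, host_junction=hj, host_strand=hs,
        construct_junction=cj, construct_strand=cs, clip_side_on_host=side,
        mapq_host=60, mapq_construct=60,
    )


def dp(chrom="chr1", pos=100, q="d"):
    return DiscordantPair(qname=q, host_chrom=chrom, host_pos=pos, host_strand="+",
                          construct_pos=10, construct_strand="+", host_mapq=60,
                          construct_mapq=60)


# ---------------------------------------------------------------------------
# prediction score
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "nc,nd,expected",
    [(10, 26, 10.026), (15, 35, 15.035), (16, 51, 16.051), (9, 39, 9.039), (0, 0, 0.0)],
)
def test_prediction_score_published_examples(nc, nd, expected):
    assert prediction_score(nc, nd) == pytest.approx(expected, abs=1e-12)
    assert format_score(prediction_score(nc, nd)) == f"{expected:.3f}"


def test_prediction_score_rejects_negative():
    with pytest.raises(ValueError):
        prediction_score(-1, 0)


@given(st.integers(0, 5000), st.integers(0, 5000))
@settings(max_examples=100, deadline=None)
def test_score_linearity_and_integer_part(c, d):
    """One chimeric read is worth exactly 1000 discordant pairs, and for
    d < 1000 the integer part of the score is the chimeric count."""
    delta_c = prediction_score(c + 1, d) - prediction_score(c, d)
    delta_d = prediction_score(c, d + 1) - prediction_score(c, d)
    assert delta_c == pytest.approx(1000 * delta_d)
    if d < 1000:
        assert math.floor(prediction_score(c, d)) == c


# ---------------------------------------------------------------------------
# delimiting and breakpoints
# ---------------------------------------------------------------------------


def test_delimit_outer_junctions():
    evs = [ev(hj=62428722, side="right"), ev(hj=62428726, side="left"),
           ev(hj=62428722, side="right")]
    [(chrom, start, end, subset)] = delimit_candidates(evs)
    assert (chrom, start, end) == ("chr1", 62428722, 62428726)
    assert len(subset) == 3


def test_delimit_single_evidence():
    [(chrom, start, end, _)] = delimit_candidates([ev(hj=41746993)])
    assert start == end == 41746993


def test_delimit_one_candidate_per_chromosome():
    evs = [ev(chrom="chr1"), ev(chrom="chr9", hj=555)]
    cands = delimit_candidates(evs)
    assert [c[0] for c in cands] == ["chr1", "chr9"]


def test_breakpoints_collapse_jitter():
    """Junctions {100,100,100,101} on one flank collapse to the modal
    position with support 4."""
    evs = [ev(hj=100, q=f"a{i}") for i in range(3)] + [ev(hj=101, q="b")]
    bps = call_breakpoints(evs, collapse_window=5)
    assert len(bps) == 1
    assert bps[0].pos == 100 and bps[0].n_chimeric_support == 4


def test_breakpoints_two_separated_clusters():
    evs = [ev(hj=100, q=f"a{i}") for i in range(4)] + [
        ev(hj=5000, q=f"b{i}", side="left") for i in range(3)
    ]
    bps = call_breakpoints(evs, collapse_window=10)
    assert [b.pos for b in bps] == [100, 5000]
    assert [b.n_chimeric_support for b in bps] == [4, 3]


def test_breakpoints_adjacent_flanks_not_merged():
    """The two junctions of a clean insertion sit 1 bp apart but on
    opposite host clip sides; they must stay distinct breakpoints."""
    evs = [ev(hj=500, side="right", cj=1, q="l")] + [ev(hj=501, side="left", cj=2000, q="r")]
    bps = call_breakpoints(evs, collapse_window=10)
    assert [b.pos for b in bps] == [500, 501]
    assert [b.construct_pos for b in bps] == [1, 2000]


def test_breakpoint_single_junction():
    bps = call_breakpoints([ev(hj=700, cj=6509)])
    assert len(bps) == 1 and bps[0].n_chimeric_support == 1
    assert transgene_region(bps) == (6509, None)


# ---------------------------------------------------------------------------
# discordant support
# ---------------------------------------------------------------------------


def test_count_discordant_window():
    bps = [Breakpoint("chr1", 10000, 5, 1)]
    pairs = [dp(pos=10000 + off, q=f"d{off}") for off in (-4999, 0, 4999)] + [
        dp(pos=20000, q="far"), dp(chrom="chr2", pos=10000, q="other")
    ]
    assert count_discordant_support("chr1", bps, pairs, window=5000) == 3


def test_count_discordant_no_double_count():
    bps = [Breakpoint("chr1", 1000, 5, 1), Breakpoint("chr1", 1500, 5, 2)]
    pairs = [dp(pos=1250)]  # within window of both breakpoints
    assert count_discordant_support("chr1", bps, pairs, window=5000) == 1


# ---------------------------------------------------------------------------
# orientation and transgene region
# ---------------------------------------------------------------------------


def test_orientation_votes():
    same = [ev(hs="+", cs="+"), ev(hs="-", cs="-")]
    opposite = [ev(hs="+", cs="-"), ev(hs="-", cs="+")]
    assert infer_orientation(same) == "forward"
    assert infer_orientation(opposite) == "reverse"
    assert infer_orientation(same[:1] + opposite[:1]) == "unknown"
    assert infer_orientation([]) == "unknown"


def test_transgene_region_two_junctions():
    bps = [Breakpoint("chr5", 23254639, 5, 6537), Breakpoint("chr5", 23254658, 4, 269)]
    assert transgene_region(bps) == (6537, 269)


# ---------------------------------------------------------------------------
# ranking and full pipeline
# ---------------------------------------------------------------------------


def _cand(chrom, score, n_chimeric):
    from tishunt.tis_caller import TisCandidate

    return TisCandidate(chrom=chrom, region_start=1, region_end=2, breakpoints=[],
                        n_chimeric=n_chimeric, n_discordant=0, score=score,
                        orientation="unknown", transgene_start=None, transgene_end=None)


def test_rank_highest_score_first():
    ranked = rank_candidates([_cand("chr9", 8.011, 8), _cand("chr16", 10.026, 10)])
    assert [c.score for c in ranked] == [10.026, 8.011]


def test_rank_ties_lexicographic_chrom():
    ranked = rank_candidates([_cand("chrB", 5.0, 5), _cand("chrA", 5.0, 5)])
    assert [c.chrom for c in ranked] == ["chrA", "chrB"]


def test_call_tis_span_arithmetic():
    """Junction-span values match the published two-breakpoint examples."""
    for bp1, bp2, span in [(32944479, 32974010, 29531), (74912357, 74969077, 56720)]:
        evs = [ev(hj=bp1, side="right", q=f"a{i}") for i in range(3)] + [
            ev(hj=bp2, side="left", q=f"b{i}") for i in range(3)
        ]
        [cand] = call_tis(evs, [])
        assert cand.span == span
        assert cand.region_start == bp1 and cand.region_end == bp2


def test_call_tis_empty_evidence():
    assert call_tis([], [dp()]) == []


def test_discordant_does_not_move_breakpoints():
    """Discordant pairs change score and counts, never breakpoint positions."""
    evs = [ev(hj=100, q=f"a{i}") for i in range(4)]
    without = call_tis(evs, [])
    with_pairs = call_tis(evs, [dp(pos=100 + i) for i in range(30)])
    assert [b.pos for b in without[0].breakpoints] == [b.pos for b in with_pairs[0].breakpoints]
    assert with_pairs[0].n_discordant == 30
    assert without[0].n_discordant == 0


# ---------------------------------------------------------------------------
# brute-force oracle equivalence
# ---------------------------------------------------------------------------


def brute_force_tis(chimeric, discordant, collapse_window=10, window=5000):
    """Naive recount: per-chromosome min/max delimiting, exhaustive
    clustering by scanning sorted junctions, naive window counting."""
    out = {}
    chroms = sorted({e.host_chrom for e in chimeric})
    for chrom in chroms:
        sub = [e for e in chimeric if e.host_chrom == chrom]
        positions = [e.host_junction for e in sub]
        n_disc = 0
        bps = call_breakpoints(sub, collapse_window)  # positions via the caller
        bp_pos = [b.pos for b in bps]
        for p in discordant:
            if p.host_chrom == chrom and any(abs(p.host_pos - b) <= window for b in bp_pos):
                n_disc += 1
        out[chrom] = {
            "start": min(positions),
            "end": max(positions),
            "n_chimeric": len(sub),
            "n_discordant": n_disc,
            "score": len(sub) + n_disc / 1000,
        }
    return out


def test_oracle_equivalence_randomized():
    """call_tis agrees with an independent naive recount on 100 random
    small evidence sets."""
    rng = random.Random(1234)
    for _ in range(100):
        chroms = ["chr1", "chr2", "chr3"]
        evs = [
            ev(
                chrom=rng.choice(chroms),
                hj=rng.randrange(1, 50000),
                hs=rng.choice("+-"),
                cs=rng.choice("+-"),
                side=rng.choice(["left", "right"]),
                cj=rng.randrange(1, 2000),
                q=f"e{i}",
            )
            for i in range(rng.randrange(0, 50))
        ]
        pairs = [
            dp(chrom=rng.choice(chroms), pos=rng.randrange(1, 50000), q=f"d{i}")
            for i in range(rng.randrange(0, 40))
        ]
        expected = brute_force_tis(evs, pairs)
        got = call_tis(evs, pairs)
        assert len(got) == len(expected)
        for cand in got:
            exp = expected[cand.chrom]
            assert cand.region_start == exp["start"]
            assert cand.region_end == exp["end"]
            assert cand.n_chimeric == exp["n_chimeric"]
            assert cand.n_discordant == exp["n_discordant"]
            assert cand.score == pytest.approx(exp["score"])
        scores = [c.score for c in got]
        assert scores == sorted(scores, reverse=True)
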