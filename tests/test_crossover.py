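"""Block segmentation and crossover-event calling against the study rules."""

import numpy as np
import pytest

from recohot.crossover import (
    STATUS_PASS,
    STATUS_SHORT_FLANK,
    call_crossovers,
    count_events,
    events_frame,
    segment_blocks,
)
from recohot.genome import uniform_genome
from recohot.pipeline import detect_events
from recohot.simulate import SimConfig, simulate_ril


def test_uniform_calls_make_one_block(matrix_factory):
    gm = matrix_factory(["a", "a", "a"], positions=[0, 100, 200])
    blocks = segment_blocks(gm, "s0")
    assert len(blocks) == 1
    b = blocks[0]
    assert (b.state, b.start, b.end, b.n_markers) == ("a", 0, 201, 3)


def test_missing_calls_skip_without_breaking_runs(matrix_factory):
    # a, -, a, b at 0/10k/20k/30k: two blocks with the boundary at the
    # midpoint of the markers flanking the state change (25 kb)
    gm = matrix_factory(["a", "-", "a", "b"], positions=[0, 10_000, 20_000, 30_000])
    blocks = segment_blocks(gm, "s0")
    assert [b.state for b in blocks] == ["a", "b"]
    assert blocks[0].end == blocks[1].start == 25_000
    assert blocks[0].n_markers == 2


def test_all_missing_chromosome_yields_no_blocks(matrix_factory):
    gm = matrix_factory(["-", "-"], positions=[0, 100])
    assert segment_blocks(gm, "s0") == []


def test_single_block_emits_no_events(matrix_factory):
    gm = matrix_factory(["a", "a"], positions=[0, 50_000])
    assert call_crossovers(segment_blocks(gm, "s0")) == []


def test_short_interior_block_fails_flank_rule(matrix_factory):
    # a-block ~50 kb | b-block ~5 kb | a-block ~50 kb: both transitions
    # flagged (one flank < 10 kb), zero passing events
    pos = [0, 50_000, 52_500, 55_000, 105_000]
    gm = matrix_factory(["a", "a", "b", "a", "a"], positions=pos)
    events = call_crossovers(segment_blocks(gm, "s0"))
    assert len(events) == 2
    assert all(e.status == STATUS_SHORT_FLANK for e in events)
    assert count_events(events) == 0


def test_breakpoint_interval_spans_flanking_markers(matrix_factory):
    gm = matrix_factory(["a", "a", "b", "b"], positions=[0, 40_000, 60_000, 100_000])
    (e,) = call_crossovers(segment_blocks(gm, "s0"))
    assert (e.start, e.end) == (40_000, 60_000)
    assert e.midpoint == 50_000
    assert e.status == STATUS_PASS or e.status == "small_block_flag"


def test_ambiguous_impure_flank_excluded(matrix_factory):
    # a run with a smoothed-out minority blip next to the breakpoint
    calls = ["a"] * 4 + ["b"] + ["a"] * 4 + ["b"] * 9
    pos = list(np.arange(len(calls)) * 20_000)
    gm = matrix_factory(calls, positions=pos)
    blocks = segment_blocks(gm, "s0", smooth_min_markers=2)
    assert [b.state for b in blocks] == ["a", "b"]
    assert blocks[0].minority_frac == pytest.approx(1 / 9)
    (e,) = call_crossovers(blocks, purity=0.95)
    assert e.status == "ambiguous_excluded"
    (e2,) = call_crossovers(blocks, purity=0.85, small_block=0)
    assert e2.status == STATUS_PASS


def test_block_count_equals_truth_switches_plus_one():
    # dense markers, no missingness, low rate: every junction is resolved
    g = uniform_genome(2, 2_000_000, 2.0)
    gm, truth = simulate_ril(g, SimConfig(n_lines=30, n_markers=1500, missing_rate=0.0, seed=23))
    for sample in gm.samples:
        for chrom in g.names:
            blocks = [b for b in segment_blocks(gm, sample, chrom)]
            assert len(blocks) == truth.junctions[sample][chrom].size + 1


def test_exact_recovery_far_from_chromosome_ends():
    # no missingness, ~1.3 kb marker spacing, small-block check off:
    # passing events are exactly the true junctions ≥ 10 kb from the ends
    g = uniform_genome(2, 2_000_000, 2.0)
    gm, truth = simulate_ril(g, SimConfig(n_lines=40, n_markers=1500, missing_rate=0.0, seed=29))
    n_pass = 0
    n_true_interior = 0
    for sample in gm.samples:
        blocks = segment_blocks(gm, sample)
        events = call_crossovers(blocks, min_flank_span=10_000, small_block=0)
        n_pass += sum(e.status == STATUS_PASS for e in events)
        for chrom in g.names:
            pos = truth.junctions[sample][chrom]
            n_true_interior += int(np.sum((pos >= 10_000) & (pos <= g.length(chrom) - 10_000)))
    assert n_pass == n_true_interior


def test_passing_events_track_truth_within_ten_percent(small_sim):
    _, gm, truth, events = small_sim
    df = events_frame(events)
    detected = (df["status"].isin([STATUS_PASS, "small_block_flag"])).sum()
    assert abs(detected - truth.total()) / truth.total() < 0.10


def test_count_conservation_and_grouping(small_sim):
    _, _, _, events = small_sim
    total = count_events(events, by="genome")
    assert count_events(events, by="sample").sum() == total
    assert count_events(events, by="chrom").sum() == total
    df = events_frame(events)
    brute = int((df["status"] == STATUS_PASS).sum())
    assert total == brute
    assert count_events([], by="genome") == 0
    assert count_events([], by="sample").empty


def test_raising_min_flank_never_increases_passing(small_sim):
    _, gm, _, _ = small_sim
    counts = []
    for flank in (0, 5_000, 10_000, 50_000, 200_000):
        ev = detect_events(gm, min_flank_span=flank, small_block=0)
        counts.append(count_events(ev))
    assert counts == sorted(counts, reverse=True)


def test_drop_small_blocks_removes_flagged_events(matrix_factory):
    gm = matrix_factory(["a", "a", "b", "b"], positions=[0, 40_000, 60_000, 100_000])
    blocks = segment_blocks(gm, "s0")
    kept = call_crossovers(blocks, small_block=200_000, drop_small_blocks=True)
    assert kept == []
    flagged = call_crossovers(blocks, small_block=200_000)
    assert len(flagged) == 1 and flagged[0].status == "small_block_flag"
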