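"""Window tracks, rates, correlations, haplotype conservation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recohot.crossover import events_frame
from recohot.genome import GenomeSpec, uniform_genome
from recohot.landscape import (
    conservation_score,
    genome_mean_rate,
    length_correlation,
    map_rate_track,
    window_counts,
    window_rates,
)


def _events(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "status"]).assign(
        left_state="a", right_state="b"
    )


def test_empty_event_list_gives_zero_track(tiny_genome):
    track = window_counts(_events([]), tiny_genome, 100_000)
    assert (track["count"] == 0).all()
    assert len(track) == 100  # 2 × 5 Mb / 100 kb


def test_event_assigned_by_midpoint(tiny_genome):
    ev = _events([("chr01", 140_000, 160_000, "s1", "pass")])  # midpoint 150 kb
    track = window_counts(ev, tiny_genome, 100_000)
    hit = track[track["count"] > 0]
    assert len(hit) == 1
    assert (hit["start"].iloc[0], hit["end"].iloc[0]) == (100_000, 200_000)


def test_counts_conserved_on_simulation(small_sim):
    genome, _, _, events = small_sim
    df = events_frame(events)
    track = window_counts(df, genome, 100_000)
    assert track["count"].sum() == (df["status"] == "pass").sum()


def test_window_width_validation(tiny_genome):
    with pytest.raises(ValueError):
        window_counts(_events([]), tiny_genome, 0)


def test_truncated_window_uses_true_width():
    g = GenomeSpec([("c1", 1_250_000)], 1.0)
    ev = _events([("c1", 1_100_000, 1_100_002, "s1", "pass")])
    track = window_rates(window_counts(ev, g, 1_000_000))
    last = track.iloc[-1]
    assert last["end"] - last["start"] == 250_000
    assert last["rate"] == pytest.approx(1 / 0.25)


def test_weighted_mean_rate_identity(small_sim):
    genome, _, _, events = small_sim
    track = window_rates(window_counts(events, genome, 100_000))
    width_mb = (track["end"] - track["start"]) / 1e6
    assert genome_mean_rate(track) == pytest.approx(track["count"].sum() / width_mb.sum())
    assert np.average(track["rate"], weights=width_mb) == pytest.approx(genome_mean_rate(track))


def test_zero_count_windows_have_zero_rate(tiny_genome):
    track = window_rates(window_counts(_events([]), tiny_genome, 100_000))
    assert (track["rate"] == 0).all()


def test_sliding_windows_flagged_as_overlapping(tiny_genome):
    track = window_counts(_events([]), tiny_genome, 100_000, step=50_000)
    assert track.attrs.get("overlapping") is True
    assert (track["end"] - track["start"] == 100_000).all()


def test_rate_track_correlates_with_planted_landscape(study_sim):
    genome, _, _, events = study_sim
    track = window_rates(window_counts(events, genome, 100_000))
    planted = []
    for _, w in track.iterrows():
        starts, ends, rates = genome.segments(w["chrom"])
        mid = (w["start"] + w["end"]) // 2
        planted.append(rates[np.searchsorted(ends, mid, side="right")])
    r, _ = stats.pearsonr(track["rate"], planted)
    assert r > 0.8


def test_proportional_counts_give_unit_correlation():
    lengths = np.array([50.0, 80.0, 120.0, 150.0])
    r, p = length_correlation(4 * lengths, lengths)
    assert r == pytest.approx(1.0)
    assert p < 1e-6


def test_correlation_matches_manual_formula():
    rng = np.random.default_rng(8)
    x = rng.random(20)
    y = 0.5 * x + rng.random(20)
    r, p = length_correlation(x, y)
    manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert r == pytest.approx(manual, rel=1e-12)
    t = manual * np.sqrt(18 / (1 - manual**2))
    assert p == pytest.approx(2 * stats.t.sf(abs(t), 18), rel=1e-9)


def test_correlation_input_validation():
    with pytest.raises(ValueError):
        length_correlation([1, 2], [3, 4])
    with pytest.raises(ValueError):
        length_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_conservation_extremes(matrix_factory):
    g = GenomeSpec([("chr01", 10_000)], 1.0)
    win = g.windows(10_000)
    gm_same = matrix_factory(["aaaa", "aaaa"], positions=[100, 200])
    assert conservation_score(gm_same, win)["conservation"].iloc[0] == pytest.approx(1.0)
    gm_split = matrix_factory(["aabb", "aabb"], positions=[100, 200])
    assert conservation_score(gm_split, win)["conservation"].iloc[0] == pytest.approx(0.5)


def test_markerless_window_unscored(matrix_factory):
    g = GenomeSpec([("chr01", 20_000)], 1.0)
    win = g.windows(10_000)
    gm = matrix_factory(["aa"], positions=[100])
    out = conservation_score(gm, win)
    assert np.isnan(out["conservation"].iloc[1])


def test_conservation_anticorrelates_with_recombination(study_sim):
    genome, gm, _, events = study_sim
    width = 1_000_000
    track = window_rates(window_counts(events, genome, width))
    cons = conservation_score(gm, genome.windows(width))
    ok = ~cons["conservation"].isna()
    rho, _ = stats.spearmanr(cons.loc[ok, "conservation"], track.loc[ok.to_numpy(), "rate"])
    assert rho < 0


def test_map_rate_track_recovers_uniform_rate():
    # perfectly linear 2 cM/Mb map → every full window at 2 cM/Mb
    g = uniform_genome(1, 10_000_000, 2.0)
    pos = np.arange(0, 10_000_000, 100_000)
    markers = pd.DataFrame(
        {"marker_id": [f"m{i}" for i in range(pos.size)], "chrom": "chr01", "pos": pos}
    )
    map_df = pd.DataFrame(
        {"marker_id": markers["marker_id"], "linkage_group": "LG01", "cm": pos / 1e6 * 2.0}
    )
    track = map_rate_track(map_df, markers, g, 1_000_000)
    assert track["rate"].iloc[:-1].to_numpy() == pytest.approx(2.0, rel=1e-9)
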