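"""G/mLOD linkage metric, grouping, genetic distances, map summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recohot.genome import uniform_genome
from recohot.linkage import (
    ContingencyCounts,
    g_statistic,
    genetic_distances,
    group_markers,
    map_summary,
    mlod,
    pairwise_mlod,
    pairwise_recfrac,
    summarize_totals,
)
from recohot.simulate import SimConfig, simulate_ril


# -- independent oracle: naive loop evaluation of the printed formulas ------
def naive_g(table):
    table = [list(map(float, row)) for row in table]
    total = sum(map(sum, table))
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    s = 0.0
    for i, r in enumerate(table):
        for j, o in enumerate(r):
            if o > 0:
                e = rows[i] * cols[j] / total
                s += o * math.log(o / e)
    return math.sqrt(max(2.0 * s, 0.0))


def naive_mlod(G, d):
    E = math.exp(-(G**2) / (2 * (d - 1)))
    return (((4 - E) * E - 3) * (d - 1) + G**2) / (2 * math.log(10))


def test_g_zero_at_independence():
    assert g_statistic(np.array([[10.0, 10.0], [10.0, 10.0]])) == pytest.approx(0.0, abs=1e-9)


def test_g_worked_example():
    # 2×2 table [[30,10],[10,30]]: 2Σo·ln(o/e) ≈ 20.93, G ≈ 4.575
    G = g_statistic(np.array([[30, 10], [10, 30]]))
    assert G == pytest.approx(4.574923578660294, rel=1e-12)
    assert g_statistic(np.array([[30, 10], [10, 30]]), classic=True) == pytest.approx(G**2, rel=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_g_scales_as_sqrt_of_count_scale(seed):
    rng = np.random.default_rng(seed)
    t = rng.integers(1, 50, size=(3, 3)).astype(float)
    assert g_statistic(t * 10) == pytest.approx(math.sqrt(10) * g_statistic(t), rel=1e-9)


def test_negative_count_rejected():
    with pytest.raises(ValueError):
        ContingencyCounts(np.array([[1.0, -2.0], [0.0, 3.0]]))


def test_mlod_null_and_worked_example():
    for d in (2, 3, 4, 9):
        assert mlod(0.0, d) == pytest.approx(0.0, abs=1e-12)
    assert mlod(3.0, 2) == pytest.approx(1.3125057994033735, rel=1e-12)
    with pytest.raises(ValueError):
        mlod(1.0, 1)


def test_mlod_monotone_and_asymptote():
    d = 4
    grid = np.linspace(0.01, 20, 400)
    vals = np.array([mlod(g, d) for g in grid])
    assert (np.diff(vals) > 0).all()
    G = 40.0
    assert mlod(G, d) == pytest.approx((G**2 - 3 * (d - 1)) / (2 * math.log(10)), rel=1e-6)


def test_g_and_mlod_agree_with_naive_oracle():
    rng = np.random.default_rng(1234)
    for _ in range(100):
        t = rng.integers(0, 40, size=(3, 3)).astype(float)
        if t.sum() == 0:
            continue
        g_pkg = g_statistic(t)
        g_ref = naive_g(t)
        assert g_pkg == pytest.approx(g_ref, rel=1e-10, abs=1e-10)
        cc = ContingencyCounts(t)
        if cc.dof >= 2:
            assert mlod(g_pkg, cc.dof) == pytest.approx(naive_mlod(g_ref, cc.dof), rel=1e-10)


def test_unlinked_chromosomes_form_two_groups():
    g = uniform_genome(2, 5_000_000, 2.0)
    gm, _ = simulate_ril(g, SimConfig(n_lines=100, n_markers=25, missing_rate=0.0, seed=21))
    groups = group_markers(gm, mlod_threshold=5.0)
    assert groups.n_groups == 2
    chrom_of = gm.markers["chrom"].to_numpy()
    for idx in groups.groups():
        assert len(set(chrom_of[idx])) == 1


def test_extreme_threshold_gives_singletons():
    g = uniform_genome(1, 5_000_000, 2.0)
    gm, _ = simulate_ril(g, SimConfig(n_lines=50, n_markers=10, missing_rate=0.0, seed=2))
    groups = group_markers(gm, mlod_threshold=1e9)
    assert groups.n_groups == gm.n_markers
    with pytest.raises(ValueError):
        group_markers(gm, mlod_threshold=0.0)


def test_grouping_matches_bruteforce_components():
    import networkx as nx

    g = uniform_genome(2, 8_000_000, 2.0)
    gm, _ = simulate_ril(g, SimConfig(n_lines=80, n_markers=25, seed=13))
    thr = 5.0
    m = pairwise_mlod(gm)
    G = nx.Graph()
    G.add_nodes_from(range(gm.n_markers))
    for i in range(gm.n_markers):
        for j in range(i + 1, gm.n_markers):
            if m[i, j] >= thr:
                G.add_edge(i, j)
    expected = {frozenset(c) for c in nx.connected_components(G)}
    got = {frozenset(idx.tolist()) for idx in group_markers(gm, thr).groups()}
    assert got == expected


def test_group_sizes_partition_markers(small_sim):
    _, gm, _, _ = small_sim
    sub = gm.subset_markers(np.arange(0, gm.n_markers, 20))  # keep grouping cheap
    groups = group_markers(sub, 5.0)
    assert groups.sizes().sum() == sub.n_markers


def test_identical_markers_have_zero_distance(matrix_factory):
    gm = matrix_factory(["abab", "abab"], positions=[0, 1000])
    md = genetic_distances(gm)
    assert md["cm"].tolist() == [0.0, 0.0]


def test_ril_corrected_haldane_closed_form(matrix_factory):
    # R = 2/10; RIL correction r = 0.2/1.6 = 0.125; Haldane −50·ln(0.75)
    left = "aaaaabbbbb"
    right = "aaaabbbbba"  # mismatches in samples 4 and 9 → R = 2/10
    gm = matrix_factory([left, right], positions=[0, 1000])
    md = genetic_distances(gm, ril_correction=True, mapping="haldane")
    assert md["cm"].iloc[1] == pytest.approx(-50.0 * math.log(0.75), rel=1e-9)
    md2 = genetic_distances(gm, ril_correction=False, mapping="haldane")
    assert md2["cm"].iloc[1] == pytest.approx(-50.0 * math.log(1 - 0.4), rel=1e-9)


def test_f6_map_recovers_planted_genetic_length():
    # 50 Mb at 1 cM/Mb: 50 cM truth; recovered within 15% at n = 200 lines
    g = uniform_genome(1, 50_000_000, 1.0)
    gm, _ = simulate_ril(g, SimConfig(n_lines=200, n_markers=100, missing_rate=0.0, seed=17))
    md = genetic_distances(gm)
    recovered = md["cm"].max()
    assert abs(recovered - 50.0) / 50.0 < 0.15


def test_summarize_totals_reproduces_published_cells():
    assert summarize_totals(4837, 2915.46)["marker_density"] == pytest.approx(1.66, abs=0.005)
    assert summarize_totals(694, 119.66)["marker_density"] == pytest.approx(5.80, abs=0.005)
    assert summarize_totals(2383, 1533.47, 1026.62)["markers_per_mb"] == pytest.approx(2.32, abs=0.005)


def test_map_summary_gap_statistics():
    import pandas as pd

    map_df = pd.DataFrame(
        {
            "marker_id": list("abcdef"),
            "linkage_group": ["g1"] * 5 + ["g2"],
            "cm": [0.0, 2.0, 4.0, 10.0, 12.0, 0.0],
        }
    )
    s = map_summary(map_df, {"g1": 2.0}).set_index("linkage_group")
    assert s.loc["g1", "max_gap_cm"] == 6.0
    assert s.loc["g1", "gap_lt5_pct"] == pytest.approx(75.0)
    assert s.loc["g1", "marker_density"] == pytest.approx(5 / 12.0)
    assert s.loc["g1", "markers_per_mb"] == pytest.approx(2.5)
    assert np.isnan(s.loc["g2", "marker_density"])  # single marker: undefined
    with pytest.raises(ValueError):
        map_summary(map_df.iloc[0:0])


def test_pairwise_recfrac_properties(matrix_factory):
    reps = 12  # ≥ 10 co-called lines so entries are reliable
    gm = matrix_factory(["ab" * reps, "ba" * reps, "ab" * reps], positions=[0, 1000, 2000])
    R, reliable = pairwise_recfrac(gm, min_shared=10)
    assert np.allclose(np.diag(R), 0.0)
    assert R[0, 1] == pytest.approx(1.0)  # perfectly repulsed
    assert R[0, 2] == pytest.approx(0.0)
    assert np.allclose(R, R.T, equal_nan=True)
    assert reliable.all()


def test_pairwise_recfrac_matches_bruteforce():
    g = uniform_genome(1, 5_000_000, 3.0)
    gm, _ = simulate_ril(g, SimConfig(n_lines=50, n_markers=20, seed=3))
    R, reliable = pairwise_recfrac(gm, min_shared=10)
    calls = gm.calls
    for i in range(20):
        for j in range(i + 1, 20):
            hom = np.isin(calls[i], [0, 1]) & np.isin(calls[j], [0, 1])
            if hom.sum() >= 10:
                expect = (calls[i][hom] != calls[j][hom]).mean()
                assert R[i, j] == pytest.approx(expect, abs=1e-12)
            else:
                assert not reliable[i, j] and np.isnan(R[i, j])
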