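"""Meiosis-simulator behaviour: Poisson crossover counts, landscape
placement, selfing heterozygosity decay, determinism."""

import numpy as np
import pytest
from scipy import stats

from recohot.genome import GenomeSpec, HotspotInterval, uniform_genome
from recohot.io import CODE_MISSING, write_genotypes
from recohot.simulate import SimConfig, simulate_gamete, simulate_panel, simulate_ril


def _pair(genome):
    a = {c: (np.array([genome.length(c)]), np.array([0])) for c in genome.names}
    b = {c: (np.array([genome.length(c)]), np.array([1])) for c in genome.names}
    return {c: (a[c], b[c]) for c in genome.names}


def test_zero_rate_landscape_gives_intact_parental_haplotype():
    g = uniform_genome(2, 1_000_000, 0.0)
    rng = np.random.default_rng(0)
    gam, xo = simulate_gamete(_pair(g), g, rng)
    for c in g.names:
        assert xo[c].size == 0
        assert gam[c][1].size == 1  # single ancestry segment


def test_crossover_count_mean_matches_genetic_length():
    # 100 Mb at 1 cM/Mb: 1 Morgan, so mean crossovers per gamete = 1.0;
    # over 10,000 gametes the mean lies within 3 s.e. (±0.03).
    g = uniform_genome(1, 100_000_000, 1.0)
    rng = np.random.default_rng(42)
    pair = _pair(g)
    counts = np.array([simulate_gamete(pair, g, rng)[1]["chr01"].size for _ in range(10_000)])
    assert 0.97 <= counts.mean() <= 1.03
    # goodness of fit against Poisson(1) at alpha = 0.01
    kmax = 6
    obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
    pmf = stats.poisson.pmf(np.arange(kmax), 1.0)
    exp = np.append(pmf, 1 - pmf.sum()) * counts.size
    _, p = stats.chisquare(obs, exp)
    assert p > 0.01


def test_crossovers_concentrate_by_landscape_mass():
    # fold-10 hotspot on 1% of the chromosome attracts ~10/109 of crossovers
    g = GenomeSpec([("c1", 100_000_000)], 1.0, [HotspotInterval("c1", 49_000_000, 50_000_000, 10.0)])
    rng = np.random.default_rng(3)
    pair = _pair(g)
    inside = total = 0
    for _ in range(4000):
        xo = simulate_gamete(pair, g, rng)[1]["c1"]
        total += xo.size
        inside += int(np.sum((xo >= 49_000_000) & (xo < 50_000_000)))
    share = inside / total
    expected = 10.0 / 109.0
    assert abs(share - expected) < 3 * np.sqrt(expected * (1 - expected) / total)


def test_f2_heterozygosity_is_half():
    g = uniform_genome(2, 5_000_000, 2.0)
    _, truth = simulate_ril(g, SimConfig(n_lines=300, generations=2, n_markers=200, missing_rate=0.0, seed=5))
    hets = np.array([bp / g.total_bp for bp in truth.het_bp.values()])
    se = hets.std(ddof=1) / np.sqrt(hets.size)
    assert abs(hets.mean() - 0.5) < 3 * se


def test_selfing_halves_heterozygosity_each_generation():
    g = uniform_genome(4, 5_000_000, 2.0)
    for gens in (3, 4):
        _, truth = simulate_ril(g, SimConfig(n_lines=250, generations=gens, n_markers=100, missing_rate=0.0, seed=gens))
        hets = np.array([bp / g.total_bp for bp in truth.het_bp.values()])
        se = hets.std(ddof=1) / np.sqrt(hets.size)
        assert abs(hets.mean() - 0.5 ** (gens - 1)) < 3 * se


def test_missingness_planted_at_configured_rate():
    g = uniform_genome(2, 5_000_000, 2.0)
    gm, _ = simulate_ril(g, SimConfig(n_lines=100, n_markers=500, missing_rate=0.04, seed=9))
    assert (gm.calls == CODE_MISSING).mean() == pytest.approx(0.04, abs=0.005)


def test_fixed_seed_reproduces_byte_identical_output(tmp_path):
    g = uniform_genome(2, 2_000_000, 3.0)
    cfg = SimConfig(n_lines=10, n_markers=100, seed=77)
    out = []
    for tag in ("x", "y"):
        gm, truth = simulate_ril(g, cfg)
        path = tmp_path / f"{tag}.tsv"
        write_genotypes(gm, path)
        out.append((path.read_bytes(), truth.total()))
    assert out[0] == out[1]


def test_truth_counts_are_conserved(small_sim):
    _, _, truth, _ = small_sim
    assert truth.per_sample().sum() == truth.total() == truth.per_chrom().sum()
    assert truth.window_counts(100_000)["count"].sum() == truth.total()


def test_truth_hotspot_share_matches_landscape_mass(study_sim):
    genome, _, truth, _ = study_sim
    share = truth.fraction_in_hotspots()
    mass = genome.hotspot_mass_fraction()
    n = truth.total()
    assert abs(share - mass) < 4 * np.sqrt(mass * (1 - mass) / n)


def test_single_founder_panel_is_monomorphic():
    g = uniform_genome(2, 2_000_000, 3.0)
    cfg = SimConfig(n_lines=5, n_markers=50, missing_rate=0.0, seed=1)
    gm, truth = simulate_panel(g, 1, 5, cfg, apply_filters=False)
    assert truth.total() == 0
    assert (gm.calls == gm.calls[:, [0]]).all()


def test_degenerate_landscape_puts_all_switches_in_hot_window():
    g = GenomeSpec([("c1", 10_000_000)], 1e-4, [HotspotInterval("c1", 4_000_000, 4_100_000, 1e7)])
    cfg = SimConfig(n_lines=10, n_markers=100, missing_rate=0.0, seed=2)
    _, truth = simulate_panel(g, 4, 10, cfg, mosaic_depth=1.0, apply_filters=False)
    for per in truth.junctions.values():
        pos = per["c1"]
        assert np.all((pos >= 4_000_000) & (pos < 4_100_000))
    assert truth.total() > 0


def test_panel_filters_apply_and_error_when_empty():
    from recohot.io import MarkerFilterError

    g = uniform_genome(1, 2_000_000, 3.0)
    cfg = SimConfig(n_lines=10, n_markers=60, missing_rate=0.0, seed=4)
    gm, _ = simulate_panel(g, 6, 10, cfg, mosaic_depth=5.0)
    assert gm.n_markers > 0
    with pytest.raises(MarkerFilterError):
        simulate_panel(g, 1, 10, cfg)  # monomorphic markers all fail MAF


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(generations=1)
    with pytest.raises(ValueError):
        SimConfig(missing_rate=1.0)
    with pytest.raises(ValueError):
        SimConfig(interference="gamma")
    with pytest.raises(ValueError):
        SimConfig(n_markers=0)
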