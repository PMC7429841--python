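import numpy as np
import pandas as pd
import pytest

from recohot.genome import GenomeSpec, HotspotInterval, scaled_study_genome
from recohot.io import GenotypeMatrix
from recohot.pipeline import detect_events
from recohot.simulate import SimConfig, simulate_ril


@pytest.fixture
def tiny_genome():
    """Two 5-Mb chromosomes, 2 cM/Mb, one 100-kb 10× hotspot on chr01."""
    return GenomeSpec(
        [("chr01", 5_000_000), ("chr02", 5_000_000)],
        2.0,
        [HotspotInterval("chr01", 2_000_000, 2_100_000, 10.0)],
    )


def make_matrix(chars, chroms=None, positions=None, samples=None):
    """Small genotype matrix from rows of call characters."""
    chars = [list(row) for row in chars]
    n, m = len(chars), len(chars[0])
    code = {"a": 0, "b": 1, "h": 2, "-": -1}
    calls = np.array([[code[c] for c in row] for row in chars], dtype=np.int8)
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(n)],
            "chrom": chroms if chroms is not None else ["chr01"] * n,
            "pos": positions if positions is not None else np.arange(n) * 1000,
        }
    )
    return GenotypeMatrix(markers, samples or [f"s{j}" for j in range(m)], calls)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def small_sim():
    """Mid-size RIL simulation shared across test modules (seeded)."""
    genome = scaled_study_genome(n_chrom=4, chrom_bp=10_000_000)
    gm, truth = simulate_ril(genome, SimConfig(n_lines=60, n_markers=1200, seed=7))
    events = detect_events(gm)
    return genome, gm, truth, events


@pytest.fixture(scope="session")
def study_sim():
    """Full study-condition simulation: 200 F6 lines, 20 × 10 Mb chromosomes,
    two planted 20-fold 100-kb hotspots per chromosome."""
    genome = scaled_study_genome()
    gm, truth = simulate_ril(genome, SimConfig(seed=101))
    events = detect_events(gm)
    return genome, gm, truth, events
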