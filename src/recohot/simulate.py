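"""Forward simulation of meiosis for RIL pedigrees and founder-mosaic panels.

Two study designs are emulated:

* an F6 recombinant inbred line (RIL) population: a biparental F1 selfed for
  ``generations − 1`` rounds, one meiosis pair per generation, with crossover
  counts Poisson-distributed at the landscape's genetic length (no
  interference) and positions drawn from the normalised landscape density;
* a natural panel: each accession is a homozygous mosaic of founder
  haplotypes whose switch points are drawn from the same landscape, with the
  number of switches scaled by a historical depth factor.

Haplotypes are stored as ancestry mosaics — arrays of segment end positions
plus founder labels — so genotype extraction at marker positions is a
``searchsorted``.  Truth tracks record, per sample and chromosome, the
positions where the finished diplotype's ancestry state changes: the
crossover junctions that survive the pedigree and are observable in marker
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .io import CODE_A, CODE_B, CODE_H, CODE_MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "TruthTrack",
    "simulate_gamete",
    "simulate_ril",
    "simulate_panel",
    "simulate_gene_annotation",
]


@dataclass
class SimConfig:
    """Population-level simulation settings.

    Defaults mirror the study design being emulated: 200 F6 lines, marker
    missingness well under the 5% map-filter ceiling, and markers dense
    enough (~5 kb spacing on a 10 Mb chromosome) to resolve the 10 kb
    breakpoint-flank rule.
    """

    n_lines: int = 200
    generations: int = 6
    n_markers: int = 2000  # per chromosome
    missing_rate: float = 0.03
    marker_type: str = "snp"  # "snp" | "indel"
    seed: int = 0
    interference: str = "none"

    def __post_init__(self) -> None:
        if self.generations < 2:
            raise ValueError("generations must be >= 2 (F2 or later)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_markers < 1:
            raise ValueError("need at least one marker per chromosome")
        if self.marker_type not in ("snp", "indel"):
            raise ValueError(f"unknown marker type {self.marker_type!r}")
        if self.interference != "none":
            raise ValueError("only interference-free (Poisson) meiosis is modelled")


# ---------------------------------------------------------------------------
# mosaic primitives
# ---------------------------------------------------------------------------

Mosaic = tuple[np.ndarray, np.ndarray]  # (segment end positions, founder labels)


def _merge(ends: np.ndarray, anc: np.ndarray) -> Mosaic:
    """Fuse adjacent segments with identical ancestry."""
    if ends.size <= 1:
        return ends, anc
    keep = np.append(anc[1:] != anc[:-1], True)
    return ends[keep], anc[keep]


def _slice(ends: np.ndarray, anc: np.ndarray, lo: int, hi: int) -> Mosaic:
    """Segments of a mosaic restricted to [lo, hi)."""
    i0 = int(np.searchsorted(ends, lo, side="right"))
    i1 = int(np.searchsorted(ends, hi, side="left"))
    e = ends[i0 : i1 + 1].copy()
    e[-1] = hi
    return e, anc[i0 : i1 + 1].copy()


def _recombine(h1: Mosaic, h2: Mosaic, xpos: np.ndarray, start: int) -> Mosaic:
    """Mosaic copying from h1/h2 alternately, switching at each ``xpos``."""
    L = int(h1[0][-1])
    cuts = np.concatenate(([0], xpos, [L]))
    pieces_e: list[np.ndarray] = []
    pieces_a: list[np.ndarray] = []
    for k in range(cuts.size - 1):
        lo, hi = int(cuts[k]), int(cuts[k + 1])
        if hi <= lo:
            continue
        src = h1 if (start + k) % 2 == 0 else h2
        e, a = _slice(src[0], src[1], lo, hi)
        pieces_e.append(e)
        pieces_a.append(a)
    return _merge(np.concatenate(pieces_e), np.concatenate(pieces_a))


def _sample_positions(genome: GenomeSpec, chrom: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` crossover positions from the normalised landscape density."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    starts, ends, rates = genome.segments(chrom)
    mass = rates * (ends - starts)
    total = mass.sum()
    if total == 0:
        return np.empty(0, dtype=np.int64)
    seg = rng.choice(mass.size, size=n, p=mass / total)
    u = rng.random(n)
    pos = (starts[seg] + u * (ends[seg] - starts[seg])).astype(np.int64)
    L = genome.length(chrom)
    pos = np.clip(pos, 1, L - 1)
    pos = np.unique(pos)  # coincident breakpoints collapse (measure-zero event)
    return pos


def simulate_gamete(
    pair: dict[str, tuple[Mosaic, Mosaic]],
    genome: GenomeSpec,
    rng: np.random.Generator,
) -> tuple[dict[str, Mosaic], dict[str, np.ndarray]]:
    """One meiosis: a recombinant gamete from a pair of parental haplotypes.

    Per chromosome the crossover count is Poisson with mean equal to the
    landscape genetic length in Morgans; positions follow the landscape
    density; the starting homolog is chosen at random.  Returns the gamete
    mosaic and the crossover positions, keyed by chromosome.
    """
    gamete: dict[str, Mosaic] = {}
    xovers: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        h1, h2 = pair[chrom]
        lam = genome.genetic_length_morgans(chrom)
        n = int(rng.poisson(lam)) if lam > 0 else 0
        xpos = _sample_positions(genome, chrom, n, rng)
        start = int(rng.integers(2))
        gamete[chrom] = _recombine(h1, h2, xpos, start)
        xovers[chrom] = xpos
    return gamete, xovers


def _diplotype(h1: Mosaic, h2: Mosaic) -> Mosaic:
    """Merge two haplotype mosaics into a genotype-state mosaic.

    States: CODE_A where both homologs carry class-a ancestry, CODE_B for
    class-b, CODE_H where they differ.  Junctions across which the state
    does not change (e.g. complementary switches at one position) vanish.
    """
    ends = np.union1d(h1[0], h2[0])
    rep = ends - 1  # any point inside each union segment
    a1 = h1[1][np.searchsorted(h1[0], rep, side="right")]
    a2 = h2[1][np.searchsorted(h2[0], rep, side="right")]
    state = np.where(a1 == a2, np.where(a1 % 2 == 0, CODE_A, CODE_B), CODE_H).astype(np.int8)
    return _merge(ends, state)


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class TruthTrack:
    """Ground-truth crossover junctions surviving into each sample.

    ``junctions[sample][chrom]`` holds the strictly increasing positions at
    which the sample's observable ancestry state changes.  For the RIL these
    are diplotype-state changes accumulated over the whole selfing pedigree;
    for the panel they are founder-class switch points.
    """

    genome: GenomeSpec
    junctions: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    het_bp: dict[str, int] | None = None

    def total(self) -> int:
        return sum(pos.size for per in self.junctions.values() for pos in per.values())

    def per_sample(self) -> pd.Series:
        return pd.Series(
            {s: sum(p.size for p in per.values()) for s, per in self.junctions.items()},
            name="n_crossovers",
        )

    def per_chrom(self) -> pd.Series:
        out = {c: 0 for c in self.genome.names}
        for per in self.junctions.values():
            for chrom, pos in per.items():
                out[chrom] += pos.size
        return pd.Series(out, name="n_crossovers")

    def window_counts(self, width: int) -> pd.DataFrame:
        """True junction counts on the non-overlapping window grid."""
        win = self.genome.windows(width)
        counts = np.zeros(len(win), dtype=np.int64)
        offsets = {}
        for chrom in self.genome.names:
            idx = win.index[win["chrom"] == chrom]
            offsets[chrom] = int(idx[0])
        for per in self.junctions.values():
            for chrom, pos in per.items():
                if pos.size:
                    np.add.at(counts, offsets[chrom] + pos // width, 1)
        win = win.copy()
        win["count"] = counts
        return win

    def het_fraction(self) -> float:
        """Residual heterozygous genome fraction, averaged over samples."""
        if self.het_bp is None:
            raise ValueError("heterozygosity tracked only for RIL simulations")
        total = self.genome.total_bp
        return float(np.mean([bp / total for bp in self.het_bp.values()]))

    def fraction_in_hotspots(self) -> float:
        """Share of true junctions falling inside planted hotspot intervals."""
        hot = 0
        tot = 0
        for per in self.junctions.values():
            for chrom, pos in per.items():
                tot += pos.size
                for hs in self.genome.chrom_hotspots(chrom):
                    hot += int(np.sum((pos >= hs.start) & (pos < hs.end)))
        return hot / tot if tot else 0.0

    def to_bed(self, path) -> None:
        """Write junctions as BED6 (1 bp features, sample in the name field)."""
        rows = []
        for sample in sorted(self.junctions):
            for chrom in self.genome.names:
                for p in self.junctions[sample].get(chrom, ()):
                    rows.append((chrom, int(p), int(p) + 1, sample, 0, "."))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# marker scaffolding
# ---------------------------------------------------------------------------


def _draw_marker_positions(genome: GenomeSpec, n_per_chrom: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Sorted unique uniform marker positions per chromosome."""
    out = {}
    for chrom in genome.names:
        L = genome.length(chrom)
        if n_per_chrom > L:
            raise ValueError(f"cannot place {n_per_chrom} unique markers on {chrom} ({L} bp)")
        pos = np.unique(rng.integers(0, L, size=int(n_per_chrom * 1.2) + 8))
        while pos.size < n_per_chrom:
            pos = np.unique(np.concatenate([pos, rng.integers(0, L, size=n_per_chrom)]))
        out[chrom] = np.sort(rng.choice(pos, n_per_chrom, replace=False))
    return out


def _marker_frame(genome: GenomeSpec, positions: dict[str, np.ndarray], prefix: str) -> pd.DataFrame:
    frames = []
    for chrom in genome.names:
        pos = positions[chrom]
        frames.append(
            pd.DataFrame(
                {
                    "marker_id": [f"{prefix}_{chrom}_{p:09d}" for p in pos],
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _genotype_from_state(state_mosaic: Mosaic, pos: np.ndarray) -> np.ndarray:
    ends, state = state_mosaic
    return state[np.searchsorted(ends, pos, side="right")].astype(np.int8)


# ---------------------------------------------------------------------------
# population simulators
# ---------------------------------------------------------------------------


def _founder_haplotype(genome: GenomeSpec, label: int) -> dict[str, Mosaic]:
    return {
        chrom: (np.array([genome.length(chrom)], dtype=np.int64), np.array([label], dtype=np.int64))
        for chrom in genome.names
    }


def simulate_ril(genome: GenomeSpec, cfg: SimConfig) -> tuple[GenotypeMatrix, TruthTrack]:
    """Simulate an F_g RIL population by single-seed descent selfing.

    Each line descends from one F1 plant through ``generations − 1`` selfing
    rounds; every round draws two independent gametes from the current
    plant.  Genotypes at the shared marker set are coded a/b/h with missing
    calls planted at ``cfg.missing_rate``.  The truth track records the
    surviving, observable crossover junctions and the residual heterozygous
    bp of every line.
    """
    master = np.random.default_rng(cfg.seed)
    positions = _draw_marker_positions(genome, cfg.n_markers, master)
    markers = _marker_frame(genome, positions, "SLAF" if cfg.marker_type == "snp" else "ID")
    streams = master.spawn(cfg.n_lines)

    hapA = _founder_haplotype(genome, 0)
    hapB = _founder_haplotype(genome, 1)

    samples = [f"RIL_{i + 1:03d}" for i in range(cfg.n_lines)]
    calls = np.empty((len(markers), cfg.n_lines), dtype=np.int8)
    truth = TruthTrack(genome, {}, het_bp={})

    chrom_slices = {}
    off = 0
    for chrom in genome.names:
        n = positions[chrom].size
        chrom_slices[chrom] = slice(off, off + n)
        off += n

    for j, (sample, rng) in enumerate(zip(samples, streams)):
        plant = {chrom: (hapA[chrom], hapB[chrom]) for chrom in genome.names}
        for _ in range(cfg.generations - 1):
            g1, _ = simulate_gamete(plant, genome, rng)
            g2, _ = simulate_gamete(plant, genome, rng)
            plant = {chrom: (g1[chrom], g2[chrom]) for chrom in genome.names}
        junctions = {}
        het_bp = 0
        for chrom in genome.names:
            dip = _diplotype(*plant[chrom])
            junctions[chrom] = dip[0][:-1].copy()  # state-change positions
            seg_len = np.diff(np.concatenate(([0], dip[0])))
            het_bp += int(seg_len[dip[1] == CODE_H].sum())
            g = _genotype_from_state(dip, positions[chrom])
            if cfg.missing_rate > 0:
                g = g.copy()
                g[rng.random(g.size) < cfg.missing_rate] = CODE_MISSING
            calls[chrom_slices[chrom], j] = g
        truth.junctions[sample] = junctions
        truth.het_bp[sample] = het_bp

    gm = GenotypeMatrix(markers, samples, calls)
    return gm, truth


def simulate_panel(
    genome: GenomeSpec,
    n_founders: int,
    n_accessions: int,
    cfg: SimConfig,
    mosaic_depth: float = 1.0,
    apply_filters: bool = True,
    min_call: float = 0.8,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, TruthTrack]:
    """Simulate a natural panel of founder-mosaic accessions.

    Founders carry one of two deep ancestral allele classes (even labels →
    class a, odd → class b), so mosaic switches between opposite-class
    founders are visible in biallelic genotypes.  Accessions are homozygous
    single-haplotype mosaics (a selfing crop); switch counts per chromosome
    are Poisson with mean ``mosaic_depth`` × genetic length in Morgans,
    positions drawn from the landscape.  The default depth of 1.0 matches
    the observed scale of a breeding panel: about two detectable events
    per chromosome per accession on a ~2-Morgan chromosome.  Truth records
    class-changing (observable) switch points.  Emitted markers optionally pass the panel
    filters: call frequency > ``min_call`` and MAF > ``min_maf``.
    """
    if n_founders < 1:
        raise ValueError("need at least one founder")
    from .io import MarkerFilterError, filter_panel_markers

    master = np.random.default_rng(cfg.seed)
    positions = _draw_marker_positions(genome, cfg.n_markers, master)
    markers = _marker_frame(genome, positions, "ID" if cfg.marker_type == "indel" else "SLAF")
    streams = master.spawn(n_accessions)

    samples = [f"ACC_{i + 1:03d}" for i in range(n_accessions)]
    calls = np.empty((len(markers), n_accessions), dtype=np.int8)
    truth = TruthTrack(genome, {})

    chrom_slices = {}
    off = 0
    for chrom in genome.names:
        n = positions[chrom].size
        chrom_slices[chrom] = slice(off, off + n)
        off += n

    for j, (sample, rng) in enumerate(zip(samples, streams)):
        junctions = {}
        for chrom in genome.names:
            L = genome.length(chrom)
            lam = genome.genetic_length_morgans(chrom) * mosaic_depth
            n_sw = int(rng.poisson(lam)) if (lam > 0 and n_founders > 1) else 0
            xpos = _sample_positions(genome, chrom, n_sw, rng)
            founders = np.empty(xpos.size + 1, dtype=np.int64)
            founders[0] = rng.integers(n_founders)
            for k in range(1, founders.size):  # consecutive founders must differ
                founders[k] = (founders[k - 1] + 1 + rng.integers(n_founders - 1)) % n_founders
            ends = np.concatenate([xpos, [L]])
            state = np.where(founders % 2 == 0, CODE_A, CODE_B).astype(np.int8)
            ends_m, state_m = _merge(ends, state)
            junctions[chrom] = ends_m[:-1].copy()
            g = state_m[np.searchsorted(ends_m, positions[chrom], side="right")].astype(np.int8)
            if cfg.missing_rate > 0:
                g = g.copy()
                g[rng.random(g.size) < cfg.missing_rate] = CODE_MISSING
            calls[chrom_slices[chrom], j] = g
        truth.junctions[sample] = junctions

    gm = GenotypeMatrix(markers, samples, calls)
    if apply_filters:
        gm = filter_panel_markers(gm, min_call=min_call, min_maf=min_maf)
        if gm.n_markers == 0:
            raise MarkerFilterError(
                "call-rate/MAF filter removed every marker "
                f"(min_call={min_call}, min_maf={min_maf})"
            )
    return gm, truth


# ---------------------------------------------------------------------------
# synthetic gene annotation (for the hotspot→gene stage)
# ---------------------------------------------------------------------------

_GO_VOCAB = [
    ("GO:0006950", "BP", "response to stress"),
    ("GO:0009733", "BP", "response to auxin"),
    ("GO:0046686", "BP", "response to cadmium ion"),
    ("GO:0009620", "BP", "response to fungus"),
    ("GO:0010025", "BP", "wax biosynthetic process"),
    ("GO:0005524", "MF", "ATP binding"),
    ("GO:0003677", "MF", "DNA binding"),
    ("GO:0003723", "MF", "RNA binding"),
    ("GO:0005515", "MF", "protein binding"),
    ("GO:0005634", "CC", "nucleus"),
    ("GO:0005737", "CC", "cytoplasm"),
    ("GO:0016020", "CC", "membrane"),
]


def simulate_gene_annotation(
    genome: GenomeSpec,
    rng: np.random.Generator,
    genes_per_mb: float = 5.0,
    mean_len: int = 3000,
    terms_per_gene: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic gene models plus a GO mapping, for pipeline demonstrations.

    Returns (genes, go_map, go_labels): genes with gene_id/chrom/start/end/
    strand, a 2-column gene→term mapping, and a term/aspect/label table
    drawn from a small plant-GO vocabulary.
    """
    genes = []
    for chrom in genome.names:
        L = genome.length(chrom)
        n = rng.poisson(genes_per_mb * L / 1e6)
        starts = np.sort(rng.integers(0, max(L - mean_len, 1), size=n))
        lengths = rng.geometric(1.0 / mean_len, size=n).clip(200, None)
        for k, (s, ln) in enumerate(zip(starts, lengths)):
            genes.append(
                (f"gene_{chrom}_{k + 1:05d}", chrom, int(s), int(min(s + ln, L)), "+-"[int(rng.integers(2))])
            )
    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
    mapping = []
    for gid in genes_df["gene_id"]:
        for t in range(rng.poisson(terms_per_gene)):
            term = _GO_VOCAB[int(rng.integers(len(_GO_VOCAB)))]
            mapping.append((gid, term[0]))
    go_map = pd.DataFrame(mapping, columns=["gene_id", "term_id"]).drop_duplicates()
    labels = pd.DataFrame(_GO_VOCAB, columns=["term_id", "aspect", "label"])
    return genes_df, go_map, labels
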