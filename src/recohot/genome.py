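"""Genome and recombination-landscape specification.

A genome is an ordered set of named chromosomes with physical lengths in bp
plus a piecewise-constant recombination landscape: a per-chromosome baseline
rate in cM/Mb and a list of hotspot intervals inside which the rate is
multiplied by a fold factor.  The landscape defines, per chromosome, a
genetic length (its integral, in cM) and a normalised crossover density used
by the meiosis simulator.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HotspotInterval", "GenomeSpec", "uniform_genome", "scaled_study_genome"]


@dataclass(frozen=True)
class HotspotInterval:
    """A planted hotspot: [start, end) on ``chrom`` at ``fold`` × baseline."""

    chrom: str
    start: int
    end: int
    fold: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"hotspot on {self.chrom}: end must exceed start")
        if self.fold < 1:
            raise ValueError(f"hotspot fold must be >= 1, got {self.fold}")


@dataclass
class GenomeSpec:
    """Chromosome lengths and a piecewise-constant crossover landscape.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    baseline_cm_per_mb
        Baseline recombination rate, either one value for every chromosome or
        a per-chromosome mapping.
    hotspots
        Intervals where the local rate is ``fold`` × baseline.  Hotspots on
        one chromosome must not overlap.
    """

    chromosomes: list[tuple[str, int]]
    baseline_cm_per_mb: float | dict[str, float] = 1.0
    hotspots: list[HotspotInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        self._lengths = dict(self.chromosomes)
        for hs in self.hotspots:
            if hs.chrom not in self._lengths:
                raise ValueError(f"hotspot on unknown chromosome {hs.chrom}")
            if hs.start < 0 or hs.end > self._lengths[hs.chrom]:
                raise ValueError(f"hotspot {hs} outside chromosome bounds")
        by_chrom: dict[str, list[HotspotInterval]] = {}
        for hs in self.hotspots:
            by_chrom.setdefault(hs.chrom, []).append(hs)
        for chrom, lst in by_chrom.items():
            lst.sort(key=lambda h: h.start)
            for a, b in zip(lst, lst[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping hotspots on {chrom}")
        self._hotspots_by_chrom = by_chrom

    # -- basic accessors -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def baseline(self, chrom: str) -> float:
        if isinstance(self.baseline_cm_per_mb, dict):
            return float(self.baseline_cm_per_mb[chrom])
        return float(self.baseline_cm_per_mb)

    def chrom_hotspots(self, chrom: str) -> list[HotspotInterval]:
        return self._hotspots_by_chrom.get(chrom, [])

    # -- landscape geometry ----------------------------------------------
    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Piecewise-constant landscape as (starts, ends, rate cM/Mb)."""
        L = self.length(chrom)
        base = self.baseline(chrom)
        breaks = {0, L}
        for hs in self.chrom_hotspots(chrom):
            breaks.update((hs.start, hs.end))
        edges = np.array(sorted(breaks), dtype=np.int64)
        starts, ends = edges[:-1], edges[1:]
        rates = np.full(starts.size, base, dtype=float)
        for hs in self.chrom_hotspots(chrom):
            inside = (starts >= hs.start) & (ends <= hs.end)
            rates[inside] = base * hs.fold
        return starts, ends, rates

    def genetic_length_cm(self, chrom: str) -> float:
        starts, ends, rates = self.segments(chrom)
        return float(np.sum(rates * (ends - starts) / 1e6))

    def genetic_length_morgans(self, chrom: str) -> float:
        return self.genetic_length_cm(chrom) / 100.0

    @property
    def total_cm(self) -> float:
        return sum(self.genetic_length_cm(c) for c in self.names)

    def hotspot_mass_fraction(self, chrom: str | None = None) -> float:
        """Share of crossover mass falling inside hotspot intervals."""
        chroms = [chrom] if chrom is not None else self.names
        hot = 0.0
        tot = 0.0
        for c in chroms:
            starts, ends, rates = self.segments(c)
            mass = rates * (ends - starts) / 1e6
            tot += mass.sum()
            for hs in self.chrom_hotspots(c):
                inside = (starts >= hs.start) & (ends <= hs.end)
                hot += mass[inside].sum()
        if tot == 0:
            return 0.0
        return hot / tot

    # -- window grids ----------------------------------------------------
    def windows(self, width: int) -> pd.DataFrame:
        """Non-overlapping tiling of every chromosome at ``width`` bp.

        The last window of each chromosome is truncated at the chromosome
        end.  Returns a frame with chrom/start/end.
        """
        if width <= 0:
            raise ValueError("window width must be positive")
        rows = []
        for chrom, L in self.chromosomes:
            starts = np.arange(0, L, width, dtype=np.int64)
            ends = np.minimum(starts + width, L)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def to_dict(self) -> dict:
        """JSON-serialisable form (inverse of :meth:`from_dict`)."""
        return {
            "chromosomes": [[c, int(l)] for c, l in self.chromosomes],
            "baseline_cm_per_mb": self.baseline_cm_per_mb,
            "hotspots": [
                {"chrom": h.chrom, "start": h.start, "end": h.end, "fold": h.fold}
                for h in self.hotspots
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeSpec":
        return cls(
            [(c, int(l)) for c, l in d["chromosomes"]],
            d.get("baseline_cm_per_mb", 1.0),
            [HotspotInterval(**h) for h in d.get("hotspots", [])],
        )

    def hotspot_window_mask(self, windows: pd.DataFrame) -> np.ndarray:
        """Boolean mask over ``windows`` rows overlapping any hotspot."""
        mask = np.zeros(len(windows), dtype=bool)
        for hs in self.hotspots:
            hit = (
                (windows["chrom"] == hs.chrom)
                & (windows["start"] < hs.end)
                & (windows["end"] > hs.start)
            )
            mask |= hit.to_numpy()
        return mask


def uniform_genome(
    n_chrom: int, chrom_bp: int, cm_per_mb: float, hotspots: list[HotspotInterval] | None = None
) -> GenomeSpec:
    """Equal-length chromosomes at a single baseline rate."""
    chroms = [(f"chr{i + 1:02d}", chrom_bp) for i in range(n_chrom)]
    return GenomeSpec(chroms, cm_per_mb, hotspots or [])


def scaled_study_genome(
    n_chrom: int = 20,
    chrom_bp: int = 10_000_000,
    cm_per_chrom: float = 145.0,
    hotspots_per_chrom: int = 2,
    hotspot_bp: int = 100_000,
    fold: float = 20.0,
    rng: np.random.Generator | None = None,
) -> GenomeSpec:
    """A 20-chromosome genome scaled down to ``chrom_bp`` per chromosome.

    Physical length is shrunk but the per-chromosome *baseline* genetic
    length is kept at a peanut-like ~145 cM (≈1.45 crossovers per meiosis
    per chromosome; planted hotspots add their mass on top), since
    crossovers per chromosome — not cM/Mb — is the biologically conserved
    quantity.  Hotspot intervals are aligned to the ``hotspot_bp`` grid so
    that planted hotspots coincide with analysis windows; they are placed in
    interior windows (never the terminal window of a chromosome) to avoid
    end-censoring by the flank-span filter.  With ``rng=None`` placement is
    deterministic (evenly spaced); with an rng, windows are drawn at random.
    """
    base = cm_per_mb = cm_per_chrom / (chrom_bp / 1e6)
    n_win = chrom_bp // hotspot_bp
    if hotspots_per_chrom >= n_win - 2:
        raise ValueError("too many hotspots for the chromosome length")
    chroms = [(f"chr{i + 1:02d}", chrom_bp) for i in range(n_chrom)]
    hotspots: list[HotspotInterval] = []
    for name, _ in chroms:
        if rng is None:
            picks = np.linspace(1, n_win - 2, hotspots_per_chrom + 2)[1:-1].astype(int)
        else:
            picks = np.sort(rng.choice(np.arange(1, n_win - 1), hotspots_per_chrom, replace=False))
        for w in picks:
            hotspots.append(HotspotInterval(name, int(w) * hotspot_bp, (int(w) + 1) * hotspot_bp, fold))
    return GenomeSpec(chroms, base, hotspots)
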