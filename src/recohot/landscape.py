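"""Windowed recombination landscapes and related summaries.

Chromosomes are tiled with fixed-width, non-overlapping, 0-based half-open
windows (100 kb for event loci, 1000 kb for rates; the last window of each
chromosome is truncated).  Passing crossover events are assigned to exactly
one window by breakpoint-interval midpoint, so window counts are conserved.
Rates divide counts by the true (truncated) window width in Mb; when a
genetic map is supplied, windows carry cM/Mb instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSpec
from .io import CODE_MISSING, GenotypeMatrix
from .crossover import STATUS_PASS, CrossoverEvent, events_frame

__all__ = [
    "window_counts",
    "window_rates",
    "genome_mean_rate",
    "map_rate_track",
    "length_correlation",
    "conservation_score",
]


def window_counts(
    events: list[CrossoverEvent] | pd.DataFrame,
    genome: GenomeSpec,
    width: int = 100_000,
    statuses: tuple[str, ...] = (STATUS_PASS,),
    step: int | None = None,
) -> pd.DataFrame:
    """Per-window counts of crossover events, assigned by midpoint.

    Default is a non-overlapping tiling; passing ``step`` < ``width`` slides
    overlapping windows instead (counts are then deliberately not conserved
    and carry an ``overlapping`` attribute in the frame's attrs).
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    df = events if isinstance(events, pd.DataFrame) else events_frame(events)
    if len(df):
        df = df[df["status"].isin(statuses)]
    if step is not None and step != width:
        return _sliding_counts(df, genome, width, step)
    win = genome.windows(width)
    counts = np.zeros(len(win), dtype=np.int64)
    offsets = {}
    for chrom in genome.names:
        idx = win.index[win["chrom"] == chrom]
        offsets[chrom] = int(idx[0])
    for chrom, grp in (df.groupby("chrom") if len(df) else ()):
        mid = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2).astype(np.int64)
        L = genome.length(chrom)
        mid = np.clip(mid, 0, L - 1)
        np.add.at(counts, offsets[chrom] + mid // width, 1)
    win["count"] = counts
    win["n_samples"] = df["sample"].nunique() if len(df) else 0
    return win


def _sliding_counts(df, genome, width, step):
    rows = []
    for chrom in genome.names:
        L = genome.length(chrom)
        starts = np.arange(0, max(L - width, 0) + 1, step, dtype=np.int64)
        ends = starts + width
        sub = df[df["chrom"] == chrom]
        mid = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)
        counts = [(int(((mid >= s) & (mid < e)).sum())) for s, e in zip(starts, ends)]
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "count": counts}))
    out = pd.concat(rows, ignore_index=True)
    out.attrs["overlapping"] = True
    return out


def window_rates(track: pd.DataFrame, per_sample: bool = False, n_samples: int | None = None) -> pd.DataFrame:
    """Add an events-per-Mb rate column to a window-count track.

    Rates use the true (possibly truncated) window width.  With
    ``per_sample`` the rate is additionally divided by the number of
    contributing samples.
    """
    track = track.copy()
    width_mb = (track["end"] - track["start"]) / 1e6
    rate = track["count"] / width_mb
    if per_sample:
        ns = n_samples if n_samples is not None else int(track.get("n_samples", pd.Series([0])).max())
        if ns <= 0:
            raise ValueError("per-sample rates need a positive sample count")
        rate = rate / ns
    track["rate"] = rate
    return track


def genome_mean_rate(track: pd.DataFrame) -> float:
    """Width-weighted mean rate = total events / total Mb (exact identity)."""
    width_mb = (track["end"] - track["start"]) / 1e6
    return float(track["count"].sum() / width_mb.sum())


def map_rate_track(
    map_df: pd.DataFrame,
    markers: pd.DataFrame,
    genome: GenomeSpec,
    width: int = 1_000_000,
) -> pd.DataFrame:
    """Per-window cM/Mb from a genetic map anchored at physical positions.

    Cumulative cM is linearly interpolated at window boundaries from the
    mapped markers (matched to ``markers`` by marker_id for bp positions,
    one linkage group per chromosome); the window rate is ΔcM over the
    true window width in Mb.  Windows outside the mapped span get rate 0.
    """
    pos_by_id = dict(zip(markers["marker_id"], markers["pos"]))
    chrom_by_id = dict(zip(markers["marker_id"], markers["chrom"]))
    win = genome.windows(width)
    win["cm"] = 0.0
    rates = np.zeros(len(win))
    for _, grp in map_df.groupby("linkage_group", sort=False):
        ids = grp["marker_id"].to_numpy()
        chroms = {chrom_by_id[i] for i in ids if i in chrom_by_id}
        if len(chroms) != 1:
            continue  # group straddling chromosomes cannot be anchored
        chrom = chroms.pop()
        bp = np.array([pos_by_id[i] for i in ids], dtype=float)
        cm = grp["cm"].to_numpy(dtype=float)
        order = np.argsort(bp, kind="stable")
        bp, cm = bp[order], cm[order]
        cm = np.maximum.accumulate(cm)  # physical order may locally invert the map
        idx = win.index[win["chrom"] == chrom].to_numpy()
        edges_lo = win.loc[idx, "start"].to_numpy(dtype=float)
        edges_hi = win.loc[idx, "end"].to_numpy(dtype=float)
        cm_lo = np.interp(edges_lo, bp, cm)
        cm_hi = np.interp(edges_hi, bp, cm)
        rates[idx] = (cm_hi - cm_lo) / ((edges_hi - edges_lo) / 1e6)
    win["rate"] = rates
    return win


def length_correlation(counts, lengths) -> tuple[float, float]:
    """Pearson correlation between per-chromosome event counts and lengths.

    Returns (r, two-sided p) from the t transform with n − 2 df.  Requires
    at least three chromosomes and non-constant inputs.
    """
    x = np.asarray(counts, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired (count, length) observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def conservation_score(gm: GenotypeMatrix, windows: pd.DataFrame) -> pd.DataFrame:
    """Haplotype-conservation fraction per window.

    A line carries a *conserved* window haplotype when all its non-missing
    calls in the window share one state; lines with an internal state
    change are local recombinants and carry a haplotype of their own.  The
    score is the fraction of called lines carrying the modal conserved
    haplotype, so heavily recombining windows — where lines fragment into
    many mosaic haplotypes — score low.  Windows without markers (or
    without any called line) are unscored (NaN).
    """
    out = windows.copy()
    scores = np.full(len(out), np.nan)
    for chrom in out["chrom"].unique():
        pos, calls = gm.chrom_slice(chrom)
        idx = out.index[out["chrom"] == chrom]
        for i in idx:
            lo, hi = out.at[i, "start"], out.at[i, "end"]
            m = (pos >= lo) & (pos < hi)
            if not m.any():
                continue
            sub = calls[m]  # markers × lines
            has = np.stack([(sub == s).any(axis=0) for s in (0, 1, 2)])
            voting = has.any(axis=0)
            if not voting.any():
                continue
            uniform = has & (has.sum(axis=0) == 1)  # exactly one state observed
            scores[i] = uniform[:, voting].sum(axis=1).max() / voting.sum()
    out["conservation"] = scores
    return out
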