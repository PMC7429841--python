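"""Hotspot calling: Poisson threshold, fold-over-mean, RIL rule, consensus.

Three window-level rules mirror the study design:

* ``poisson`` — the smallest count k* whose upper tail P(X ≥ k*) under
  Poisson(λ = mean events per 100-kb window) drops to α flags windows with
  count ≥ k*;
* ``fold3x`` — windows whose rate is at least ``fold`` × the genome mean
  (paper-replication mode fixes the literal 25 n/Mb threshold, three times
  the study's 8.40 mean);
* ``ril50`` — windows of the RIL genetic map with strictly more than
  50 cM/Mb.

The consensus definition intersects four toggleable criteria: low haplotype
conservation, the RIL rule, panel rate above ``fold`` × the panel mean, and
weak pairwise linkage (high mean recombination fraction) in the window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import poisson as _poisson

__all__ = [
    "poisson_threshold",
    "call_poisson_hotspots",
    "call_fold_hotspots",
    "call_ril_hotspots",
    "consensus_hotspots",
    "hotspot_fraction",
]


def poisson_threshold(lam: float, alpha: float) -> int:
    """Smallest integer k with upper-tail P(X ≥ k) ≤ α under Poisson(λ)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    # sf(k-1) = P(X >= k); isf gives the largest k-1 with sf > alpha
    k = int(_poisson.isf(alpha, lam)) + 1
    while k > 1 and _poisson.sf(k - 2, lam) <= alpha:
        k -= 1
    return k


def _calls(track: pd.DataFrame, mask: np.ndarray, rule: str, threshold: float) -> pd.DataFrame:
    out = track.loc[mask, [c for c in ("chrom", "start", "end", "count", "rate") if c in track.columns]].copy()
    out["rules_fired"] = rule
    out["threshold"] = threshold
    return out.reset_index(drop=True)


def call_poisson_hotspots(
    track: pd.DataFrame, alpha: float = 0.01, bonferroni: bool = False
) -> pd.DataFrame:
    """Windows whose event count reaches the Poisson-tail threshold.

    λ is the mean count per window of the track; with ``bonferroni`` the
    α is divided by the number of windows.
    """
    lam = float(track["count"].mean())
    a = alpha / len(track) if bonferroni else alpha
    k = poisson_threshold(lam, a)
    calls = _calls(track, (track["count"] >= k).to_numpy(), "poisson", float(k))
    calls.attrs.update(alpha=a, lam=lam, k_star=k)
    return calls


def call_fold_hotspots(
    track: pd.DataFrame, fold: float = 3.0, fixed_threshold: float | None = None
) -> pd.DataFrame:
    """Windows with rate ≥ fold × genome mean (or a fixed literal threshold).

    The genome mean is the width-weighted mean (total events / total Mb).
    ``fixed_threshold`` replicates the study's literal 25 n/Mb cut.
    """
    if "rate" not in track.columns:
        raise ValueError("track has no rate column; call window_rates first")
    width_mb = (track["end"] - track["start"]) / 1e6
    mean = float(track["count"].sum() / width_mb.sum()) if "count" in track.columns else float(
        np.average(track["rate"], weights=width_mb)
    )
    thr = fixed_threshold if fixed_threshold is not None else fold * mean
    calls = _calls(track, (track["rate"] >= thr).to_numpy(), "fold3x", float(thr))
    calls.attrs.update(mean_rate=mean, fold=fold)
    return calls


def call_ril_hotspots(cm_track: pd.DataFrame, threshold: float = 50.0) -> pd.DataFrame:
    """Windows of a RIL cM/Mb track strictly above the absolute threshold."""
    return _calls(cm_track, (cm_track["rate"] > threshold).to_numpy(), "ril50", float(threshold))


def consensus_hotspots(
    windows: pd.DataFrame,
    ril_calls: pd.DataFrame | None = None,
    panel_track: pd.DataFrame | None = None,
    conservation: pd.DataFrame | None = None,
    recfrac_weakness: pd.DataFrame | None = None,
    panel_fold: float = 3.0,
    conservation_quantile: float = 0.25,
    weakness_quantile: float = 0.75,
) -> pd.DataFrame:
    """Multi-principle consensus over a common window grid.

    A window is consensus iff every supplied criterion holds: haplotype
    conservation below its ``conservation_quantile``; membership in the RIL
    rule calls; panel rate ≥ ``panel_fold`` × panel mean; and mean pairwise
    recombination fraction (``value`` column of ``recfrac_weakness``) above
    its ``weakness_quantile``.  Passing None for a component drops that
    criterion.  All tracks must share the grid of ``windows``.
    """
    key = windows[["chrom", "start", "end"]].reset_index(drop=True)

    def _check_grid(df: pd.DataFrame, name: str) -> None:
        if not df[["chrom", "start", "end"]].reset_index(drop=True).equals(key):
            raise ValueError(f"{name} track is not on the consensus window grid")

    ok = np.ones(len(key), dtype=bool)
    fired = ["consensus"]
    if ril_calls is not None:
        in_ril = key.merge(ril_calls[["chrom", "start", "end"]].assign(_hit=True), how="left")["_hit"].notna()
        ok &= in_ril.to_numpy()
        fired.append("ril50")
    if panel_track is not None:
        _check_grid(panel_track, "panel")
        width_mb = (panel_track["end"] - panel_track["start"]) / 1e6
        mean = float(panel_track["count"].sum() / width_mb.sum())
        ok &= (panel_track["rate"] >= panel_fold * mean).to_numpy()
        fired.append("fold3x")
    if conservation is not None:
        _check_grid(conservation, "conservation")
        cons = conservation["conservation"].to_numpy()
        cut = np.nanquantile(cons, conservation_quantile)
        ok &= np.where(np.isnan(cons), False, cons <= cut)
    if recfrac_weakness is not None:
        _check_grid(recfrac_weakness, "recfrac")
        w = recfrac_weakness["value"].to_numpy()
        cut = np.nanquantile(w, weakness_quantile)
        ok &= np.where(np.isnan(w), False, w >= cut)
    out = key.loc[ok].copy()
    out["rules_fired"] = ",".join(fired)
    out["threshold"] = np.nan
    return out.reset_index(drop=True)


def hotspot_fraction(n_calls: int, total_regions: int) -> float:
    """Hotspot share as a percentage, reported to 2 decimals."""
    if total_regions <= 0:
        raise ValueError("total_regions must be positive")
    return round(100.0 * n_calls / total_regions, 2)
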