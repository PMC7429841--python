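"""Hotspot-to-gene intersection and GO-category frequency tallies.

Genes are collected from the 100-kb interval around each hotspot window
(a symmetric flank on both sides; flank = 0 gives strict overlap) and their
functional categories tallied against a user-supplied gene→GO mapping.
Frequencies are per-term — terms overlap, so they need not sum to one —
and genes without any annotation are counted in an explicit bucket.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = ["genes_near_hotspots", "go_frequency"]


def genes_near_hotspots(
    calls: pd.DataFrame, genes: pd.DataFrame, flank: int = 100_000
) -> pd.DataFrame:
    """Genes overlapping any hotspot window expanded by ``flank`` bp per side.

    Intervals are half-open; a gene starting exactly at window_end + flank
    is excluded.  The result is deduplicated by gene_id and ordered as in
    ``genes``; it is invariant to the ordering of ``calls``.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if calls.empty or genes.empty:
        return genes.iloc[0:0].copy()
    trees: dict[str, IntervalTree] = {}
    for _, w in calls.iterrows():
        lo = max(int(w["start"]) - flank, 0)
        hi = int(w["end"]) + flank
        trees.setdefault(w["chrom"], IntervalTree()).addi(lo, hi)
    keep = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes.itertuples(index=False)):
        tree = trees.get(g.chrom)
        if tree is not None and tree.overlap(int(g.start), int(g.end)):
            keep[i] = True
    out = genes.loc[keep].drop_duplicates(subset="gene_id")
    return out.reset_index(drop=True)


def go_frequency(
    genes: pd.DataFrame, go_map: pd.DataFrame, labels: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-term gene counts and fractions for a gene set.

    Returns rows (term_id, aspect, label, count, fraction) sorted by count;
    ``fraction`` divides by the number of annotated genes in the set.  A
    final ``unannotated`` row counts genes absent from the mapping.
    """
    gene_ids = set(genes["gene_id"])
    hits = go_map[go_map["gene_id"].isin(gene_ids)]
    annotated = set(hits["gene_id"])
    n_annot = len(annotated)
    counts = hits.groupby("term_id")["gene_id"].nunique().sort_values(ascending=False)
    out = counts.rename("count").reset_index()
    out["fraction"] = out["count"] / n_annot if n_annot else np.nan
    if labels is not None:
        out = out.merge(labels, on="term_id", how="left")
    else:
        out["aspect"] = pd.NA
        out["label"] = pd.NA
    out = out[["term_id", "aspect", "label", "count", "fraction"]]
    unann = len(gene_ids) - n_annot
    out.loc[len(out)] = ["unannotated", pd.NA, "no GO annotation", unann, np.nan]
    return out
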