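"""Linkage grouping: independence-G metric, modified LOD, map summaries.

Marker pairs are scored with an independence test on their joint genotype
table.  The statistic used here is

    G = sqrt( 2 Σ o · ln(o/e) )

with ``o`` the observed count per cell and ``e`` the margin-product
expectation (row total × column total / grand total); cells with o = 0
contribute zero.  Note the square root: G² equals the classical likelihood-
ratio statistic, and a ``classic_g`` switch lets the pairwise metric feed
the classical (un-rooted) statistic into the LOD transform instead.

The modified LOD score is the approximate transformation

    mLOD = { [ (4 − E) · E − 3 ] · (d − 1) + G² } / (2 ln 10),
    E = exp( −G² / (2 (d − 1)) ),

with ``d`` the contingency-table degrees of freedom.  Markers are then
clustered into linkage groups by single linkage on the thresholded pairwise
mLOD graph.  Adjacent-marker genetic distances come from observed
recombinant fractions with an optional RIL-by-selfing correction and a
Haldane or Kosambi mapping function.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .io import CODE_A, CODE_B, CODE_MISSING, GenotypeMatrix

__all__ = [
    "ContingencyCounts",
    "g_statistic",
    "mlod",
    "pairwise_mlod",
    "group_markers",
    "LinkageGroupSet",
    "genetic_distances",
    "map_summary",
    "summarize_totals",
    "pairwise_recfrac",
]

logger = logging.getLogger(__name__)

LN10_2 = 2.0 * math.log(10.0)


@dataclass
class ContingencyCounts:
    """Observed genotype-pair counts with margin-product expectations."""

    observed: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.ndim != 2:
            raise ValueError("observed counts must be a 2-D table")
        if (self.observed < 0).any():
            raise ValueError("negative count in contingency table")

    @property
    def expected(self) -> np.ndarray:
        o = self.observed
        total = o.sum()
        if total == 0:
            raise ValueError("empty contingency table")
        return np.outer(o.sum(axis=1), o.sum(axis=0)) / total

    @property
    def dof(self) -> int:
        r = int((self.observed.sum(axis=1) > 0).sum())
        c = int((self.observed.sum(axis=0) > 0).sum())
        return max(r - 1, 0) * max(c - 1, 0)


def _g_inner(o: np.ndarray, e: np.ndarray) -> float:
    """2 Σ o ln(o/e), zero-observation cells contributing 0."""
    mask = o > 0
    if (e[mask] <= 0).any():
        raise ValueError("zero expected count where observations exist")
    return float(2.0 * np.sum(o[mask] * np.log(o[mask] / e[mask])))


def g_statistic(counts: ContingencyCounts | np.ndarray, classic: bool = False) -> float:
    """Independence statistic for one genotype-pair table.

    Default is the square-rooted form sqrt(2 Σ o ln(o/e)); ``classic=True``
    returns the classical likelihood-ratio statistic 2 Σ o ln(o/e) itself.
    """
    if not isinstance(counts, ContingencyCounts):
        counts = ContingencyCounts(counts)
    inner = _g_inner(counts.observed, counts.expected)
    inner = max(inner, 0.0)  # guard tiny negative round-off at independence
    return inner if classic else math.sqrt(inner)


def mlod(G: float, d: int) -> float:
    """Modified LOD transform of the square-rooted independence statistic.

    mLOD(0, d) = 0 for any d; as G grows the score approaches
    (G² − 3(d−1)) / (2 ln 10).
    """
    if d < 2:
        raise ValueError("degrees of freedom must be >= 2 for the mLOD transform")
    if G < 0:
        raise ValueError("G must be non-negative")
    g2 = G * G
    E = math.exp(-g2 / (2.0 * (d - 1)))
    return (((4.0 - E) * E - 3.0) * (d - 1) + g2) / LN10_2


def _mlod_vec(g2: np.ndarray, d: np.ndarray) -> np.ndarray:
    d = np.maximum(d, 2)  # printed transform is singular at d=1; see docs
    E = np.exp(-g2 / (2.0 * (d - 1)))
    return (((4.0 - E) * E - 3.0) * (d - 1) + g2) / LN10_2


def _pair_tables(calls: np.ndarray) -> np.ndarray:
    """All pairwise 3×3 genotype tables, shape (3, 3, p, p).

    One-hot products over samples; missing calls drop out of every table.
    """
    X = np.stack([(calls == k) for k in (0, 1, 2)]).astype(np.float64)  # (3, p, n)
    return np.einsum("gin,hjn->ghij", X, X, optimize=True)


def pairwise_mlod(gm: GenotypeMatrix, classic_g: bool = False) -> np.ndarray:
    """Symmetric matrix of pairwise mLOD scores between all markers.

    ``classic_g=True`` squares the classical statistic before the transform
    (i.e. treats 2Σo·ln(o/e) itself as G); the default treats it as G², as
    implied by the square-rooted G definition.
    """
    counts = _pair_tables(gm.calls)  # (3,3,p,p)
    p = gm.n_markers
    row = counts.sum(axis=1)  # (3,p,p) margins of marker i
    col = counts.sum(axis=0)  # (3,p,p) margins of marker j
    tot = counts.sum(axis=(0, 1))  # (p,p)
    tot_safe = np.where(tot > 0, tot, 1.0)
    e = row[:, None, :, :] * col[None, :, :, :] / tot_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts / np.where(e > 0, e, 1.0)), 0.0)
    inner = np.maximum(2.0 * term.sum(axis=(0, 1)), 0.0)
    g2 = inner**2 if classic_g else inner
    d = (np.maximum((row > 0).sum(axis=0) - 1, 0) * np.maximum((col > 0).sum(axis=0) - 1, 0)).astype(float)
    out = _mlod_vec(g2, d)
    out[d < 1] = 0.0  # monomorphic against monomorphic: no linkage information
    out[np.arange(p), np.arange(p)] = 0.0
    return out


@dataclass
class LinkageGroupSet:
    """Partition of markers into linkage groups.

    Groups are numbered LG01, LG02, … in order of first marker appearance;
    ``assignments`` maps each marker index to its group index.
    """

    marker_ids: list[str]
    assignments: np.ndarray

    @property
    def n_groups(self) -> int:
        return int(self.assignments.max()) + 1 if self.assignments.size else 0

    def groups(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.assignments == g) for g in range(self.n_groups)]

    def group_names(self) -> list[str]:
        return [f"LG{g + 1:02d}" for g in range(self.n_groups)]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_groups)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "linkage_group": [f"LG{g + 1:02d}" for g in self.assignments],
            }
        )


def group_markers(gm: GenotypeMatrix, mlod_threshold: float = 5.0, classic_g: bool = False) -> LinkageGroupSet:
    """Single-linkage clustering of markers on the pairwise-mLOD graph.

    Two markers share a group iff they are connected by a chain of pairs
    with mLOD ≥ ``mlod_threshold``.  Deterministic for a fixed input.
    """
    if mlod_threshold <= 0:
        raise ValueError("mlod_threshold must be positive")
    if gm.n_markers < 2:
        raise ValueError("need at least two markers to group")
    m = pairwise_mlod(gm, classic_g=classic_g)
    graph = sp.csr_matrix(m >= mlod_threshold)
    _, labels = connected_components(graph, directed=False)
    # renumber in order of first appearance so output is stable
    order = {}
    renumbered = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        renumbered[i] = order[lab]
    return LinkageGroupSet(list(gm.markers["marker_id"]), renumbered)


# ---------------------------------------------------------------------------
# genetic distances and map summaries
# ---------------------------------------------------------------------------


def _recfrac_adjacent(calls: np.ndarray) -> np.ndarray:
    """Observed recombinant fraction between consecutive markers.

    Informative lines are those homozygous (a or b) at both markers;
    heterozygous or missing calls are excluded.  Pairs with no informative
    line get R = 0 (and a warning upstream).
    """
    a = calls[:-1]
    b = calls[1:]
    hom_a = (a == CODE_A) | (a == CODE_B)
    hom_b = (b == CODE_A) | (b == CODE_B)
    inf = hom_a & hom_b
    rec = inf & (a != b)
    n_inf = inf.sum(axis=1)
    with np.errstate(invalid="ignore"):
        R = np.where(n_inf > 0, rec.sum(axis=1) / np.maximum(n_inf, 1), 0.0)
    return R


def _map_fn(r: np.ndarray, mapping: str) -> np.ndarray:
    if mapping == "haldane":
        return -50.0 * np.log1p(-2.0 * r)
    if mapping == "kosambi":
        return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    raise ValueError(f"unknown mapping function {mapping!r}")


def genetic_distances(
    gm: GenotypeMatrix,
    groups: LinkageGroupSet | None = None,
    mapping: str = "haldane",
    ril_correction: bool = True,
    generations: int | None = None,
) -> pd.DataFrame:
    """Cumulative cM positions per linkage group from adjacent-marker R.

    Markers are ordered by physical position within each group.  With
    ``ril_correction`` the observed recombinant fraction R between the
    nearly homozygous lines of a selfing RIL is deflated to a per-meiosis
    r = R / (2 − 2R) (the inverse of R = 2r / (1 + 2r) at F∞) before the
    mapping function.  R implying r ≥ 0.5 is capped at r = 0.49 with a
    logged warning.  Returns a map frame (marker_id, linkage_group, cm).
    """
    if groups is None:
        # default: one group per chromosome in physical order
        chroms = gm.markers["chrom"].to_numpy()
        labels = {c: i for i, c in enumerate(dict.fromkeys(chroms))}
        groups = LinkageGroupSet(list(gm.markers["marker_id"]), np.array([labels[c] for c in chroms]))
    rows = []
    for gname, idx in zip(groups.group_names(), groups.groups()):
        sub = gm.markers.iloc[idx]
        order = idx[np.argsort(sub["pos"].to_numpy(), kind="stable")]
        ids = gm.markers["marker_id"].to_numpy()[order]
        if order.size == 1:
            rows.append(pd.DataFrame({"marker_id": ids, "linkage_group": gname, "cm": [0.0]}))
            continue
        R = _recfrac_adjacent(gm.calls[order])
        r = R / (2.0 - 2.0 * R) if ril_correction else R.copy()
        over = r >= 0.5
        if over.any():
            logger.warning("%d adjacent pair(s) in %s at r >= 0.5; capped at 0.49", int(over.sum()), gname)
            r[over] = 0.49
        cm = np.concatenate([[0.0], np.cumsum(_map_fn(r, mapping))])
        rows.append(pd.DataFrame({"marker_id": ids, "linkage_group": gname, "cm": cm}))
    return pd.concat(rows, ignore_index=True)


def summarize_totals(n_markers: int, genetic_cm: float, physical_mb: float | None = None) -> dict:
    """Density and per-Mb ratios from whole-group totals.

    This is the arithmetic behind a published map-summary row: marker
    density = n / cM; markers per Mb = n / Mb; cM per Mb = cM / Mb.  The two
    per-Mb quantities are kept distinct and both reported.
    """
    out = {
        "n_markers": int(n_markers),
        "genetic_cm": float(genetic_cm),
        "marker_density": n_markers / genetic_cm if genetic_cm > 0 else math.nan,
    }
    if physical_mb is not None:
        out["physical_mb"] = float(physical_mb)
        out["markers_per_mb"] = n_markers / physical_mb
        out["cm_per_mb"] = genetic_cm / physical_mb
    return out


def map_summary(map_df: pd.DataFrame, physical_mb: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-group map quality statistics in published-table layout.

    Columns: n_markers, genetic_cm, marker_density (markers/cM), max_gap_cm,
    gap_lt5_pct, and — when physical lengths are supplied — physical_mb,
    markers_per_mb, cm_per_mb.  Single-marker groups report NaN for density
    and gap statistics (undefined).
    """
    if map_df.empty:
        raise ValueError("empty map")
    rows = []
    for lg, grp in map_df.groupby("linkage_group", sort=False):
        cm = np.sort(grp["cm"].to_numpy())
        n = cm.size
        row: dict = {"linkage_group": lg, "n_markers": n}
        if n >= 2:
            length = float(cm[-1] - cm[0])
            gaps = np.diff(cm)
            row.update(
                genetic_cm=length,
                marker_density=n / length if length > 0 else math.nan,
                max_gap_cm=float(gaps.max()),
                gap_lt5_pct=100.0 * float((gaps < 5.0).mean()),
            )
        else:
            row.update(genetic_cm=0.0, marker_density=math.nan, max_gap_cm=math.nan, gap_lt5_pct=math.nan)
        if physical_mb is not None and lg in physical_mb:
            mb = float(physical_mb[lg])
            row.update(physical_mb=mb, markers_per_mb=n / mb, cm_per_mb=row["genetic_cm"] / mb)
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_recfrac(
    gm: GenotypeMatrix, indices: np.ndarray | None = None, min_shared: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise recombination-fraction matrix for a marker group (heat map).

    Returns (R, reliable): R is symmetric with zero diagonal, entry ij the
    recombinant fraction among lines homozygous at both markers; entries
    backed by fewer than ``min_shared`` co-called lines are NaN and flagged
    False in ``reliable``.
    """
    calls = gm.calls if indices is None else gm.calls[np.asarray(indices)]
    if calls.shape[0] < 2:
        raise ValueError("need at least two markers for a heat map")
    A = (calls == CODE_A).astype(np.float64)
    B = (calls == CODE_B).astype(np.float64)
    n_aa = A @ A.T
    n_bb = B @ B.T
    n_ab = A @ B.T
    n_ba = B @ A.T
    informative = n_aa + n_bb + n_ab + n_ba
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(informative > 0, (n_ab + n_ba) / np.maximum(informative, 1), np.nan)
    reliable = informative >= min_shared
    R[~reliable] = np.nan
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(reliable, True)
    return R, reliable
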