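"""Published peanut reference tables and their arithmetic replication.

The package ships the published summary tables of the cultivated-peanut
recombination study it is modelled on: the F6 RIL linkage-map summary
(markers, genetic length, density, gaps, physical length per linkage
group) and the 49-accession panel's per-chromosome crossover counts and
rates, together with the published hotspot counts.  The raw sequencing
data behind those tables were never deposited, so these printed totals are
the replication inputs: every derived ratio (marker density, markers/Mb,
events/Mb, hotspot percentages, the count-vs-length correlation) is
recomputed here from printed numerators and denominators by the same code
paths used for simulated data.

A note on labels: the published map table's "recombination rate (cM/Mb)"
column numerically equals markers ÷ physical Mb, not genetic cM ÷ Mb.  The
replication keeps both quantities, reporting the markers/Mb value against
the printed column and the honest cM/Mb alongside.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .hotspots import hotspot_fraction
from .landscape import length_correlation
from .linkage import summarize_totals

__all__ = [
    "ril_map_table",
    "panel_table",
    "replicate_map_ratios",
    "replicate_panel_rates",
    "count_length_correlation",
    "hotspot_percentages",
    "peanut_genome",
    "RIL_HOTSPOTS",
    "RIL_EVENT_LOCI",
    "PANEL_HOTSPOTS",
    "PANEL_EVENTS",
]

# Published hotspot counts and their denominators.
RIL_EVENT_LOCI = 4837  # crossover-event loci in the RIL map
RIL_HOTSPOTS = {"total": 210, "A": 120, "B": 90}
PANEL_EVENTS = 2073  # crossover events in the 49-accession panel
PANEL_HOTSPOTS = {"total": 163, "A": 49, "B": 114}


def _load(name: str) -> pd.DataFrame:
    with resources.files("recohot.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def ril_map_table(level: str | None = None) -> pd.DataFrame:
    """Published RIL linkage-map summary (20 LGs + subgenome + genome rows)."""
    df = _load("peanut_ril_map.tsv")
    return df if level is None else df[df["level"] == level].reset_index(drop=True)


def panel_table(level: str | None = None) -> pd.DataFrame:
    """Published panel per-chromosome crossover counts, spans and rates."""
    df = _load("peanut_panel_recombination.tsv")
    return df if level is None else df[df["level"] == level].reset_index(drop=True)


def replicate_map_ratios() -> pd.DataFrame:
    """Recompute density, markers/Mb and cM/Mb for every map-table row.

    Adds computed columns next to the printed ones so agreement can be
    checked cell by cell.
    """
    df = ril_map_table().copy()
    comp = [
        summarize_totals(int(r.n_markers), float(r.genetic_cm), float(r.physical_mb))
        for r in df.itertuples()
    ]
    df["marker_density"] = [c["marker_density"] for c in comp]
    df["markers_per_mb"] = [c["markers_per_mb"] for c in comp]
    df["cm_per_mb"] = [c["cm_per_mb"] for c in comp]
    return df


def replicate_panel_rates() -> pd.DataFrame:
    """Recompute events/Mb for every panel-table row from count and span."""
    df = panel_table().copy()
    df["rate_n_per_mb"] = df["n_events"] / df["span_mb"]
    return df


def count_length_correlation() -> tuple[float, float]:
    """Pearson r and p between the panel's 20 per-chromosome (count, Mb) pairs."""
    df = panel_table("chrom")
    return length_correlation(df["n_events"], df["span_mb"])


def hotspot_percentages() -> dict[str, float]:
    """Published hotspot shares recomputed from counts and denominators.

    RIL hotspots are expressed against the RIL map's event loci, panel
    hotspots against the panel's crossover events, as published.  (The
    published A-genome RIL share disagrees with its own numerator/
    denominator — 120/4837 is 2.48, printed as 2.35; the arithmetic value
    is reported.)
    """
    return {
        "ril_total": hotspot_fraction(RIL_HOTSPOTS["total"], RIL_EVENT_LOCI),
        "ril_A": hotspot_fraction(RIL_HOTSPOTS["A"], RIL_EVENT_LOCI),
        "ril_B": hotspot_fraction(RIL_HOTSPOTS["B"], RIL_EVENT_LOCI),
        "panel_total": hotspot_fraction(PANEL_HOTSPOTS["total"], PANEL_EVENTS),
        "panel_A": hotspot_fraction(PANEL_HOTSPOTS["A"], PANEL_EVENTS),
        "panel_B": hotspot_fraction(PANEL_HOTSPOTS["B"], PANEL_EVENTS),
    }


def peanut_genome() -> GenomeSpec:
    """Full-scale peanut genome: published chromosome spans and map rates.

    Chromosome lengths come from the panel table's physical spans; the
    per-chromosome baseline is the published genetic length divided by the
    physical length (true cM/Mb).  No hotspots are planted — this spec is
    for full-scale demonstrations, not truth-tracked recovery.
    """
    spans = panel_table("chrom")
    cms = ril_map_table("chrom").set_index("linkage_group")["genetic_cm"]
    chroms = [(r.chrom, int(r.end_bp)) for r in spans.itertuples()]
    baseline = {
        r.chrom: float(cms[r.chrom]) / (r.end_bp / 1e6) for r in spans.itertuples()
    }
    return GenomeSpec(chroms, baseline, [])
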