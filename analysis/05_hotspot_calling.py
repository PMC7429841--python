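"""Call recombination hotspots and score recovery of the planted truth.

Applies all four rules on the 100-kb grid — Poisson tail threshold,
fold-over-mean (panel), the >50 cM/Mb RIL-map rule, and the multi-
principle consensus — then scores sensitivity and FDR of fold-3 calling
against the planted 20× hotspot windows.
"""

import json
from pathlib import Path

from recohot.crossover import events_frame
from recohot.genome import GenomeSpec
from recohot.io import read_genotypes, read_map
from recohot.landscape import conservation_score, map_rate_track, window_counts, window_rates
from recohot.hotspots import (
    call_fold_hotspots,
    call_poisson_hotspots,
    call_ril_hotspots,
    consensus_hotspots,
    hotspot_fraction,
)
from recohot.pipeline import detect_events

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"
for need in ("ril_events.tsv", "ril_map.tsv"):
    if not (SCRATCH / need).exists():
        raise SystemExit("run analysis/02–04 first")

genome = GenomeSpec.from_dict(json.loads((SCRATCH / "genome.json").read_text()))
win = genome.windows(100_000)
hot_mask = genome.hotspot_window_mask(win)
planted = set(map(tuple, win.loc[hot_mask, ["chrom", "start"]].itertuples(index=False)))

import pandas as pd

ril_events = pd.read_csv(SCRATCH / "ril_events.tsv", sep="\t")
panel_events = pd.read_csv(SCRATCH / "panel_events.tsv", sep="\t")
ril_track = window_rates(window_counts(ril_events, genome, 100_000))
panel_track = window_rates(window_counts(panel_events, genome, 100_000))

fold_calls = call_fold_hotspots(ril_track, fold=3.0)
pois_calls = call_poisson_hotspots(ril_track, alpha=0.01, bonferroni=True)
gm = read_genotypes(SCRATCH / "ril_genotypes.tsv")
cm_track = map_rate_track(read_map(SCRATCH / "ril_map.tsv"), gm.markers, genome, 100_000)
ril_calls = call_ril_hotspots(cm_track, 50.0)
cons = conservation_score(gm, win)
consensus = consensus_hotspots(win, ril_calls, panel_track, cons)

report = {}
for name, calls in [("fold3x", fold_calls), ("poisson", pois_calls),
                    ("ril50", ril_calls), ("consensus", consensus)]:
    called = set(map(tuple, calls[["chrom", "start"]].itertuples(index=False)))
    tp = len(called & planted)
    report[name] = {
        "calls": len(called),
        "pct_of_windows": hotspot_fraction(len(called), len(win)),
        "sensitivity": round(tp / len(planted), 3),
        "fdr": round((len(called) - tp) / max(len(called), 1), 3),
    }
    calls.to_csv(RESULTS / f"sim_hotspots_{name}.tsv", sep="\t", index=False)
    print(f"{name:10s} {report[name]}")

(RESULTS / "sim_hotspot_recovery.json").write_text(json.dumps(report, indent=2) + "\n")
print(f"{len(planted)} planted hotspot windows of {len(win)} total "
      f"({hotspot_fraction(len(planted), len(win))}%)")
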