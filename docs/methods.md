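# Methods

## Populations and genotype coding

Two population designs are handled. A biparental RIL population: an F1
between two inbred parents selfed for g − 1 generations (g = 6 by
default), genotyped at biallelic, hemi-SNP-like markers. A natural panel:
accessions modelled as homozygous mosaics of a small founder set,
genotyped at InDel-like biallelic markers. Calls are coded against the two
parental alleles — `a` (parent-A homozygote), `b` (parent-B homozygote),
`h` (heterozygote), `-` (missing) — which captures hemi-SNP cross types
without committing to nucleotide detail. Coordinates are 0-based,
half-open everywhere internally; VCF and GFF3 are converted at the
boundary.

Marker-selection filters follow the study design exactly as printed:
markers with missing fraction ≤ 5% (inclusive) enter map construction;
panel markers must have call frequency strictly > 0.8 and MAF strictly
> 0.05, a heterozygote contributing one copy of each allele.

## Meiosis model

Crossovers per chromosome per meiosis are Poisson with mean equal to the
landscape's genetic length in Morgans; positions are drawn from the
normalised landscape density. The landscape is piecewise constant: a
per-chromosome baseline in cM/Mb with hotspot intervals at fold × baseline.
Interference is not modelled and no obligate chiasma is enforced — the
simplest model consistent with the Poisson-threshold logic used
downstream; chromosomes may pass through meiosis without crossover.

RIL lines descend by single-seed selfing: each generation draws two
independent gametes from the current plant. Residual heterozygosity
therefore decays as 0.5^(g−1), giving 3.125% at F6. The truth track
records, per line and chromosome, the positions where the finished
diplotype's ancestry state (aa/ab/bb) changes: these are the crossover
junctions that survive the pedigree and are observable in marker data.
Junctions across which the state does not change (complementary switches
at one position on the two homologs) are intentionally not counted — they
are invisible to any genotype-based caller, and this convention is what
makes the exact-recovery property (passing events = true junctions away
from chromosome ends, under dense error-free markers) well defined.

Panel accessions are single-haplotype (homozygous) mosaics, reflecting a
selfing crop. Founders carry one of two deep ancestral allele classes
(even/odd founder labels), so only switches between opposite-class
founders change the emitted genotype; the truth track records exactly
those observable switch points. Switch counts per chromosome are Poisson
with mean `mosaic_depth` × genetic length in Morgans.

All randomness flows from one seed through `numpy.random.default_rng`;
per-sample child streams (`spawn`) keep lines independent and the whole
output byte-reproducible.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| RIL lines | 200 | the emulated study design |
| generations | 6 (F6) | the emulated study design |
| markers per chromosome | 2,000 | ~5 kb spacing on 10 Mb, well under the 10 kb flank rule |
| missing rate | 0.03 | under the 5% map-filter ceiling, as real data must be |
| panel accessions / founders | 49 / 8 | panel size as studied; founder count typical of a breeding program's effective ancestry |
| `mosaic_depth` | 1.0 | reproduces a breeding panel's observed event scale: ≈2 events per chromosome per accession on a ~2-Morgan chromosome (≈2,000 events over 49 accessions × 20 chromosomes) |

The scaled demonstration genome (`scaled_study_genome`) keeps 20
chromosomes but shrinks each to 10 Mb while preserving a peanut-like
baseline genetic length of ~145 cM per chromosome (≈1.45 crossovers per
meiosis). Crossovers per chromosome — not cM/Mb — is the biologically
conserved quantity, so the scaled genome's cM/Mb is high by construction.
Hotspots are planted two per chromosome as 100-kb intervals at 20×
baseline, aligned to the 100-kb window grid so sensitivity/FDR against
the planted truth is unambiguous, and placed in interior windows so the
flank-span filter does not censor them at chromosome ends. These sizes
keep the full simulation-plus-detection cycle around half a minute on one
core; they are the problem sizes used by the test suite and the
acceptance script.

### What the generator does not emulate

Sequencing reads, restriction-site tag distribution and genotyping-error
structure (calls are either correct or missing, never wrong); segregation
distortion; crossover interference; homoeologous exchange between the A
and B subgenomes; population structure or kinship in the panel. Passing
tests therefore demonstrate the correctness of the *calling machinery*
under a clean meiosis model, not robustness to genotyping error — on real
data the smoothing (`smooth_min_markers`) and purity controls exist
precisely because single-marker errors masquerade as double crossovers.

## Crossover calling

Maximal same-state runs become blocks; missing calls are skipped without
breaking runs; block boundaries sit at the midpoint between the bounding
markers, so blocks tile the marker-covered span. Every state change is an
emitted event with its breakpoint interval spanning from the last marker
of the left block to the first marker of the right. Filters, in order of
precedence:

* **ambiguous_excluded** — a flanking block's minority-call fraction
  (introduced by smoothing) exceeds 1 − purity (default purity 0.9), or
  both flanks are heterozygous;
* **short_flank** — a flanking block spans < 10 kb. The flank rule is read
  as "each flanking same-state block must span ≥ 10 kb"; the alternative
  reading (breakpoint interval itself narrow) is available as
  `breakpoint_max_width`, off by default. The status enum carries this
  fourth value because emitted-but-failing events must remain separable
  from review-flagged ones;
* **small_block_flag** — a flanking block spans ≤ 200 kb: retained but
  flagged, mirroring a manual-review step; `drop_small_blocks` automates
  exclusion.

Only `pass` events enter window counts, assigned by breakpoint-interval
midpoint to non-overlapping windows (an optional `step` gives true sliding
windows for exploration, deliberately unconserved). Rates divide by the
true width of the (possibly truncated) final window.

## Linkage metric

The pairwise statistic is computed on the full 3×3 genotype table (a/b/h ×
a/b/h) over co-called samples; zero-observation cells contribute zero, and
G carries the square root so that G² is the classical likelihood-ratio
statistic. The mLOD transform consumes G²; a `classic_g` switch instead
feeds the square of the un-rooted statistic for comparison, since the
grouping literature is ambiguous about which form its tools use. Degrees
of freedom are (rows−1)(cols−1) over nonzero margins; because the printed
transform is singular at d = 1 (a two-class × two-class table, common in a
nearly homozygous F6 when no heterozygote is sampled), the pairwise metric
uses d_eff = max(d, 1 + 1) — i.e. clamps to 2 — and the scalar `mlod()`
rejects d < 2 outright. Pairs with no linkage information (monomorphic
markers, d = 0) score 0.

Grouping is single-linkage: connected components of the mLOD ≥ threshold
graph (threshold 5 by default, the conventional LOD cut). Marker ordering
within groups defaults to physical position; de novo ordering and error
correction are an external mapping tool's contribution and are out of
scope. Distances use R from lines homozygous at both markers; the RIL
correction inverts R = 2r/(1+2r) (selfing RIL at fixation); r ≥ 0.5 is
capped at 0.49 with a logged warning. Haldane is the default map function
(Kosambi available); the source study names neither.

Map summaries report marker density (markers/cM), max gap, the share of
gaps < 5 cM, and both markers/Mb and cM/Mb. The shipped published map
table's "recombination rate (cM/Mb)" column numerically equals markers/Mb,
so replication targets compare against markers/Mb while the honest cM/Mb
is reported alongside. Single-marker groups report NaN density and gap
statistics rather than fabricating values.

## Hotspot rules

* **Poisson**: λ is the mean event count per 100-kb window; k* is the
  smallest k with P(X ≥ k) ≤ α under Poisson(λ). α defaults to 0.01 (the
  source study never states one) with optional Bonferroni across windows;
  both are logged in the call metadata. α is validated to (0, 1) strictly,
  so k* ≥ 1 always.
* **Fold**: rate ≥ fold × the width-weighted genome mean (fold 3);
  paper-replication mode fixes the literal 25 n/Mb threshold (three times
  the published 8.40 mean).
* **RIL absolute**: genetic-map windows strictly above 50 cM/Mb, with
  per-window cM/Mb obtained by interpolating cumulative cM at window
  boundaries from the mapped markers' physical anchors.
* **Consensus**: conjunction of four individually toggleable criteria —
  low haplotype conservation (below the 25% quantile), the RIL rule, panel
  rate ≥ 3× the panel mean, and weak pairwise linkage (mean recombination
  fraction above the 75% quantile); all tracks must share one window grid.

Haplotype conservation is the fraction of called lines carrying the modal
*uniform* window haplotype: a line whose non-missing calls in the window
all share one state carries a conserved haplotype; a line with an internal
state change is a local recombinant. Heavily recombining windows fragment
lines into many mosaic haplotypes and score low — the simulated Spearman
correlation between conservation and window rate is strongly negative
(ρ ≈ −0.7 at 1-Mb windows). A plain modal-state definition carries no
signal in a biparental population, where every window is ~50:50 a/b
regardless of recombination; this is why conservation is defined at the
haplotype level.

Genes are collected from hotspot windows expanded by a symmetric 100-kb
flank (flank 0 gives strict overlap), deduplicated by gene id, and tallied
per GO term against a user-supplied two-column mapping plus a
term/aspect/label table. Frequencies are per-term (terms overlap, so they
need not sum to one) and genes without annotation are counted explicitly.
No enrichment p-values are computed — frequencies only.

## Published-table replication

The raw data behind the emulated study were never deposited, so its
headline counts (4,837 mapped markers, ~30 crossovers per plant, 3,865
hotspot genes) are not reproducible from scratch. The package instead
ships the published summary tables as data and recomputes every *derived*
cell — densities, per-Mb rates, hotspot percentages, the count-vs-length
Pearson correlation (r = 0.72, p = 0.00039 over 20 chromosomes) — from
printed numerators and denominators through the same code paths used for
simulated data. One printed cell is internally inconsistent: the A-genome
RIL hotspot share prints as 2.35% but its own fraction 120/4837 is 2.48%;
the arithmetic value is reported. The scaled simulation uses equal-length
chromosomes (prescribed by the recovery design), which makes the
count-vs-length correlation degenerate there; the correlation is
demonstrated on the published spans instead.

## Numerical choices and degenerate inputs

Coincident crossover positions within one meiosis collapse (integer bp, a
measure-zero event). Ties in thresholds follow the printed inequalities:
≤ for the missing filter, strict > for call-rate/MAF and the 50 cM/Mb
rule, ≥ for the flank span and fold rules. Filters are idempotent and
order-preserving. A chromosome with all calls missing yields no blocks
(logged); a pair of markers with fewer than 10 co-called lines is flagged
unreliable in the heat-map matrix; an empty post-filter panel raises an
error naming the filter. The G statistic clamps tiny negative round-off at
independence to zero before the square root.

## Known limitations

Pairwise mLOD is dense O(p²) in markers — grouping is intended for binned
or thinned marker sets (the analysis driver thins to ~100 markers per
chromosome). The genetic-map length estimate inherits the upward bias of
summing many noisy adjacent-marker distances at finite sample size. The
consensus rule's quantile cuts are pragmatic defaults, not calibrated
error rates. Gene-conversion events, read-level breakpoint refinement and
LD-based historical hotspot inference are out of scope.
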