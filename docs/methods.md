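# Methods

## Coordinates and interval conventions

All coordinates are 0-based half-open (the BED convention) everywhere
inside the package; conversion happens only at I/O boundaries, and
there is none to do for the supported formats. Chromosome names are
compared as exact strings — no `chr` aliasing — because silent aliasing
is a classic source of irreproducible overlap counts. Gene/TSS tables
are TSVs with named header columns rather than BED12, since the
anchors carry non-positional metadata (CGI flag, occupancy metric).

## Binned tracks and fold enrichment

Reads are assigned to fixed-width bins by their midpoint: one read, one
bin, independent of fragment length. Region counts symmetrically sum
the bins whose *midpoints* lie inside the region, so a boundary bin is
never counted by two adjacent regions. Depth normalization is
reads-per-million of the track total.

Fold enrichment over input for a region is

    FE = ((c_chip + ψ) / T_chip) / ((c_in + ψ) / T_in)

with raw counts c, library totals T and pseudocount ψ = 1 by default.
The pseudocount guarantees positivity (needed for log display and rank
tests) and is the simplest defensible treatment of zero-input bins.
FE of a track against itself is exactly 1 for any region and any ψ.

Two bin sizes are defaulted: 200 bp for state-level enrichment and
50 bp for profiles; both are parameters. A deliberate property of
total-read normalization: if enriched regions occupy a fraction ε of
the genome with mean excess enrichment, measured FE deflates by a
factor ≈ 1/(1+ε·excess). The simulator keeps state annotations at a few
percent of the toy genome (as real promoter/enhancer annotations are),
so this bias stays under ~6% — visible in the recovered medians
(≈ 3.8 for a configured 4.0) and well inside the recovery tolerance.

## Statistics

- **Box summaries** use linear interpolation between order statistics
  at positions 1+(n−1)p for quartiles (the spreadsheet "type 7" rule)
  and Tukey whiskers: fences at q1 − 1.5·IQR and q3 + 1.5·IQR, whiskers
  at the most extreme *attained* values inside the fences, points
  beyond reported as outliers. The quartile convention matters because
  whisker placement depends on it, so it is fixed and documented.
- **Kruskal–Wallis** is computed on mid-ranks with the standard tie
  correction and a chi-square reference with k−1 df (delegated to
  scipy). All-identical data is defined as H = 0, p = 1 rather than an
  error. A permutation oracle in the tests confirms the chi-square
  approximation on small samples.
- **Dunn's post-hoc** (implemented here; no scipy equivalent) uses
  z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1)))·(1/n_i + 1/n_j))
  with two-sided normal p-values, Bonferroni-adjusted across all pairs
  by default (šidák/holm/none are options). Adjusted p is clipped to be
  ≥ raw p.
- **One-way ANOVA** optionally adds pairwise pooled-t comparisons of
  each group against a designated control, Holm-adjusted — the usual
  "stars against control" display; this post-hoc choice is an
  interpretation and is configurable.
- Degenerate inputs (zero within-group variance with unequal means)
  raise rather than returning infinities.

## Peak processing

Merging is single-linkage over the relation gap ≤ max_gap, where gap =
start_next − end_prev under half-open coordinates (overlapping or
touching peaks have gap ≤ 0); a gap of exactly max_gap merges
("within 200 bp or less"). The merged peak spans the union and takes
the maximum member score. Merging is idempotent, never increases peak
count, never decreases covered bases.

State annotation and co-occupancy use a ≥ 1 bp overlap threshold by
default (configurable): a peak "falls within" a state if it overlaps
any segment of that state. Classification counts each peak once —
promoter-only / enhancer-only / both / neither — so the four fractions
partition to 1. Co-occupancy is asymmetric by design: the fraction of
B peaks touching any A peak. All implementations are sorted sweeps held
to exact agreement with brute-force O(n²) oracles in the tests.

Peak calling itself is out of scope: peak sets enter as
narrowPeak/BED, and a `min_score` filter applies a caller's
significance cutoff (e.g. −log10 p ≥ 15) when wanted.

## Profiles and quintiles

Column 0 of an anchor profile is the anchor base itself; the window is
[−flank, +flank] inclusive. Minus-strand anchors sample mirrored
positions so "downstream" is always rightward; unstranded anchor sets
can be treated as plus. Anchors whose window crosses a chromosome end
are dropped (not zero-padded — padding biases column means) and the
drop count is reported. Quintiles cut metric-ranked anchors (ties
broken by stable genomic order) into five contiguous groups whose sizes
differ by at most one, larger groups first; label 1 is the lowest
metric. Scaled gene-body profiles sample flanks at native bin
resolution and rescale the body to 100 bins (default) by averaging the
native bins that map to each body bin; genes shorter than one native
bin replicate their single sample.

## qPCR calculus

Accessibility is 2^(Ct_undigested − Ct_digested) — the fraction of
template surviving nuclease digestion. Values above 1 are biologically
impossible (digestion cannot create template) and are flagged, never
clamped: clamping hides assay failure. Percent-of-control divides each
condition's replicate-mean accessibility by the control mean per locus;
aggregation is arithmetic on the ratio scale by default, with a
geometric-mean option since ΔCt noise is log-scale. Percent input
adjusts the input Ct by log2(1/input_fraction) before differencing; the
input fraction is a required input, not a constant. Amplification
efficiency is assumed exactly 2 per cycle throughout — a documented
limitation, with no efficiency-correction option.

## The synthetic-data generator

The generator's defaults are the study conditions the tests and the
acceptance script run under:

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 5 Mb chromosomes | toy genome, exact-string names |
| states | 40 segments × 2 kb per promoter state; 30 × 1.6 kb per enhancer state | a few % of the genome, like real annotations |
| fe_map | active 4.0, weak 1.5, inactive 1.0, enhancer-4 3.0, others 1.0 | true fold enrichment per state |
| depth | 30 expected input reads per 200 bp bin | 300 reads per promoter segment; quintile-ratio SE < 6% |
| genes | 40, TSS at active-promoter midpoints | quintile amplitudes (0.4, 0.7, 1.0, 1.3, 1.6) in a ±500 bp TSS window |
| peaks | 500 per set, 300 bp wide | placed in target states with q = 0.8; set B overlaps A with c = 0.6 |
| qPCR | 6 loci × 3 conditions × 3 replicates, Ct noise sd 0.05 | DHS loci drop to 50% under one knockdown; centromeric control flat |

Counts are Poisson (negative-binomial overdispersion behind a
`dispersion` knob): the downstream analyses are rank- and ratio-based,
so Poisson is the simplest model that exercises them. ChIP rates are
depth × state FE × TSS amplitude; input rates are flat. The TSS
amplitudes are *relative to the state mean* and median-centred at 1, so
the state-level fold enrichment keeps its configured value while the
top/bottom quintile signal ratio is 4. Peak placement and co-occupancy
are per-peak Bernoulli draws, so recovered fractions sit in the exact
binomial interval of q and c. Ct pairs are
ct_u ~ N(ct_base, sd), ct_d = ct_u + log2(1/accessibility) + N(0, sd):
zero noise round-trips exactly.

The realized truth (per-gene amplitudes, per-peak memberships, the
accessibility map) is serialized to `truth.json` next to every dataset,
so recovery tests compare against what was drawn, not against the
config logic that drew it.

What the simulation does *not* emulate: fragment-length and GC
structure, mappability, duplicate reads, adjacent chromatin states
(states are separated by unannotated gaps, so the "both" classification
arises only with real, continuous segmentations), overdispersion by
default, and qPCR efficiency ≠ 2. Passing recovery tests therefore
demonstrates correctness of the measurement pipeline under a clean
count model, not robustness to these real-data features.

## Problem sizes

The default simulation (10 Mb, 50k bins, 500 peaks/set, 40 genes) runs
in well under a second; the full test suite takes a few seconds. The
statistical calibration uses 1000 null simulations for the type-I rate
of the rank test (binomial band [0.03, 0.07] at α = 0.05) and 500
simulated assays for the power of the condition test against a 50%
accessibility drop at n = 3 with ~5% CV noise. The brute-force oracle
comparison covers 1000 random instances of up to 50 intervals.

## Known limitations

- `StateSegmentation.state_of` is a linear scan — fine for the segment
  counts here, not for genome-scale annotations.
- bedGraph round-trips rely on a single metadata comment line carrying
  bin size and totals; foreign bedGraphs without it are rejected rather
  than guessed at.
- The minus-strand gene-body convention samples from the stated TSS
  base toward the TES; genes whose TSS sits exactly on a bin boundary
  sample one bin beyond their half-open 3' limit.
- No BAM input; reads enter as BED intervals or pre-binned counts.
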