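# chromaggr

Chromatin-state enrichment, peak co-occupancy, TSS metaprofiles and
qPCR accessibility analysis for ChIP-seq studies of chromatin
remodelers — packaged as a library with a thin `chromaggr` command-line
layer and a synthetic-data generator that makes every stage testable
against known ground truth.

## The problem

Studies of chromatin remodeler recruitment (e.g. the CHD family at
human promoters) rest on a small set of recurring computations:

- **Fold enrichment over input.** For a region *r*, with raw ChIP count
  *c*<sub>ChIP</sub>, input count *c*<sub>in</sub>, library totals
  *T*<sub>ChIP</sub>, *T*<sub>in</sub> and pseudocount ψ:

  FE(r) = [(c_ChIP + ψ)/T_ChIP] / [(c_in + ψ)/T_in]

  grouped by chromatin-state label (active / weak / inactive promoter,
  enhancer states) and compared with the Kruskal–Wallis rank test plus
  Dunn's tie-corrected post-hoc.
- **Peak processing downstream of a caller.** Merging binding sites
  within one nucleosome length (gap ≤ 200 bp, single linkage), the
  fraction of peaks falling in chosen chromatin states, a
  promoter / enhancer / both / neither classification, and asymmetric
  co-occupancy between two factors ("x% of B sites overlap ≥ 1 A
  peak").
- **Strand-aware metaprofiles.** Average depth-normalized signal from
  −2500 to +2500 bp around TSSs, stratified into quintiles of ascending
  occupancy, plus length-scaled gene-body profiles with flanks.
- **qPCR calculus.** Nuclease accessibility 2^(Ct_undigested −
  Ct_digested), percent-of-control normalization, ChIP percent input
  100·2^(Ct_input − log2(1/f) − Ct_IP) for input fraction *f*, the
  H3.3/H3 occupancy ratio, and t-test / one-way-ANOVA condition
  comparisons.

The package implements each step behind a typed API
(`GenomicInterval`, `StateSegmentation`, `BinnedTrack`, `GeneAnchor`),
reads and writes the plain-text formats of the field (BED/narrowPeak,
bedGraph, TSV tables), and ships a simulator whose configuration *is*
the ground truth, so parameter-recovery tests close the loop.

## Worked example

```sh
python examples/01_state_enrichment.py
```

prints (seed 1):

```
median fold enrichment over input per chromatin state:
  active promoter         3.77
  enhancer state 4        2.81
  weak promoter           1.44
  ...
Kruskal-Wallis over the three promoter states (k = 3):
  H = 105.8, p = 1.07e-23
```

The simulation configures a 4×/1.5×/1× enrichment gradient across the
promoter states; the measured medians recover it (3.77 ≈ 4 within the
counting noise and the small deflation that total-read normalization
imposes), and the rank test separates the three states decisively.
The other examples cover quintile TSS profiles
(`02_tss_quintile_profiles.py`: top/bottom signal ratio 3.99 against a
configured 4), peak merging/annotation/co-occupancy
(`03_peak_processing.py`: 82.4% in-state placement vs. configured 80%,
58.6% co-occupancy vs. 60%), the qPCR calculus
(`04_qpcr_accessibility.py`: CHD1-knockdown accessibility ≈ 50% of
control), and the end-to-end pipeline (`05_full_pipeline.py`).

The same stages are exposed as subcommands:

```sh
chromaggr simulate --seed 1 --out data/
chromaggr enrich-states --chip data/chip.bedgraph --input data/input.bedgraph \
    --states data/states.bed --out enrichment.tsv
chromaggr peaks-merge --peaks data/peaks_a.bed --max-gap 200 --out merged.bed
chromaggr run --seed 1 --out runs/demo
```

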