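"""Ground-truth simulator for every pipeline stage.

Generates a toy genome carrying a chromatin-state segmentation,
state-structured ChIP/input count tracks, peak sets with configured
state placement and co-occupancy, genes with quintile-graded TSS
amplitudes, and qPCR Ct tables encoding known accessibilities — with
the realized truth serialized next to the data so recovery tests never
re-derive it from generator logic.

Model choices: bin counts are Poisson (the downstream analyses are
rank- and ratio-based, so the simplest count model that exercises them;
a dispersion knob adds negative-binomial overdispersion when wanted).
Chromatin states deliberately cover only a few percent of the toy
genome, mirroring real annotations; this keeps the total-read
normalization of fold enrichment nearly unbiased (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from chromaggr.intervals import (
    GeneAnchor,
    GenomicInterval,
    StateSegmentation,
    ValidationError,
)
from chromaggr.signal import BinnedTrack, counts_track

PROMOTER_STATES = ("active promoter", "weak promoter", "inactive promoter")
ENHANCER_STATES = tuple(f"enhancer state {i}" for i in range(4, 8))

DEFAULT_LAYOUT = {
    "active promoter": (40, 2000),
    "weak promoter": (40, 2000),
    "inactive promoter": (40, 2000),
    "enhancer state 4": (30, 1600),
    "enhancer state 5": (30, 1600),
    "enhancer state 6": (30, 1600),
    "enhancer state 7": (30, 1600),
}

DEFAULT_FE = {
    "active promoter": 4.0,
    "weak promoter": 1.5,
    "inactive promoter": 1.0,
    "enhancer state 4": 3.0,
    "enhancer state 5": 1.0,
    "enhancer state 6": 1.0,
    "enhancer state 7": 1.0,
}

# accessibility truth: DNase-hypersensitive loci drop to 50% of control
# under CHD1 knockdown; an inaccessible centromeric control stays flat
DEFAULT_QPCR_ACCESSIBILITY = {
    "TSS_DHS_1": {"control siRNA": 0.50, "CHD1 siRNA": 0.25, "CHD2 siRNA": 0.50},
    "TSS_DHS_2": {"control siRNA": 0.40, "CHD1 siRNA": 0.20, "CHD2 siRNA": 0.40},
    "intragenic_DHS": {"control siRNA": 0.30, "CHD1 siRNA": 0.15, "CHD2 siRNA": 0.30},
    "intergenic_DHS": {"control siRNA": 0.35, "CHD1 siRNA": 0.175, "CHD2 siRNA": 0.35},
    "tRNA_DHS": {"control siRNA": 0.45, "CHD1 siRNA": 0.225, "CHD2 siRNA": 0.45},
    "centromeric_repeat": {"control siRNA": 0.02, "CHD1 siRNA": 0.02, "CHD2 siRNA": 0.02},
}

# ChIP percent-input truth (total H3 at a TSS): occupancy rises under
# CHD2 and double knockdown
DEFAULT_QPCR_PERCENT_INPUT = {
    "TSS_DHS_1": {
        "control siRNA": 2.0,
        "CHD1 siRNA": 2.4,
        "CHD2 siRNA": 3.8,
        "CHD1+2 siRNA": 4.3,
    },
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions.

    ``depth`` is the expected input reads per bin — 30 reads per 200 bp
    bin gives 300 expected input reads per 2 kb promoter segment, enough
    for the column-0 quintile signal ratio to have a relative SD under
    6% (see docs/methods.md).
    ``quintile_amplitudes`` multiply the ChIP rate in a window around
    each gene's TSS, graded by the gene's occupancy quintile.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    bin_size: int = 200
    state_layout: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LAYOUT)
    )
    fe_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FE))
    depth: float = 30.0
    dispersion: float = 0.0  # 0 = Poisson; >0 adds NB overdispersion
    n_genes: int = 40
    gene_length: int = 5000
    # TSS amplitudes are relative to the state mean and median-centered at
    # 1 so the state-level fold enrichment keeps its configured value;
    # the top/bottom quintile signal ratio is 1.6/0.4 = 4.
    quintile_amplitudes: tuple[float, ...] = (0.4, 0.7, 1.0, 1.3, 1.6)
    tss_window: int = 500
    cgi_probability: float = 0.7
    n_peaks: int = 500
    peak_width: int = 300
    peak_state_fraction: float = 0.8  # q: fraction placed in target states
    peak_target_states: tuple[str, ...] = ("active promoter", "enhancer state 4")
    cooccupancy: float = 0.6  # c: fraction of set B overlapping set A
    qpcr_accessibility: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_QPCR_ACCESSIBILITY.items()}
    )
    qpcr_percent_input: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_QPCR_PERCENT_INPUT.items()}
    )
    qpcr_replicates: int = 3
    ct_base: float = 22.0
    ct_sd: float = 0.05
    input_fraction: float = 0.01

    def __post_init__(self) -> None:
        if any(fe <= 0 for fe in self.fe_map.values()):
            raise ValidationError("fold enrichments must be > 0")
        if not 0 <= self.peak_state_fraction <= 1:
            raise ValidationError("peak_state_fraction must be in [0, 1]")
        if not 0 <= self.cooccupancy <= 1:
            raise ValidationError("cooccupancy must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """The realized truth recovery tests compare against."""

    fe_map: dict[str, float]
    gene_amplitudes: list[float]
    gene_quintiles: list[int]
    peak_in_state: list[bool]
    peak_b_overlaps_a: list[bool]
    accessibility: dict[str, dict[str, float]]
    percent_input: dict[str, dict[str, float]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[StateSegmentation, list[GeneAnchor], GroundTruth]:
    """Place non-overlapping labeled segments and genes on the toy genome.

    Segments of every configured state are shuffled together and laid
    down left to right with random gaps, split across chromosomes. Genes
    put their TSS at the midpoint of an active-promoter segment, are
    assigned a quintile amplitude (graded 1..5 by construction) and a
    stratification metric equal to that amplitude plus small jitter.
    """
    rng = rng if rng is not None else config.rng()
    pieces: list[tuple[str, int]] = []
    for state, (count, length) in config.state_layout.items():
        pieces += [(state, length)] * count
    order = rng.permutation(len(pieces))
    pieces = [pieces[i] for i in order]

    chroms = list(config.chrom_sizes)
    total_seg = sum(length for _, length in pieces)
    total_size = sum(config.chrom_sizes.values())
    if total_seg >= 0.5 * total_size:
        raise ValidationError("state layout exceeds half the genome; enlarge chromosomes")

    segments: list[GenomicInterval] = []
    per_chrom = np.array_split(np.arange(len(pieces)), len(chroms))
    for chrom, idxs in zip(chroms, per_chrom):
        size = config.chrom_sizes[chrom]
        seg_total = sum(pieces[i][1] for i in idxs)
        slack = size - seg_total - (len(idxs) + 1) * config.bin_size
        if slack < 0:
            raise ValidationError(f"state layout exceeds {chrom} size")
        # exponential gap draws rescaled to exactly tile the chromosome,
        # with one trailing gap so segments never touch the end
        raw = rng.exponential(1.0, size=len(idxs) + 1)
        gaps = (raw / raw.sum() * slack).astype(int) + config.bin_size
        cursor = 0
        for i, gap in zip(idxs, gaps[:-1]):
            state, length = pieces[i]
            start = cursor + int(gap)
            segments.append(GenomicInterval(chrom, start, start + length, name=state))
            cursor = start + length
    segmentation = StateSegmentation(segments, state_catalog=set(config.state_layout))

    active = [s for s in segmentation.segments if s.name == "active promoter"]
    if config.n_genes > len(active):
        raise ValidationError("more genes requested than active promoter segments")
    chosen = rng.choice(len(active), size=config.n_genes, replace=False)
    # grade amplitudes evenly across genes: quintile q gets amplitude[q-1]
    quintile_of_gene = np.repeat(
        np.arange(1, 6), math.ceil(config.n_genes / 5)
    )[: config.n_genes]
    rng.shuffle(quintile_of_gene)
    genes: list[GeneAnchor] = []
    amplitudes: list[float] = []
    for g, seg_idx in enumerate(chosen):
        seg = active[int(seg_idx)]
        q = int(quintile_of_gene[g])
        amp = float(config.quintile_amplitudes[q - 1])
        tss = seg.midpoint
        strand = "+" if rng.random() < 0.5 else "-"
        tes = tss + config.gene_length if strand == "+" else tss - config.gene_length
        size = config.chrom_sizes[seg.chrom]
        if not (0 <= min(tss, tes) and max(tss, tes) < size):
            strand = "+" if strand == "-" else "-"
            tes = tss + config.gene_length if strand == "+" else tss - config.gene_length
        genes.append(
            GeneAnchor(
                chrom=seg.chrom,
                tss=tss,
                tes=tes,
                strand=strand,
                cgi_flag=bool(rng.random() < config.cgi_probability),
                metric=amp * (1 + 0.01 * rng.standard_normal()),
                name=f"gene{g}",
            )
        )
        amplitudes.append(amp)
    truth = GroundTruth(
        fe_map=dict(config.fe_map),
        gene_amplitudes=amplitudes,
        gene_quintiles=[int(q) for q in quintile_of_gene],
        peak_in_state=[],
        peak_b_overlaps_a=[],
        accessibility={k: dict(v) for k, v in config.qpcr_accessibility.items()},
        percent_input={k: dict(v) for k, v in config.qpcr_percent_input.items()},
    )
    return segmentation, genes, truth


def _rate_map(
    config: SimulationConfig,
    segmentation: StateSegmentation,
    genes: list[GeneAnchor],
    amplitudes: list[float],
) -> dict[str, np.ndarray]:
    """Expected ChIP reads per bin: depth x state FE x TSS amplitude."""
    b = config.bin_size
    rates = {
        chrom: np.full(math.ceil(size / b), config.depth)
        for chrom, size in config.chrom_sizes.items()
    }
    for seg in segmentation.segments:
        fe = config.fe_map[seg.name]
        lo, hi = seg.start // b, math.ceil(seg.end / b)
        rates[seg.chrom][lo:hi] = config.depth * fe
    for gene, amp in zip(genes, amplitudes):
        lo = max(0, (gene.tss - config.tss_window) // b)
        hi = min(len(rates[gene.chrom]), math.ceil((gene.tss + config.tss_window) / b))
        rates[gene.chrom][lo:hi] *= amp
    return rates


def _draw_counts(
    rng: np.random.Generator, rate: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(rate).astype(float)
    # NB via gamma-Poisson mixture; dispersion = 1/shape
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, rate / shape)).astype(float)


def simulate_tracks(
    genome: tuple[StateSegmentation, list[GeneAnchor], GroundTruth],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[BinnedTrack, BinnedTrack]:
    """Draw ChIP and input count tracks over the simulated genome.

    Input bins are Poisson(depth); ChIP bins are Poisson(depth x FE of
    the bin's state x the TSS amplitude where a gene window applies).
    """
    rng = rng if rng is not None else config.rng()
    segmentation, genes, truth = genome
    rates = _rate_map(config, segmentation, genes, truth.gene_amplitudes)
    chip = {c: _draw_counts(rng, r, config.dispersion) for c, r in rates.items()}
    inp = {
        c: _draw_counts(rng, np.full_like(r, config.depth), config.dispersion)
        for c, r in rates.items()
    }
    return counts_track(chip, config.bin_size), counts_track(inp, config.bin_size)


def _gaps(
    segmentation: StateSegmentation, chrom_sizes: Mapping[str, int], min_len: int
) -> list[GenomicInterval]:
    out = []
    for chrom, size in chrom_sizes.items():
        cursor = 0
        for seg in segmentation.by_chrom().get(chrom, []):
            if seg.start - cursor >= min_len:
                out.append(GenomicInterval(chrom, cursor, seg.start))
            cursor = seg.end
        if size - cursor >= min_len:
            out.append(GenomicInterval(chrom, cursor, size))
    return out


def _place_in(rng: np.random.Generator, region: GenomicInterval, width: int) -> GenomicInterval:
    start = int(rng.integers(region.start, region.end - width + 1))
    return GenomicInterval(region.chrom, start, start + width)


def simulate_peaks(
    genome: tuple[StateSegmentation, list[GeneAnchor], GroundTruth],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Two peak sets with configured state placement and co-occupancy.

    Set A: each peak lands inside a target-state segment with
    probability q, otherwise wholly inside an unannotated gap. Set B:
    each peak overlaps some set A peak with probability c, otherwise
    avoids all of set A. Realized memberships are recorded in the truth.
    """
    rng = rng if rng is not None else config.rng()
    segmentation, _genes, truth = genome
    width = config.peak_width
    targets = [
        s for s in segmentation.segments
        if s.name in config.peak_target_states and len(s) >= width
    ]
    gaps = _gaps(segmentation, config.chrom_sizes, min_len=3 * width)
    if not targets or not gaps:
        raise ValidationError("insufficient space to place peaks")

    set_a: list[GenomicInterval] = []
    in_state: list[bool] = []
    for i in range(config.n_peaks):
        hit = bool(rng.random() < config.peak_state_fraction)
        region = targets[int(rng.integers(len(targets)))] if hit else gaps[
            int(rng.integers(len(gaps)))
        ]
        p = _place_in(rng, region, width)
        set_a.append(GenomicInterval(p.chrom, p.start, p.end, name=f"peakA_{i}",
                                     score=float(15 + rng.random() * 20)))
        in_state.append(hit)

    sorted_a = sorted(set_a, key=lambda p: (p.chrom, p.start))
    set_b: list[GenomicInterval] = []
    b_overlap: list[bool] = []
    for i in range(config.n_peaks):
        hit = bool(rng.random() < config.cooccupancy)
        if hit:
            a = set_a[int(rng.integers(len(set_a)))]
            lo = max(0, a.start - width + 1)
            start = int(rng.integers(lo, a.end))
            p = GenomicInterval(a.chrom, start, start + width)
        else:
            for _ in range(1000):
                gap = gaps[int(rng.integers(len(gaps)))]
                p = _place_in(rng, gap, width)
                if not _hits_any(p, sorted_a):
                    break
            else:
                raise ValidationError("could not place a non-overlapping set B peak")
        set_b.append(GenomicInterval(p.chrom, p.start, p.end, name=f"peakB_{i}",
                                     score=float(15 + rng.random() * 20)))
        b_overlap.append(hit)

    truth.peak_in_state = in_state
    truth.peak_b_overlaps_a = b_overlap
    return sorted_a, sorted(set_b, key=lambda p: (p.chrom, p.start))


def _hits_any(p: GenomicInterval, sorted_peaks: list[GenomicInterval]) -> bool:
    import bisect

    keys = [(q.chrom, q.start) for q in sorted_peaks]
    i = bisect.bisect_right(keys, (p.chrom, p.end))
    for q in sorted_peaks[max(0, i - 50): i]:
        if q.overlaps(p):
            return True
    return False


def simulate_qpcr(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Accessibility-assay Ct table encoding the configured truth.

    ct_undigested ~ Normal(ct_base, sd); ct_digested adds
    log2(1/accessibility) plus independent Normal(0, sd), so with sd=0
    the computed accessibility round-trips exactly.
    """
    rng = rng if rng is not None else config.rng()
    rows = []
    for locus, conds in config.qpcr_accessibility.items():
        for cond, acc in conds.items():
            if acc <= 0:
                raise ValidationError("true accessibility must be > 0")
            for rep in range(1, config.qpcr_replicates + 1):
                ct_u = config.ct_base + config.ct_sd * rng.standard_normal()
                ct_d = ct_u + math.log2(1.0 / acc) + config.ct_sd * rng.standard_normal()
                rows.append(
                    {
                        "locus": locus,
                        "condition": cond,
                        "replicate": rep,
                        "ct_undigested": ct_u,
                        "ct_digested": ct_d,
                    }
                )
    return pd.DataFrame(rows)


def simulate_qpcr_chip(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """ChIP-qPCR Ct table whose percent-input recovers the configured truth."""
    rng = rng if rng is not None else config.rng()
    f = config.input_fraction
    rows = []
    for locus, conds in config.qpcr_percent_input.items():
        for cond, pct in conds.items():
            for rep in range(1, config.qpcr_replicates + 1):
                ct_input = 30.0 + config.ct_sd * rng.standard_normal()
                adjusted = ct_input - math.log2(1.0 / f)
                ct_ip = adjusted - math.log2(pct / 100.0) + config.ct_sd * rng.standard_normal()
                rows.append(
                    {
                        "locus": locus,
                        "condition": cond,
                        "replicate": rep,
                        "ct_ip": ct_ip,
                        "ct_input": ct_input,
                        "input_fraction": f,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces, plus its truth."""

    segmentation: StateSegmentation
    genes: list[GeneAnchor]
    chip: BinnedTrack
    input_track: BinnedTrack
    peaks_a: list[GenomicInterval]
    peaks_b: list[GenomicInterval]
    qpcr: pd.DataFrame
    qpcr_chip: pd.DataFrame
    truth: GroundTruth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage through one seeded stream."""
    rng = config.rng()
    genome = simulate_genome(config, rng)
    chip, inp = simulate_tracks(genome, config, rng)
    peaks_a, peaks_b = simulate_peaks(genome, config, rng)
    qpcr = simulate_qpcr(config, rng)
    qpcr_chip = simulate_qpcr_chip(config, rng)
    segmentation, genes, truth = genome
    return SimulatedDataset(
        segmentation=segmentation,
        genes=genes,
        chip=chip,
        input_track=inp,
        peaks_a=peaks_a,
        peaks_b=peaks_b,
        qpcr=qpcr,
        qpcr_chip=qpcr_chip,
        truth=truth,
    )
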