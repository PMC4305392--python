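"""Binned coverage tracks, depth normalization and fold enrichment over input.

The fold-enrichment quantity computed here is the measurement behind all
state-wise ChIP comparisons: depth-normalized ChIP counts over a region
divided by depth-normalized input (non-immunoprecipitated chromatin)
counts, with a pseudocount guaranteeing positivity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from chromaggr.intervals import GenomicInterval, ValidationError


@dataclass
class BinnedTrack:
    """Fixed-width per-chromosome signal vectors.

    ``data`` maps chromosome name to a vector of per-bin values (raw read
    counts, or reads-per-million after :func:`normalize_to_depth`).
    ``total_reads`` is the depth used for normalization. Bin ``i`` covers
    ``[i*bin_size, (i+1)*bin_size)``.
    """

    bin_size: int
    data: dict[str, np.ndarray] = field(default_factory=dict)
    total_reads: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be > 0")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}
        for chrom, vec in self.data.items():
            if np.any(vec < 0):
                raise ValidationError(f"negative bin values on {chrom}")
        if self.normalized and self.total_reads <= 0:
            raise ValidationError("normalized track requires total_reads > 0")

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def chrom_size(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_size

    def value_at(self, chrom: str, pos: int) -> float:
        """Value of the bin containing genomic position ``pos``."""
        if chrom not in self.data:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        vec = self.data[chrom]
        idx = pos // self.bin_size
        if pos < 0 or idx >= len(vec):
            raise ValidationError(f"position {chrom}:{pos} outside track")
        return float(vec[idx])

    def region_bin_slice(self, region: GenomicInterval) -> np.ndarray:
        """Values of all bins whose midpoint lies inside ``region``.

        Symmetric with the read-midpoint binning rule: a bin belongs to
        the region iff its midpoint does, so boundary bins are never
        double-counted between adjacent regions.
        """
        if region.chrom not in self.data:
            raise ValidationError(f"region on unknown chromosome {region.chrom!r}")
        vec = self.data[region.chrom]
        # bin midpoint of bin i is i*b + b/2; require start <= mid < end
        first = math.ceil((region.start - self.bin_size / 2) / self.bin_size)
        last = math.ceil((region.end - self.bin_size / 2) / self.bin_size)  # exclusive
        first = max(first, 0)
        last = min(last, len(vec))
        return vec[first:last]

    def region_count(self, region: GenomicInterval) -> float:
        return float(self.region_bin_slice(region).sum())


@dataclass(frozen=True)
class EnrichmentRecord:
    """Fold enrichment over input for one region (dimensionless ratio)."""

    region: GenomicInterval
    fold_enrichment: float
    state_label: str | None = None

    def __post_init__(self) -> None:
        if not self.fold_enrichment > 0:
            raise ValidationError("fold_enrichment must be > 0")


def bin_coverage(
    reads: Iterable[GenomicInterval],
    bin_size: int,
    chrom_sizes: Mapping[str, int],
) -> BinnedTrack:
    """Count reads into fixed-width bins by read midpoint.

    Each read contributes exactly 1 to the bin containing its midpoint
    (fragment-length agnostic). ``total_reads`` equals the number of
    reads binned; the sum over all bins is conserved.
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be > 0")
    data = {
        chrom: np.zeros(math.ceil(size / bin_size), dtype=float)
        for chrom, size in chrom_sizes.items()
    }
    n = 0
    for read in reads:
        if read.chrom not in data:
            raise ValidationError(f"read on undeclared chromosome: {read}")
        if read.end > chrom_sizes[read.chrom] or read.start < 0:
            raise ValidationError(f"read outside declared chromosome size: {read}")
        data[read.chrom][read.midpoint // bin_size] += 1
        n += 1
    return BinnedTrack(bin_size=bin_size, data=data, total_reads=float(n))


def counts_track(
    counts: Mapping[str, np.ndarray], bin_size: int
) -> BinnedTrack:
    """Wrap pre-binned raw counts as a track; total is the count sum."""
    data = {c: np.asarray(v, dtype=float) for c, v in counts.items()}
    total = float(sum(v.sum() for v in data.values()))
    return BinnedTrack(bin_size=bin_size, data=data, total_reads=total)


def normalize_to_depth(track: BinnedTrack) -> BinnedTrack:
    """Scale bin values to reads-per-million of the track total."""
    if track.total_reads <= 0:
        raise ValidationError("cannot depth-normalize a track with total_reads == 0")
    scale = 1e6 / track.total_reads
    return BinnedTrack(
        bin_size=track.bin_size,
        data={c: v * scale for c, v in track.data.items()},
        total_reads=track.total_reads,
        normalized=True,
    )


def region_fold_enrichment(
    chip: BinnedTrack,
    input_track: BinnedTrack,
    region: GenomicInterval,
    pseudocount: float = 1.0,
    state_label: str | None = None,
) -> EnrichmentRecord:
    """Fold enrichment over input for one region.

    FE = ((c_chip + psi)/T_chip) / ((c_in + psi)/T_in) where c is the raw
    count summed over bins whose midpoint falls in the region and T the
    track total. Requires raw (unnormalized) tracks so the counts and
    totals retain read units.
    """
    if chip.bin_size != input_track.bin_size:
        raise ValidationError("chip and input tracks must share bin_size")
    if set(chip.data) != set(input_track.data):
        raise ValidationError("chip and input tracks must share the chromosome set")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    c_chip = chip.region_count(region)
    c_in = input_track.region_count(region)
    num = (c_chip + pseudocount) / chip.total_reads
    den = (c_in + pseudocount) / input_track.total_reads
    if den == 0:
        raise ValidationError(
            "zero input count with zero pseudocount; use pseudocount > 0"
        )
    return EnrichmentRecord(region=region, fold_enrichment=num / den, state_label=state_label)


def profile_signal(
    track: BinnedTrack, region: GenomicInterval, bin_size: int | None = None
) -> np.ndarray:
    """Per-bin signal across a region, sampled at output-bin midpoints.

    Output length is ceil(region length / bin_size); a region shorter
    than one bin yields a single-bin vector. Defaults to the track's own
    bin size.
    """
    b = bin_size or track.bin_size
    n = max(1, math.ceil(len(region) / b))
    out = np.empty(n)
    size = track.chrom_size(region.chrom)
    for j in range(n):
        mid = region.start + j * b + b // 2
        out[j] = track.value_at(region.chrom, min(mid, size - 1))
    return out


# ---------------------------------------------------------------------------
# bedGraph I/O: one line per non-zero bin; track metadata in a JSON comment.

def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    meta = {
        "bin_size": track.bin_size,
        "total_reads": track.total_reads,
        "normalized": track.normalized,
        "chrom_sizes": {c: track.chrom_size(c) for c in track.chroms},
    }
    with open(path, "w") as fh:
        fh.write("#chromaggr " + json.dumps(meta) + "\n")
        for chrom in track.chroms:
            vec = track.data[chrom]
            for i in np.nonzero(vec)[0]:
                s = i * track.bin_size
                fh.write(f"{chrom}\t{s}\t{s + track.bin_size}\t{vec[i]:g}\n")


def read_bedgraph(path: str | Path) -> BinnedTrack:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#chromaggr "):
            raise ValidationError("bedGraph missing chromaggr metadata header")
        meta = json.loads(header[len("#chromaggr "):])
        bin_size = int(meta["bin_size"])
        data = {
            c: np.zeros(math.ceil(size / bin_size))
            for c, size in meta["chrom_sizes"].items()
        }
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            chrom, s, _e, v = line.rstrip("\n").split("\t")
            data[chrom][int(s) // bin_size] = float(v)
    return BinnedTrack(
        bin_size=bin_size,
        data=data,
        total_reads=float(meta["total_reads"]),
        normalized=bool(meta["normalized"]),
    )
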