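"""Anchor-centered metaprofiles and occupancy-quintile stratification.

Builds strand-oriented average signal profiles around TSSs (or any
anchor set, e.g. transcription-factor sites), stratifies anchors into
quintiles of ascending occupancy, and computes scaled gene-body
profiles with fixed-resolution flanks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from chromaggr.intervals import GeneAnchor, ValidationError
from chromaggr.signal import BinnedTrack


@dataclass
class ProfileMatrix:
    """Per-anchor signal rows over a common relative-position axis.

    ``columns`` holds the offsets (in bp) of each column from the anchor;
    column 0 is the anchor base itself. Minus-strand anchors are
    orientation-flipped before entry, so "downstream" is always to the
    right. ``dropped`` counts anchors discarded because their window ran
    off a chromosome end (dropping, not zero-padding, keeps column means
    unbiased).
    """

    values: np.ndarray
    columns: np.ndarray
    anchor_ids: list[str] = field(default_factory=list)
    dropped: int = 0

    def mean_profile(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.anchor_ids, columns=self.columns)


def assign_quintiles(anchors: Sequence[GeneAnchor]) -> dict[int, int]:
    """Quintile label (1..5, ascending metric) per anchor index.

    Anchors are ranked by metric ascending with ties broken by stable
    genomic order, then ranks are cut into 5 contiguous groups whose
    sizes differ by at most one (larger groups first).
    """
    n = len(anchors)
    if n < 5:
        raise ValidationError(f"need >= 5 anchors for quintiles, got {n}")
    order = sorted(
        range(n), key=lambda i: (anchors[i].metric, anchors[i].chrom, anchors[i].tss, i)
    )
    assignment: dict[int, int] = {}
    for q, chunk in enumerate(np.array_split(np.asarray(order), 5), start=1):
        for idx in chunk:
            assignment[int(idx)] = q
    return assignment


def _anchor_positions(anchor: GeneAnchor, offsets: np.ndarray) -> np.ndarray:
    """Genomic positions sampled for one anchor; minus strand flips."""
    sign = 1 if anchor.strand == "+" else -1
    return anchor.tss + sign * offsets


def anchor_profile(
    track: BinnedTrack,
    anchors: Sequence[GeneAnchor],
    flank: int = 2500,
    bin_size: int = 50,
) -> ProfileMatrix:
    """Strand-oriented signal matrix around anchors, e.g. TSS +/- 2.5 kb.

    Column j holds the track value at anchor + j*bin_size on the plus
    strand and anchor - j*bin_size on the minus strand, for j from
    -flank//bin_size to +flank//bin_size inclusive. Anchors whose window
    exceeds a chromosome end are dropped and counted.
    """
    if not track.normalized:
        raise ValidationError("anchor profiles require a depth-normalized track")
    k = flank // bin_size
    offsets = np.arange(-k, k + 1) * bin_size
    rows, ids = [], []
    dropped = 0
    for anchor in anchors:
        if anchor.chrom not in track.data:
            dropped += 1
            continue
        pos = _anchor_positions(anchor, offsets)
        size = track.chrom_size(anchor.chrom)
        if pos.min() < 0 or pos.max() >= size:
            dropped += 1
            continue
        vec = track.data[anchor.chrom]
        rows.append(vec[pos // track.bin_size])
        ids.append(anchor.name if anchor.name != "." else f"{anchor.chrom}:{anchor.tss}")
    if not rows:
        raise ValidationError("no usable anchors (all dropped)")
    return ProfileMatrix(
        values=np.asarray(rows), columns=offsets, anchor_ids=ids, dropped=dropped
    )


def stratified_profiles(
    track: BinnedTrack,
    anchors: Sequence[GeneAnchor],
    assignment: dict[int, int] | None = None,
    flank: int = 2500,
    bin_size: int = 50,
) -> dict[int, ProfileMatrix]:
    """One profile matrix per quintile group (empty groups omitted)."""
    if assignment is None:
        assignment = assign_quintiles(anchors)
    out: dict[int, ProfileMatrix] = {}
    for q in sorted(set(assignment.values())):
        members = [anchors[i] for i, lab in assignment.items() if lab == q]
        if not members:
            continue
        try:
            out[q] = anchor_profile(track, members, flank=flank, bin_size=bin_size)
        except ValidationError:
            continue  # every member dropped at a chromosome edge
    return out


def scaled_gene_profile(
    track: BinnedTrack,
    genes: Sequence[GeneAnchor],
    flank: int = 2500,
    n_body_bins: int = 100,
    bin_size: int = 50,
) -> np.ndarray:
    """Composite mean profile: upstream flank, length-scaled gene body,
    downstream flank.

    Flanks are sampled at native bin resolution. The body is sampled at
    native resolution between TSS and TES, then linearly rescaled to
    ``n_body_bins`` by averaging the native bins mapping to each body
    bin. Minus-strand genes are flipped so transcription always runs
    left to right. Genes shorter than one native bin contribute their
    single body sample replicated.
    """
    if not track.normalized:
        raise ValidationError("gene profiles require a depth-normalized track")
    k = flank // bin_size
    rows = []
    for gene in genes:
        if gene.chrom not in track.data:
            continue
        sign = 1 if gene.strand == "+" else -1
        length = abs(gene.tes - gene.tss)
        n_native = max(1, math.ceil(length / bin_size))
        up = gene.tss - sign * np.arange(k, 0, -1) * bin_size
        body = gene.tss + sign * np.arange(n_native) * bin_size
        # clamp the last body sample inside the gene on short final bins
        body = np.clip(body * sign, None, (gene.tss + sign * (length - 1)) * sign) * sign
        down = gene.tes + sign * np.arange(1, k + 1) * bin_size
        pos = np.concatenate([up, body, down])
        size = track.chrom_size(gene.chrom)
        if pos.min() < 0 or pos.max() >= size:
            continue
        vec = track.data[gene.chrom]
        native = vec[pos // track.bin_size]
        body_native = native[k: k + n_native]
        # body bin j averages native bins [j*n/m, (j+1)*n/m); at least one
        edges = (np.arange(n_body_bins + 1) * n_native) // n_body_bins
        scaled = np.array(
            [
                body_native[lo: max(hi, lo + 1)].mean()
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        rows.append(np.concatenate([native[:k], scaled, native[k + n_native:]]))
    if not rows:
        raise ValidationError("no usable genes")
    return np.asarray(rows).mean(axis=0)
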