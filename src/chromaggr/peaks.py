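"""Post-peak-calling interval processing.

Peak calling itself is consumed, not re-implemented: peaks enter as
narrowPeak/BED (typically called at a stringent p cut-off), and this
module handles what comes after — gap-based merging (binding sites
within one nucleosome length, 200 bp, of each other collapse to one
site), chromatin-state annotation with promoter/enhancer classification,
and asymmetric co-occupancy between two factors.

All implementations are sorted sweep-lines over half-open intervals;
tests hold them to exact agreement with brute-force O(n^2) oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from chromaggr.intervals import (
    GenomicInterval,
    StateSegmentation,
    ValidationError,
    sort_intervals,
)


@dataclass
class PeakStateAnnotation:
    """Per-peak overlapped state labels plus classification fractions.

    ``summary`` maps {promoter-only, enhancer-only, both, neither} to
    fractions that sum to 1 over the peak set (each peak counted once).
    """

    peak_labels: list[set[str]]
    peak_classes: list[str]
    summary: dict[str, float]


def filter_by_score(
    peaks: Sequence[GenomicInterval], min_score: float
) -> list[GenomicInterval]:
    """Keep peaks with score >= min_score (e.g. -log10 p >= 15 for a
    p <= 1e-15 cut-off on caller output)."""
    return [p for p in peaks if p.score >= min_score]


def merge_within(
    peaks: Sequence[GenomicInterval], max_gap: int = 200
) -> list[GenomicInterval]:
    """Single-linkage merge of peaks whose inter-peak gap is <= max_gap.

    The gap between consecutive sorted peaks is ``start_next - end_prev``
    (half-open coordinates, so touching or overlapping peaks have gap
    <= 0). Merging chains transitively; the merged peak spans the union
    and takes the maximum member score. gap == max_gap merges ("within
    200 bp or less"). Idempotent.
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    if not peaks:
        return []
    merged: list[GenomicInterval] = []
    for p in sort_intervals(peaks):
        last = merged[-1] if merged else None
        if last is not None and p.chrom == last.chrom and p.start - last.end <= max_gap:
            merged[-1] = GenomicInterval(
                chrom=last.chrom,
                start=last.start,
                end=max(last.end, p.end),
                name=last.name,
                score=max(last.score, p.score),
                strand=last.strand,
            )
        else:
            merged.append(p)
    return merged


def _overlap_flags(
    peaks: Sequence[GenomicInterval],
    targets: Sequence[GenomicInterval],
    min_overlap: int,
) -> list[bool]:
    """For each peak, whether it overlaps >= min_overlap bp of any target.

    Sorted two-pointer sweep per chromosome; O((n+m) log(n+m)).
    """
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].chrom, peaks[i].start))
    tgt = sort_intervals(targets)
    flags = [False] * len(peaks)
    ti = 0
    active: list[GenomicInterval] = []
    for idx in order:
        p = peaks[idx]
        while ti < len(tgt) and (tgt[ti].chrom, tgt[ti].start) <= (p.chrom, p.end):
            active.append(tgt[ti])
            ti += 1
        # prune targets that can no longer overlap anything at/after p
        active = [t for t in active if t.chrom == p.chrom and t.end > p.start]
        flags[idx] = any(
            min(p.end, t.end) - max(p.start, t.start) >= min_overlap for t in active
        )
    return flags


def intersect_fraction(
    peaks: Sequence[GenomicInterval],
    segmentation: StateSegmentation,
    state_subset: Sequence[str],
    min_overlap: int = 1,
) -> float:
    """Fraction of peaks overlapping at least one segment whose label is
    in ``state_subset`` (>= min_overlap bp; default 1 bp, permissive)."""
    if not peaks:
        raise ValidationError("intersect fraction of an empty peak set is undefined")
    subset = set(state_subset)
    targets = [s for s in segmentation.segments if s.name in subset]
    flags = _overlap_flags(peaks, targets, min_overlap)
    return sum(flags) / len(peaks)


def classify_peak_states(
    peaks: Sequence[GenomicInterval],
    segmentation: StateSegmentation,
    promoter_labels: Sequence[str],
    enhancer_labels: Sequence[str],
    min_overlap: int = 1,
) -> PeakStateAnnotation:
    """Assign each peak its overlapped state labels and classify it.

    Chromatin states tile the genome continuously, so a peak may span
    several; classification is promoter-only / enhancer-only / both /
    neither by which label families it touches. Fractions sum to 1.
    """
    prom, enh = set(promoter_labels), set(enhancer_labels)
    if prom & enh:
        raise ValidationError(f"label sets overlap: {sorted(prom & enh)}")
    if not peaks:
        raise ValidationError("cannot classify an empty peak set")
    labels_per_peak: list[set[str]] = []
    for p in peaks:
        hit = {
            s.name
            for s in segmentation.segments
            if s.chrom == p.chrom
            and min(p.end, s.end) - max(p.start, s.start) >= min_overlap
        }
        labels_per_peak.append(hit)
    classes = []
    for hit in labels_per_peak:
        has_p, has_e = bool(hit & prom), bool(hit & enh)
        classes.append(
            "both" if has_p and has_e
            else "promoter-only" if has_p
            else "enhancer-only" if has_e
            else "neither"
        )
    n = len(peaks)
    summary = {
        c: classes.count(c) / n
        for c in ("promoter-only", "enhancer-only", "both", "neither")
    }
    return PeakStateAnnotation(labels_per_peak, classes, summary)


def cooccupancy_fraction(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> float:
    """Fraction of set_b peaks overlapping >= min_overlap bp of any set_a
    peak. Asymmetric: "x% of B sites overlap at least one A peak"."""
    if not set_b:
        raise ValidationError("co-occupancy of an empty set_b is undefined")
    flags = _overlap_flags(set_b, set_a, min_overlap)
    return sum(flags) / len(set_b)
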