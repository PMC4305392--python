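"""Brute-force O(n^2) reference implementations for interval operations.

Deliberately naive (transitive closure by union-find, all-pairs overlap
scans) and independent of the sweep-line code paths they check.
"""

from __future__ import annotations

from chromaggr.intervals import GenomicInterval


def _pair_gap(p: GenomicInterval, q: GenomicInterval) -> int | None:
    if p.chrom != q.chrom:
        return None
    return max(p.start, q.start) - min(p.end, q.end)


def brute_merge(peaks, max_gap):
    """Union-find transitive closure over the gap <= max_gap relation."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            g = _pair_gap(peaks[i], peaks[j])
            if g is not None and g <= max_gap:
                parent[find(i)] = find(j)
    clusters: dict[int, list[GenomicInterval]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(peaks[i])
    merged = [
        GenomicInterval(
            members[0].chrom,
            min(m.start for m in members),
            max(m.end for m in members),
            score=max(m.score for m in members),
        )
        for members in clusters.values()
    ]
    return sorted(merged, key=lambda p: (p.chrom, p.start))


def brute_overlaps_any(peak, targets, min_overlap=1):
    return any(
        peak.chrom == t.chrom
        and min(peak.end, t.end) - max(peak.start, t.start) >= min_overlap
        for t in targets
    )


def brute_intersect_fraction(peaks, segments, state_subset, min_overlap=1):
    targets = [s for s in segments if s.name in set(state_subset)]
    hits = sum(brute_overlaps_any(p, targets, min_overlap) for p in peaks)
    return hits / len(peaks)


def brute_cooccupancy(set_a, set_b, min_overlap=1):
    hits = sum(brute_overlaps_any(b, set_a, min_overlap) for b in set_b)
    return hits / len(set_b)


def brute_classify(peaks, segments, promoter_labels, enhancer_labels, min_overlap=1):
    prom, enh = set(promoter_labels), set(enhancer_labels)
    classes = []
    for p in peaks:
        labels = {
            s.name for s in segments
            if p.chrom == s.chrom
            and min(p.end, s.end) - max(p.start, s.start) >= min_overlap
        }
        has_p, has_e = bool(labels & prom), bool(labels & enh)
        classes.append(
            "both" if has_p and has_e
            else "promoter-only" if has_p
            else "enhancer-only" if has_e
            else "neither"
        )
    return classes


def random_intervals(rng, n, span=5000, max_len=400, chroms=("chr1", "chr2")):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, score=float(rng.random())))
    return sorted(out, key=lambda p: (p.chrom, p.start))


def random_segmentation_intervals(rng, n, labels, span=5000, max_len=300):
    """Random non-overlapping labeled segments (for classification oracles)."""
    out = []
    for chrom in ("chr1", "chr2"):
        cursor = 0
        for _ in range(n):
            gap = int(rng.integers(1, 200))
            length = int(rng.integers(1, max_len))
            start = cursor + gap
            if start + length > span:
                break
            out.append(
                GenomicInterval(
                    chrom, start, start + length,
                    name=labels[int(rng.integers(len(labels)))],
                )
            )
            cursor = start + length
    return out
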