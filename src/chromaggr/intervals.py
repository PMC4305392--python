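"""Genomic-interval model and text-format I/O.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; conversion, if any, happens only at the I/O boundary.
Chromosome names are compared as exact strings — no ``chr`` aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised for malformed BED-like lines; carries the line number."""


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is '+', '-' or '.' (unspecified); ``name`` is free text
    (peak id or chromatin-state label depending on context); ``score``
    is a real (e.g. -log10 p from a peak caller).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end ({self.end}) must be > start ({self.start})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        """True if the two intervals share at least ``min_overlap`` bases."""
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap


@dataclass(frozen=True)
class GeneAnchor:
    """A gene record anchoring strand-oriented profiles.

    ``metric`` is the stratification value (expression or Pol II
    occupancy); ``cgi_flag`` marks a CpG-island-overlapping TSS.
    """

    chrom: str
    tss: int
    tes: int
    strand: str
    cgi_flag: bool = False
    metric: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError("gene strand must be '+' or '-'")
        if self.tss == self.tes:
            raise ValidationError("tss must differ from tes")

    @property
    def body(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi, strand=self.strand, name=self.name)


@dataclass
class StateSegmentation:
    """An ordered, per-chromosome non-overlapping labeled genome partition.

    Each segment is a :class:`GenomicInterval` whose ``name`` carries the
    chromatin-state label (e.g. "active promoter", "enhancer state 4").
    """

    segments: list[GenomicInterval] = field(default_factory=list)
    state_catalog: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.chrom == prev.chrom and cur.start < prev.end:
                raise ValidationError(
                    f"overlapping segments on {cur.chrom}: "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )
        labels = {s.name for s in self.segments}
        if not self.state_catalog:
            self.state_catalog = labels
        else:
            unknown = labels - self.state_catalog
            if unknown:
                raise ValidationError(f"labels not in catalog: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.segments)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def state_of(self, chrom: str, pos: int) -> str | None:
        """Label of the segment containing ``pos``, or None in a gap.

        Linear scan; fine for the segment counts this package handles.
        """
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                return seg.name
        return None


# ---------------------------------------------------------------------------
# BED / narrowPeak

def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >= 3 tab-separated columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
    name = fields[3] if len(fields) > 3 else "."
    try:
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-numeric score") from exc
    strand = fields[5] if len(fields) > 5 else "."
    try:
        return GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
    except ValidationError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from exc


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6/narrowPeak into intervals.

    Columns 4-6 map to name/score/strand; columns beyond 6 (narrowPeak
    signalValue/pValue/qValue/summit) are accepted and ignored. Raises
    :class:`BedParseError` naming the offending line on malformed input.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            out.append(_parse_bed_line(line, lineno))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; 6 columns when any strand is set, else 3-5."""
    rows = list(intervals)
    six = any(iv.strand != "." for iv in rows)
    named = six or any(iv.name != "." or iv.score != 0.0 for iv in rows)
    with open(path, "w") as fh:
        for iv in rows:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if named:
                cols += [iv.name, _fmt_score(iv.score)]
            if six:
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_segmentation(
    path: str | Path, catalog: set[str] | None = None
) -> StateSegmentation:
    """Read a chromatin-state segmentation (BED with label in column 4).

    Segments are sorted per chromosome; within-chromosome overlap is
    rejected. If a ``catalog`` is supplied, unknown labels are rejected.
    """
    segs = read_bed(path)
    for i, seg in enumerate(segs, start=1):
        if seg.name == ".":
            raise BedParseError(f"segment {i}: missing state label (column 4)")
    return StateSegmentation(segs, state_catalog=set(catalog) if catalog else set())


def write_segmentation(seg: StateSegmentation, path: str | Path) -> None:
    write_bed(seg.segments, path)


# ---------------------------------------------------------------------------
# Gene and qPCR tables (TSV dialects with named header columns)

GENE_COLUMNS = ["chrom", "tss", "tes", "strand", "cgi", "metric"]


def read_gene_table(path: str | Path) -> list[GeneAnchor]:
    """Read the gene/TSS TSV: chrom, tss, tes, strand, cgi, metric [, name]."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"gene table missing columns: {missing}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneAnchor(
                chrom=str(row.chrom),
                tss=int(row.tss),
                tes=int(row.tes),
                strand=str(row.strand),
                cgi_flag=bool(row.cgi),
                metric=float(row.metric),
                name=str(getattr(row, "name", ".")),
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneAnchor], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "tes": [g.tes for g in genes],
            "strand": [g.strand for g in genes],
            "cgi": [int(g.cgi_flag) for g in genes],
            "metric": [g.metric for g in genes],
            "name": [g.name for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct TSV.

    Required columns: locus, condition, replicate, plus either
    (ct_undigested, ct_digested) for accessibility assays or
    (ct_ip, ct_input, input_fraction) for ChIP percent-input.
    """
    df = pd.read_csv(path, sep="\t")
    base = {"locus", "condition", "replicate"}
    if not base <= set(df.columns):
        raise ValidationError(f"qPCR table missing columns: {sorted(base - set(df.columns))}")
    acc = {"ct_undigested", "ct_digested"} <= set(df.columns)
    chip = {"ct_ip", "ct_input"} <= set(df.columns)
    if not (acc or chip):
        raise ValidationError(
            "qPCR table needs ct_undigested/ct_digested or ct_ip/ct_input columns"
        )
    return df


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Stable sort by (chrom, start, end)."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def shift_interval(iv: GenomicInterval, offset: int) -> GenomicInterval:
    return replace(iv, start=iv.start + offset, end=iv.end + offset)
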