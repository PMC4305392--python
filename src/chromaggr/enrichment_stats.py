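"""Per-state enrichment distributions and the statistical battery.

Covers the comparisons used for state-wise occupancy analyses: Tukey
box-plot summaries, Kruskal–Wallis with tie correction, Dunn's rank-based
post-hoc with multiplicity adjustment, one-way ANOVA with comparisons
against a control group, and the pooled-variance two-sample t-test.

Kruskal–Wallis, ANOVA and the t-test dispatch to scipy.stats; Dunn's
test (no scipy equivalent) is implemented here on mid-ranks with the
standard tie-corrected variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from chromaggr.intervals import StateSegmentation, ValidationError
from chromaggr.signal import BinnedTrack, region_fold_enrichment

ADJUSTMENTS = {"bonferroni": "bonferroni", "sidak": "sidak", "holm": "holm", "none": None}


@dataclass
class StateEnrichmentTable:
    """Fold-enrichment values grouped by chromatin-state label."""

    groups: dict[str, np.ndarray]
    regions: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        for label, vec in self.groups.items():
            if vec.size and not np.all(vec > 0):
                raise ValidationError(f"non-positive fold enrichment in {label!r}")

    def medians(self) -> dict[str, float]:
        return {
            k: float(np.median(v)) for k, v in self.groups.items() if v.size
        }

    def subset(self, labels: Sequence[str]) -> list[np.ndarray]:
        return [self.groups[l] for l in labels]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, vec in self.groups.items():
            regs = self.regions.get(label, [None] * len(vec))
            for fe, reg in zip(vec, regs):
                rows.append(
                    {
                        "state": label,
                        "chrom": getattr(reg, "chrom", None),
                        "start": getattr(reg, "start", None),
                        "end": getattr(reg, "end", None),
                        "fold_enrichment": fe,
                    }
                )
        return pd.DataFrame(rows, columns=["state", "chrom", "start", "end", "fold_enrichment"])


@dataclass(frozen=True)
class BoxSummary:
    """Tukey box-plot numbers: quartiles, whiskers at the most extreme
    data points within 1.5*IQR fences, points beyond as outliers."""

    median: float
    q1: float
    q3: float
    lo_whisker: float
    hi_whisker: float
    outliers: tuple[float, ...]


@dataclass
class TestResult:
    """Outcome of a hypothesis test, with optional pairwise table."""

    statistic: float
    p_value: float
    df: tuple[int, ...] | int | None = None
    group_sizes: tuple[int, ...] | None = None
    method: str = ""
    pairwise: pd.DataFrame | None = None


def enrichment_by_state(
    chip: BinnedTrack,
    input_track: BinnedTrack,
    segmentation: StateSegmentation,
    pseudocount: float = 1.0,
) -> StateEnrichmentTable:
    """One fold-enrichment value per segment, grouped by state label.

    States present in the catalog but without segments appear with empty
    vectors so downstream grouping is total.
    """
    groups: dict[str, list[float]] = {label: [] for label in segmentation.state_catalog}
    regions: dict[str, list] = {label: [] for label in segmentation.state_catalog}
    for seg in segmentation.segments:
        rec = region_fold_enrichment(chip, input_track, seg, pseudocount, state_label=seg.name)
        groups[seg.name].append(rec.fold_enrichment)
        regions[seg.name].append(seg)
    return StateEnrichmentTable(
        groups={k: np.asarray(v) for k, v in groups.items()}, regions=regions
    )


def tukey_box_summary(values: Sequence[float]) -> BoxSummary:
    """Five-number box summary with Tukey whiskers.

    Quartiles use linear interpolation between order statistics at
    positions 1+(n-1)p (numpy's default, the spreadsheet "type 7" rule);
    fences sit at q1 - 1.5*IQR and q3 + 1.5*IQR; whiskers are the extreme
    attained data values inside the fences.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("box summary of empty data")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = np.sort(x[(x < lo_fence) | (x > hi_fence)])
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        lo_whisker=float(inside.min()),
        hi_whisker=float(inside.max()),
        outliers=tuple(float(v) for v in outliers),
    )


def _check_groups(groups: Sequence[Sequence[float]], min_k: int = 2, min_n: int = 1):
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < min_k:
        raise ValidationError(f"need >= {min_k} groups, got {len(arrs)}")
    for i, g in enumerate(arrs):
        if g.size < min_n:
            raise ValidationError(f"group {i} has {g.size} < {min_n} values")
    return arrs


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H on mid-ranks with tie correction; p from chi2(k-1).

    All-identical data is a degenerate case: H is defined as 0, p = 1.
    """
    arrs = _check_groups(groups, min_k=2, min_n=1)
    pooled = np.concatenate(arrs)
    if pooled.size < 3:
        raise ValidationError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return TestResult(
            statistic=0.0, p_value=1.0, df=len(arrs) - 1,
            group_sizes=tuple(len(g) for g in arrs), method="kruskal-wallis",
        )
    h, p = sps.kruskal(*arrs)
    return TestResult(
        statistic=float(h), p_value=float(p), df=len(arrs) - 1,
        group_sizes=tuple(len(g) for g in arrs), method="kruskal-wallis",
    )


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjustment: str = "bonferroni",
    labels: Sequence[str] | None = None,
) -> TestResult:
    """Dunn's rank-based pairwise post-hoc after Kruskal–Wallis.

    z_ij = (meanrank_i - meanrank_j) / sqrt((N(N+1)/12 - T)*(1/n_i + 1/n_j))
    with the tie term T = sum(t^3 - t) / (12 (N - 1)) over tie-group sizes
    t; two-sided p from the standard normal, adjusted across all
    k(k-1)/2 comparisons (default Bonferroni).
    """
    if adjustment not in ADJUSTMENTS:
        raise ValidationError(f"adjustment must be one of {sorted(ADJUSTMENTS)}")
    arrs = _check_groups(groups, min_k=2, min_n=1)
    labels = list(labels) if labels is not None else [f"group{i+1}" for i in range(len(arrs))]
    pooled = np.concatenate(arrs)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)  # mid-ranks
    sizes = [g.size for g in arrs]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[offsets[i]: offsets[i + 1]].mean() for i in range(len(arrs))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (n_tot - 1)))
    base_var = n_tot * (n_tot + 1) / 12 - tie_term
    rows = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            se = np.sqrt(base_var * (1 / sizes[i] + 1 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * sps.norm.sf(abs(z))
            rows.append({"comparison": f"{labels[i]} vs {labels[j]}", "z": z, "p": p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = _adjust(table["p"].to_numpy(), adjustment)
    kw = kruskal_wallis(groups)
    kw.pairwise = table
    kw.method = f"kruskal-wallis + dunn ({adjustment})"
    return kw


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if ADJUSTMENTS[method] is None or p.size == 0:
        return p
    return np.maximum(p, multipletests(p, method=ADJUSTMENTS[method])[1])


def one_way_anova(
    groups: Sequence[Sequence[float]],
    control_index: int | None = None,
    adjustment: str = "holm",
    labels: Sequence[str] | None = None,
) -> TestResult:
    """One-way ANOVA F with (k-1, N-k) df.

    With ``control_index`` set, each other group is additionally compared
    against the control by pooled t, adjusted across comparisons
    (Holm by default) — the usual "stars against control" display.
    """
    arrs = _check_groups(groups, min_k=2, min_n=2)
    labels = list(labels) if labels is not None else [f"group{i+1}" for i in range(len(arrs))]
    n_tot = sum(g.size for g in arrs)
    msw = sum(((g - g.mean()) ** 2).sum() for g in arrs) / (n_tot - len(arrs))
    means = [g.mean() for g in arrs]
    if msw == 0:
        if max(means) > min(means):
            raise ValidationError("zero within-group variance with unequal means: F undefined")
        result = TestResult(statistic=0.0, p_value=1.0)
    else:
        f, p = sps.f_oneway(*arrs)
        result = TestResult(statistic=float(f), p_value=float(p))
    result.df = (len(arrs) - 1, n_tot - len(arrs))
    result.group_sizes = tuple(g.size for g in arrs)
    result.method = "one-way anova"
    if control_index is not None:
        rows = []
        for i, g in enumerate(arrs):
            if i == control_index:
                continue
            t = students_t(g, arrs[control_index])
            rows.append(
                {
                    "comparison": f"{labels[i]} vs {labels[control_index]}",
                    "t": t.statistic,
                    "p": t.p_value,
                }
            )
        table = pd.DataFrame(rows)
        table["p_adjusted"] = _adjust(table["p"].to_numpy(), adjustment)
        result.pairwise = table
        result.method += f" + control comparisons ({adjustment})"
    return result


def students_t(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sample pooled-variance (Student's) t, two-sided."""
    a, b = _check_groups([group_a, group_b], min_k=2, min_n=2)
    pooled_var = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        if a.mean() != b.mean():
            raise ValidationError("zero pooled variance with unequal means: t undefined")
        return TestResult(
            statistic=0.0, p_value=1.0, df=a.size + b.size - 2,
            group_sizes=(a.size, b.size), method="student t",
        )
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(
        statistic=float(t), p_value=float(p), df=a.size + b.size - 2,
        group_sizes=(a.size, b.size), method="student t",
    )
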