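"""qPCR calculus: nuclease accessibility, percent input, H3.3/H3 ratios.

Cycle-threshold (Ct) arithmetic assumes exactly two-fold amplification
per cycle, as the accessibility formula 2^(Ct_undigested - Ct_digested)
implies; there is no efficiency correction (documented limitation).
Accessibility is the fraction of template surviving nuclease digestion,
so values above 1 indicate an assay anomaly and are flagged, never
clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from chromaggr.intervals import ValidationError
from chromaggr.enrichment_stats import TestResult, one_way_anova, students_t


@dataclass(frozen=True)
class AccessibilityResult:
    """Replicate-mean accessibility for one locus/condition, as a ratio
    and as a percentage of the control condition."""

    locus: str
    condition: str
    accessibility: float
    percent_of_control: float
    flagged: bool = False


def accessibility(ct_undigested: float, ct_digested: float) -> float:
    """Template fraction surviving digestion: 2^(Ct_undigested - Ct_digested).

    Accessible chromatin is digested, raising Ct_digested and shrinking
    the ratio toward 0; protected chromatin leaves the two Ct values
    equal (ratio 1).
    """
    if not (math.isfinite(ct_undigested) and math.isfinite(ct_digested)):
        raise ValidationError("Ct values must be finite")
    return 2.0 ** (ct_undigested - ct_digested)


def is_anomalous(acc: float) -> bool:
    """Digestion should never increase template; > 1 flags assay failure."""
    return acc > 1.0


def _replicate_accessibilities(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["accessibility"] = [
        accessibility(u, d) for u, d in zip(df["ct_undigested"], df["ct_digested"])
    ]
    return out


def percent_of_control(
    records: pd.DataFrame,
    control_condition: str,
    aggregate: str = "arithmetic",
) -> list[AccessibilityResult]:
    """Per-locus accessibility normalized to the control condition, x100.

    For each locus, replicate accessibilities are aggregated per
    condition (arithmetic mean on the ratio scale by default; geometric
    mean available since delta-Ct noise is log-scale) and divided by the
    control-condition aggregate. The control maps to 100% by
    construction.
    """
    if aggregate not in ("arithmetic", "geometric"):
        raise ValidationError("aggregate must be 'arithmetic' or 'geometric'")
    df = _replicate_accessibilities(records)
    agg = (
        (lambda v: float(np.mean(v)))
        if aggregate == "arithmetic"
        else (lambda v: float(np.exp(np.mean(np.log(v)))))
    )
    results = []
    for locus, sub in df.groupby("locus", sort=False):
        conds = {c: agg(g["accessibility"].to_numpy()) for c, g in sub.groupby("condition", sort=False)}
        if control_condition not in conds:
            raise ValidationError(f"locus {locus!r} lacks control condition {control_condition!r}")
        ctrl = conds[control_condition]
        if ctrl == 0:
            raise ValidationError(f"control accessibility is 0 at locus {locus!r}")
        for cond, val in conds.items():
            results.append(
                AccessibilityResult(
                    locus=str(locus),
                    condition=str(cond),
                    accessibility=val,
                    percent_of_control=100.0 * val / ctrl,
                    flagged=is_anomalous(val),
                )
            )
    return results


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP yield as a percentage of dilution-adjusted input chromatin.

    The input sample is a fraction of the IP chromatin, so its Ct is
    first shifted by log2(1/input_fraction) cycles to represent 100%
    input; percent input is then 100 * 2^(adjusted_input_Ct - ct_ip).
    """
    if not (0 < input_fraction <= 1):
        raise ValidationError("input_fraction must be in (0, 1]")
    if not (math.isfinite(ct_ip) and math.isfinite(ct_input)):
        raise ValidationError("Ct values must be finite")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def relative_h33(h33_percent_input: float, h3_percent_input: float) -> float:
    """H3.3 occupancy normalized to total H3 occupancy (dimensionless).

    H3.3 deposition tracks nucleosome turnover; dividing by total H3
    separates variant enrichment from bulk nucleosome occupancy changes.
    """
    if h3_percent_input <= 0:
        raise ValidationError("H3 percent input must be > 0")
    return h33_percent_input / h3_percent_input


def condition_comparison(
    records: pd.DataFrame,
    control_condition: str,
    value_column: str | None = None,
    per_locus: bool = True,
) -> dict[str, TestResult]:
    """Test condition effects on replicate accessibility values.

    Dispatches to the pooled t-test for two conditions and one-way ANOVA
    (with comparisons against the control) for more. Runs per locus by
    default, or pooled across loci with ``per_locus=False``. Requires
    >= 2 replicates per condition.
    """
    if value_column is None:
        records = _replicate_accessibilities(records)
        value_column = "accessibility"
    conditions = list(dict.fromkeys(records["condition"]))
    if control_condition not in conditions:
        raise ValidationError(f"control condition {control_condition!r} absent")
    if len(conditions) < 2:
        raise ValidationError("need >= 2 conditions to compare")
    ordered = [control_condition] + [c for c in conditions if c != control_condition]
    groups_of = (
        records.groupby("locus", sort=False)
        if per_locus
        else [("pooled", records)]
    )
    out: dict[str, TestResult] = {}
    for locus, sub in groups_of:
        groups = [
            sub.loc[sub["condition"] == c, value_column].to_numpy() for c in ordered
        ]
        if any(g.size < 2 for g in groups):
            raise ValidationError(f"locus {locus!r}: need >= 2 replicates per condition")
        if len(groups) == 2:
            out[str(locus)] = students_t(groups[1], groups[0])
        else:
            out[str(locus)] = one_way_anova(
                groups, control_index=0, labels=ordered
            )
    return out
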