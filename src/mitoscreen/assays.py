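"""Phenotype-assay statistics.

Covers the downstream validation readouts: CCK-8 viability (OD450),
siRNA proliferation hit calling, annexin-V apoptosis fractions, soft
agar colony counts, and xenograft growth from caliper measurements
using the ellipsoid approximation

    volume = π/6 × major × minor²   [mm³]

All group comparisons are two-tailed pooled-variance Student's t tests;
zero-variance comparisons report p = 1 with a flag.
"""

from __future__ import annotations

import itertools
import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import InsufficientDataError, ValidationError
from .stats import TTestResult, pooled_ttest

logger = logging.getLogger("mitoscreen")

__all__ = [
    "relative_viability",
    "proliferation_hit_call",
    "dose_response_table",
    "apoptosis_summary",
    "colony_compare",
    "tumor_volume",
    "growth_curve_compare",
    "endpoint_weight_compare",
    "read_assay_table",
]


def relative_viability(
    treated: Sequence[float], vehicle: Sequence[float]
) -> dict:
    """Percent viability of treated cells relative to the vehicle control.

    percent = 100 × mean(treated OD450) / mean(vehicle OD450); the sd is
    that of per-replicate treated ODs against the fixed vehicle mean;
    the p value is a pooled-variance t on the raw OD values.
    """
    treated = np.asarray(treated, dtype=float)
    vehicle = np.asarray(vehicle, dtype=float)
    if len(treated) < 2 or len(vehicle) < 2:
        raise InsufficientDataError("need >=2 OD450 replicates per group")
    if np.any(treated <= 0) or np.any(vehicle <= 0):
        raise ValidationError("OD450 absorbances must be > 0")
    ratios = 100.0 * treated / vehicle.mean()
    t: TTestResult = pooled_ttest(treated, vehicle)
    return {
        "percent": float(ratios.mean()),
        "sd": float(ratios.std(ddof=1)),
        "p_value": t.p_value,
        "zero_variance": t.zero_variance,
    }


def proliferation_hit_call(
    si_viability_percent: float, threshold_percent: float = 75.0
) -> bool:
    """An siRNA is a proliferation hit when viability is strictly below
    the threshold (75% exactly is not a hit: "less than 75%")."""
    if si_viability_percent < 0:
        raise ValidationError("viability percent must be >= 0")
    return bool(si_viability_percent < threshold_percent)


def dose_response_table(
    doses: Mapping[float, tuple[Sequence[float], Sequence[float]]]
) -> pd.DataFrame:
    """Per-concentration relative-viability summaries with per-dose t tests.

    ``doses`` maps concentration -> (treated OD replicates, vehicle OD
    replicates).  No dose-response curve is fitted.
    """
    rows = []
    for conc in sorted(doses):
        treated, vehicle = doses[conc]
        r = relative_viability(treated, vehicle)
        rows.append({"concentration": conc, **r})
    return pd.DataFrame(rows)


def apoptosis_summary(
    groups: Mapping[str, Sequence[float]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean ± sd annexin-positive percentages per group plus pairwise t tests.

    Input fractions must lie in [0, 1]; output percentages are 100×.
    """
    summaries = []
    for name, fractions in groups.items():
        fr = np.asarray(fractions, dtype=float)
        if len(fr) < 2:
            raise InsufficientDataError(f"group {name!r}: need >=2 experiments")
        if np.any((fr < 0) | (fr > 1)):
            raise ValidationError(
                f"group {name!r}: annexin-positive fractions must be in [0, 1]"
            )
        summaries.append({
            "group": name,
            "mean_percent": float(100.0 * fr.mean()),
            "sd_percent": float((100.0 * fr).std(ddof=1)),
            "n": len(fr),
        })
    pairs = []
    for a, b in itertools.combinations(groups, 2):
        t = pooled_ttest(
            100.0 * np.asarray(groups[a], float), 100.0 * np.asarray(groups[b], float)
        )
        pairs.append({
            "group_a": a, "group_b": b,
            "p_value": t.p_value, "zero_variance": t.zero_variance,
        })
    return pd.DataFrame(summaries), pd.DataFrame(pairs)


def colony_compare(
    group_a: Sequence[int],
    group_b: Sequence[int],
    min_cells_per_colony: int = 50,
) -> dict:
    """Compare colony counts between two groups (two-tailed pooled t).

    Counts are assumed already filtered by the colony-size rule; the
    rule itself (colonies of >= ``min_cells_per_colony`` cells) is
    recorded as metadata in the output.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, x in (("A", a), ("B", b)):
        if len(x) < 2:
            raise InsufficientDataError(f"group {name}: need >=2 replicate counts")
        if np.any(x < 0) or not np.allclose(x, np.round(x)):
            raise ValidationError(f"group {name}: colony counts must be >=0 integers")
    t: TTestResult = pooled_ttest(a, b)
    return {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
        "p_value": t.p_value, "zero_variance": t.zero_variance,
        "min_cells_per_colony": int(min_cells_per_colony),
    }


def tumor_volume(major_mm: float, minor_mm: float) -> float:
    """Ellipsoid caliper volume π/6 × major × minor² in mm³."""
    if not (minor_mm > 0):
        raise ValidationError("axes must be > 0")
    if minor_mm > major_mm:
        raise ValidationError(
            f"minor axis ({minor_mm}) exceeds major axis ({major_mm})"
        )
    return math.pi / 6.0 * major_mm * minor_mm**2


def growth_curve_compare(arm_a: pd.DataFrame, arm_b: pd.DataFrame) -> dict:
    """Per-timepoint tumor-volume comparison between two xenograft arms.

    Each arm is a frame with columns mouse, day, major_mm, minor_mm (one
    caliper measurement per mouse per day).  Volumes are computed with
    :func:`tumor_volume`; each aligned day gets mean ± sd per arm and a
    two-tailed pooled t; the last day serves as the endpoint summary.
    """
    frames = {}
    for name, arm in (("a", arm_a), ("b", arm_b)):
        arm = arm.copy()
        required = {"mouse", "day", "major_mm", "minor_mm"}
        if not required.issubset(arm.columns):
            raise ValidationError(f"arm {name}: need columns {sorted(required)}")
        if arm["mouse"].nunique() < 2:
            raise InsufficientDataError(f"arm {name}: need >=2 mice")
        arm["volume"] = [
            tumor_volume(maj, mi) for maj, mi in zip(arm["major_mm"], arm["minor_mm"])
        ]
        frames[name] = arm
    days_a = set(frames["a"]["day"])
    days_b = set(frames["b"]["day"])
    if days_a != days_b:
        raise ValidationError(
            f"measurement days not aligned between arms: {sorted(days_a ^ days_b)}"
        )
    rows = []
    for day in sorted(days_a):
        va = frames["a"].loc[frames["a"]["day"] == day, "volume"].to_numpy()
        vb = frames["b"].loc[frames["b"]["day"] == day, "volume"].to_numpy()
        t = pooled_ttest(va, vb)
        rows.append({
            "day": day,
            "mean_a": va.mean(), "sd_a": va.std(ddof=1),
            "mean_b": vb.mean(), "sd_b": vb.std(ddof=1),
            "p_value": t.p_value, "zero_variance": t.zero_variance,
        })
    per_day = pd.DataFrame(rows)
    last = per_day.iloc[-1]
    return {
        "per_day": per_day,
        "endpoint_day": last["day"],
        "endpoint_ratio": float(last["mean_a"] / last["mean_b"]),
        "endpoint_p_value": float(last["p_value"]),
    }


def endpoint_weight_compare(
    weights_a: Sequence[float], weights_b: Sequence[float]
) -> dict:
    """Two-tailed t on endpoint tumor weights between arms."""
    t = pooled_ttest(weights_a, weights_b)
    a = np.asarray(weights_a, float)
    b = np.asarray(weights_b, float)
    return {
        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        "p_value": t.p_value, "zero_variance": t.zero_variance,
    }


def read_assay_table(path: str | Path) -> pd.DataFrame:
    """Read the long-format assay TSV (assay, group, replicate, payload...)."""
    df = pd.read_csv(path, sep="\t")
    if not {"assay", "group", "replicate"}.issubset(df.columns):
        raise ValidationError(f"{path}: need columns assay, group, replicate")
    return df
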