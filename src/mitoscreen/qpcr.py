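"""Relative quantification of qPCR data (ΔCt / ΔΔCt).

Each observation is one sample/condition with replicate threshold
cycles (Ct) for the target gene and for the β-actin endogenous control.
With perfect doubling per cycle (efficiency fixed at 2):

    ΔCt   = mean(target Ct) - mean(reference Ct)
    −ΔCt  = -(ΔCt)                      (higher = more transcript)
    level = 2^(−ΔCt)                    (relative to β-actin)

Folds between conditions are ΔΔCt ratios of mean relative levels; the
accompanying p value is a two-tailed equal-variance Student's t on the
−ΔCt values (Ct differences are closer to normal than ratios are).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    InsufficientDataError,
    PairingError,
    ValidationError,
)
from .stats import TTestResult, pooled_ttest, round_half_up

logger = logging.getLogger("mitoscreen")

__all__ = [
    "CtObservation",
    "read_ct_table",
    "write_ct_table",
    "relative_level",
    "fold_between_conditions",
    "pair_observations",
    "specimen_survey",
    "knockdown_qc",
]

#: replicate Ct spread (max - min) beyond which a QC warning is logged
REPLICATE_SPREAD_WARN = 1.5


@dataclass
class CtObservation:
    """Replicate Ct values for target and reference genes in one sample."""

    sample_id: str
    condition: str
    target_ct: np.ndarray
    reference_ct: np.ndarray

    def __post_init__(self) -> None:
        self.target_ct = np.asarray(self.target_ct, dtype=float)
        self.reference_ct = np.asarray(self.reference_ct, dtype=float)
        for name, ct in (("target", self.target_ct), ("reference", self.reference_ct)):
            if ct.size < 1:
                raise ValidationError(f"{self.sample_id}: no {name} Ct replicates")
            if not np.all((ct > 0) & (ct < 50)):
                raise ValidationError(
                    f"{self.sample_id}: {name} Ct values outside (0, 50): {ct}"
                )
            spread = float(ct.max() - ct.min())
            if spread > REPLICATE_SPREAD_WARN:
                logger.warning(
                    "qPCR QC: %s/%s %s replicate spread %.2f cycles > %.1f",
                    self.sample_id, self.condition, name, spread,
                    REPLICATE_SPREAD_WARN,
                )

    @property
    def delta_ct(self) -> float:
        return float(self.target_ct.mean() - self.reference_ct.mean())

    @property
    def neg_delta_ct(self) -> float:
        return -self.delta_ct

    @property
    def rel_level(self) -> float:
        return float(2.0 ** self.neg_delta_ct)


def relative_level(obs: CtObservation) -> dict[str, float]:
    """ΔCt, −ΔCt and the 2^(−ΔCt) relative level for one observation."""
    return {
        "delta_ct": obs.delta_ct,
        "neg_delta_ct": obs.neg_delta_ct,
        "rel_level": obs.rel_level,
    }


# ---------------------------------------------------------------------------
# TSV I/O (columns: sample_id, condition, gene_role, replicate, ct)
# ---------------------------------------------------------------------------

def read_ct_table(path: str | Path) -> list[CtObservation]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "gene_role", "replicate", "ct"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: need columns {sorted(required)}")
    obs = []
    for (sid, cond), grp in df.groupby(["sample_id", "condition"], sort=False):
        target = grp.loc[grp["gene_role"] == "target", "ct"].to_numpy(float)
        reference = grp.loc[grp["gene_role"] == "reference", "ct"].to_numpy(float)
        obs.append(CtObservation(str(sid), str(cond), target, reference))
    return obs


def write_ct_table(observations: Iterable[CtObservation], path: str | Path) -> None:
    rows = []
    for o in observations:
        for role, cts in (("target", o.target_ct), ("reference", o.reference_ct)):
            for i, ct in enumerate(cts, start=1):
                rows.append((o.sample_id, o.condition, role, i, repr(float(ct))))
    pd.DataFrame(
        rows, columns=["sample_id", "condition", "gene_role", "replicate", "ct"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Condition comparisons
# ---------------------------------------------------------------------------

def fold_between_conditions(
    condition_a: Sequence[CtObservation], condition_b: Sequence[CtObservation]
) -> dict:
    """ΔΔCt fold of condition A over condition B with sd and t-test p.

    fold = mean(levels_A) / mean(levels_B); the sd is that of the
    per-observation A levels each divided by the fixed mean B level
    (the single-number-per-cell "fold ± s.d." convention); the p value
    comes from a pooled-variance t on the −ΔCt values.
    """
    if len(condition_a) < 2 or len(condition_b) < 2:
        raise InsufficientDataError(
            f"need >=2 observations per condition, got "
            f"{len(condition_a)} and {len(condition_b)}"
        )
    levels_a = np.array([o.rel_level for o in condition_a])
    levels_b = np.array([o.rel_level for o in condition_b])
    ratios = levels_a / levels_b.mean()
    t: TTestResult = pooled_ttest(
        [o.neg_delta_ct for o in condition_a],
        [o.neg_delta_ct for o in condition_b],
    )
    return {
        "fold": float(levels_a.mean() / levels_b.mean()),
        "sd": float(ratios.std(ddof=1)),
        "p_value": t.p_value,
        "zero_variance": t.zero_variance,
    }


# ---------------------------------------------------------------------------
# Paired tumor/adjacent specimen survey
# ---------------------------------------------------------------------------

def pair_observations(
    observations: Sequence[CtObservation],
    tumor_condition: str = "tumor",
    adjacent_condition: str = "adjacent",
) -> list[tuple[CtObservation, CtObservation]]:
    """Match tumor and adjacent observations by sample id into pairs."""
    tumors = {o.sample_id: o for o in observations if o.condition == tumor_condition}
    adjs = {o.sample_id: o for o in observations if o.condition == adjacent_condition}
    unmatched = sorted(set(tumors) ^ set(adjs))
    if unmatched:
        raise PairingError(f"unmatched pair ids: {unmatched}")
    return [(tumors[sid], adjs[sid]) for sid in tumors]


def _box_stats(values: np.ndarray) -> dict[str, float]:
    return {
        "median": float(np.median(values)),
        "q25": float(np.percentile(values, 25)),
        "q75": float(np.percentile(values, 75)),
        "min": float(values.min()),
        "max": float(values.max()),
    }


def specimen_survey(
    pairs: Sequence[tuple[CtObservation, CtObservation]],
    call_fold_threshold: float = 2.0,
) -> dict:
    """Per-pair tumor/adjacent folds, up-regulation calls and box stats.

    A pair is called up-regulated when the tumor's relative level is at
    least ``call_fold_threshold`` times the adjacent level (fold =
    2^(−ΔCt_tumor − (−ΔCt_adjacent))).  ``percent_up`` is reported to
    one decimal, rounding half-up.  Box statistics (median, quartiles,
    extremes) of −ΔCt are returned per group.
    """
    if len(pairs) < 1:
        raise InsufficientDataError("need >=1 pair")
    per_pair = pd.DataFrame([
        {
            "pair_id": t.sample_id,
            "fold": 2.0 ** (t.neg_delta_ct - a.neg_delta_ct),
            "tumor_neg_delta_ct": t.neg_delta_ct,
            "adjacent_neg_delta_ct": a.neg_delta_ct,
        }
        for t, a in pairs
    ])
    per_pair["call"] = per_pair["fold"] >= call_fold_threshold
    n_up = int(per_pair["call"].sum())
    n_total = len(per_pair)
    return {
        "per_pair": per_pair,
        "n_up": n_up,
        "n_total": n_total,
        "percent_up": round_half_up(100.0 * n_up / n_total, 1),
        "box_tumor": _box_stats(per_pair["tumor_neg_delta_ct"].to_numpy()),
        "box_adjacent": _box_stats(per_pair["adjacent_neg_delta_ct"].to_numpy()),
        "call_fold_threshold": call_fold_threshold,
    }


# ---------------------------------------------------------------------------
# siRNA knockdown QC
# ---------------------------------------------------------------------------

def knockdown_qc(
    si_obs: Sequence[CtObservation],
    nc_obs: Sequence[CtObservation],
    max_remaining: float = 0.60,
) -> dict:
    """Fraction of transcript remaining after knockdown vs negative control.

    Passes only when the remaining fraction is strictly below
    ``max_remaining`` (a 0.60 remaining fraction fails: the criterion is
    "decreased to less than 60%").
    """
    if len(si_obs) < 1 or len(nc_obs) < 1:
        raise InsufficientDataError("need >=1 observation per condition")
    remaining = (
        np.mean([o.rel_level for o in si_obs])
        / np.mean([o.rel_level for o in nc_obs])
    )
    return {"remaining_fraction": float(remaining), "pass": bool(remaining < max_remaining)}
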