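"""Synthetic-data generators for every stage of the pipeline.

The generators emit exactly the TSV dialects the readers consume, so
they double as the test-fixture factory.  The expression generator
emulates the regime the screen was designed for: a multi-dataset
collection of probe-level log2 matrices with per-sample intensity
offsets, multi-probe genes, per-dataset missing genes, and a spiked
subset of genes overexpressed (+Δ log2) in a parameterized fraction of
tumors — the inter-patient heterogeneity that makes the frequency gate
meaningful.  Every draw is fixed by the config seed: identical config
=> byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ConfigError,
    ExpressionDataset,
    ValidationError,
    write_expression_dataset,
    write_probe_annotation,
)
from .qpcr import CtObservation

logger = logging.getLogger("mitoscreen")

__all__ = [
    "SimConfig",
    "make_expression_collection",
    "write_collection",
    "make_qpcr_experiment",
    "make_specimen_cohort",
    "AssayEffects",
    "make_assay_tables",
    "write_assay_tables",
]


# ---------------------------------------------------------------------------
# Expression collection
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-condition parameters for the expression-collection generator.

    Defaults mirror the screened microarray regime: three datasets,
    a few hundred genes with log2 baselines ~ Normal(8, 1), log2
    measurement noise sd 0.5, per-sample loading offsets sd 0.5, ten
    spiked genes raised by Δ = 1.5 log2 in 60% of tumors, 60 tumors and
    20 normal livers per dataset, and 5% of genes missing per dataset.
    """

    seed: int = 0
    n_datasets: int = 3
    n_genes: int = 500
    probes_per_gene: tuple[int, int] = (1, 3)
    n_tumor: int = 60
    n_normal: int = 20
    n_adjacent: int = 0
    baseline_mu_mean: float = 8.0
    baseline_mu_sd: float = 1.0
    noise_sd: float = 0.5
    sample_offset_sd: float = 0.5
    spike_genes: tuple[int, ...] | None = None  # default: first 10 gene ids
    spike_delta: float = 1.5
    spike_fraction: float = 0.60
    missing_gene_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("baseline_mu_sd", "noise_sd", "sample_offset_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 <= self.spike_fraction <= 1):
            raise ConfigError("spike_fraction must be in [0, 1]")
        if not (0 <= self.missing_gene_rate < 1):
            raise ConfigError("missing_gene_rate must be in [0, 1)")
        if self.probes_per_gene[0] < 1 or self.probes_per_gene[1] < self.probes_per_gene[0]:
            raise ConfigError("probes_per_gene must be a valid (low, high) range")

    @property
    def gene_ids(self) -> list[int]:
        # Entrez-style positive integers
        return list(range(1001, 1001 + self.n_genes))

    def resolved_spike_genes(self) -> list[int]:
        spikes = (
            list(self.spike_genes)
            if self.spike_genes is not None
            else self.gene_ids[:10]
        )
        unknown = sorted(set(spikes) - set(self.gene_ids))
        if unknown:
            raise ConfigError(f"spike gene ids outside gene range: {unknown}")
        return spikes


def make_expression_collection(
    cfg: SimConfig,
) -> tuple[list[ExpressionDataset], dict[str, int], pd.DataFrame]:
    """Generate datasets + probe annotation + spike truth table.

    Per gene g a log2 baseline μ_g is drawn once and shared across
    datasets; each probe value is μ_g (+Δ for tumor spike carriers)
    + per-sample offset δ_s + Normal(0, σ) noise.  Spike carriers are
    Bernoulli(spike_fraction) per tumor, independently per dataset; a
    ``missing_gene_rate`` fraction of genes is dropped per dataset.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = np.array(cfg.gene_ids)
    spikes = set(cfg.resolved_spike_genes())
    mu = rng.normal(cfg.baseline_mu_mean, cfg.baseline_mu_sd, size=cfg.n_genes)
    # quantize baselines to a 2^-20 grid so that in the noiseless limit
    # probe/replicate averages are exact in floating point and spiked
    # tumors sit at exactly 2^delta-fold over the reference
    mu = np.round(mu * 2.0**20) / 2.0**20
    mu_by_gene = dict(zip(gene_ids.tolist(), mu))

    datasets: list[ExpressionDataset] = []
    annotation: dict[str, int] = {}
    truth_rows = []
    for d in range(cfg.n_datasets):
        ds_id = f"SIM{d + 1:02d}"
        n_missing = int(round(cfg.missing_gene_rate * cfg.n_genes))
        missing = set(
            rng.choice(gene_ids, size=n_missing, replace=False).tolist()
        ) if n_missing else set()
        present_genes = [g for g in gene_ids.tolist() if g not in missing]

        sample_ids = (
            [f"{ds_id}_T{i + 1:03d}" for i in range(cfg.n_tumor)]
            + [f"{ds_id}_N{i + 1:03d}" for i in range(cfg.n_normal)]
            + [f"{ds_id}_A{i + 1:03d}" for i in range(cfg.n_adjacent)]
        )
        groups = (
            ["tumor"] * cfg.n_tumor
            + ["normal_liver"] * cfg.n_normal
            + ["adjacent_nontumor"] * cfg.n_adjacent
        )
        n_samples = len(sample_ids)
        offsets = rng.normal(0.0, cfg.sample_offset_sd, size=n_samples)

        probe_rows = []
        probe_ids = []
        carriers_by_gene: dict[int, np.ndarray] = {}
        for g in present_genes:
            n_probes = int(rng.integers(cfg.probes_per_gene[0], cfg.probes_per_gene[1] + 1))
            spike_add = np.zeros(n_samples)
            if g in spikes:
                carrier = rng.random(cfg.n_tumor) < cfg.spike_fraction
                carriers_by_gene[g] = carrier
                spike_add[: cfg.n_tumor] = np.where(carrier, cfg.spike_delta, 0.0)
            base = mu_by_gene[g] + spike_add + offsets
            for k in range(n_probes):
                pid = f"{ds_id}_p{g}_{k + 1}"
                probe_ids.append(pid)
                annotation[pid] = g
                probe_rows.append(base + rng.normal(0.0, cfg.noise_sd, size=n_samples))

        values = pd.DataFrame(
            np.vstack(probe_rows), index=pd.Index(probe_ids, name="probe_id"),
            columns=sample_ids,
        )
        pairing = {
            f"{ds_id}_T{i + 1:03d}": f"{ds_id}_A{i + 1:03d}"
            for i in range(min(cfg.n_tumor, cfg.n_adjacent))
        }
        datasets.append(ExpressionDataset(
            dataset_id=ds_id,
            values=values,
            sample_group=pd.Series(groups, index=sample_ids, name="group"),
            pairing=pairing,
        ))
        tumor_ids = sample_ids[: cfg.n_tumor]
        for g in gene_ids.tolist():
            carrier = carriers_by_gene.get(g)
            truth_rows.append({
                "dataset_id": ds_id,
                "entrez_id": g,
                "spiked": g in spikes,
                "present": g not in missing,
                "n_carriers": int(carrier.sum()) if carrier is not None else 0,
                "carriers": ";".join(
                    np.array(tumor_ids)[carrier].tolist()
                ) if carrier is not None else "",
            })
    truth = pd.DataFrame(truth_rows)
    logger.info(
        "simulated %d datasets x %d genes (%d spiked), seed=%d",
        cfg.n_datasets, cfg.n_genes, len(spikes), cfg.seed,
    )
    return datasets, annotation, truth


def write_collection(
    datasets: Sequence[ExpressionDataset],
    annotation: Mapping[str, int],
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> list[Path]:
    """Write every dataset, the annotation and the truth table as TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for ds in datasets:
        mpath = out / f"{ds.dataset_id}_matrix.tsv"
        dpath = out / f"{ds.dataset_id}_metadata.tsv"
        write_expression_dataset(ds, mpath, dpath)
        written += [mpath, dpath]
    apath = out / "probe_annotation.tsv"
    write_probe_annotation(annotation, apath)
    tpath = out / "truth.tsv"
    truth.to_csv(tpath, sep="\t", index=False)
    return written + [apath, tpath]


# ---------------------------------------------------------------------------
# qPCR experiments
# ---------------------------------------------------------------------------

def make_qpcr_experiment(
    true_fold: float,
    n_reps: int = 3,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
    n_obs: int = 3,
    reference_ct_mean: float = 16.0,
    target_offset: float = 8.0,
) -> tuple[list[CtObservation], list[CtObservation]]:
    """Two-condition qPCR experiment with a known true fold (A over B).

    Condition B targets sit ``target_offset`` cycles above the β-actin
    reference; condition A targets are shifted by −log2(true_fold)
    cycles, so the ΔΔCt estimate should recover ``true_fold``.  Each
    condition yields ``n_obs`` observations of ``n_reps`` replicates
    with Normal(0, ct_noise_sd) cycle noise on every well.
    """
    if not true_fold > 0:
        raise ConfigError("true_fold must be > 0")
    rng = np.random.default_rng(seed)

    def draw(condition: str, shift: float) -> list[CtObservation]:
        obs = []
        for i in range(n_obs):
            ref = reference_ct_mean + rng.normal(0.0, ct_noise_sd, size=n_reps)
            tgt = (
                reference_ct_mean + target_offset + shift
                + rng.normal(0.0, ct_noise_sd, size=n_reps)
            )
            obs.append(CtObservation(f"{condition}_{i + 1}", condition, tgt, ref))
        return obs

    return draw("A", -math.log2(true_fold)), draw("B", 0.0)


# ---------------------------------------------------------------------------
# Paired specimen cohort
# ---------------------------------------------------------------------------

def make_specimen_cohort(
    n_pairs: int = 53,
    frac_up: float = 46.0 / 53.0,
    up_fold_range: tuple[float, float] = (2.5, 12.0),
    seed: int = 0,
    ct_noise_sd: float = 0.05,
    n_reps: int = 3,
) -> list[tuple[CtObservation, CtObservation]]:
    """Paired tumor/adjacent cohort with a set fraction of up-regulated pairs.

    round(frac_up × n_pairs) pairs get a tumor/adjacent fold drawn
    uniformly from ``up_fold_range`` (kept above the 2-fold call
    threshold); the rest get folds near 1 (uniform in [0.7, 1.4], below
    the threshold).  Small replicate Ct noise leaves the calls intact.
    """
    if not (0 <= frac_up <= 1):
        raise ConfigError("frac_up must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_up = int(round(frac_up * n_pairs))
    pairs = []
    for i in range(n_pairs):
        if i < n_up:
            fold = float(rng.uniform(*up_fold_range))
        else:
            fold = float(rng.uniform(0.7, 1.4))
        adj_delta_ct = float(rng.uniform(9.0, 12.0))  # low baseline transcript
        tum_delta_ct = adj_delta_ct - math.log2(fold)
        sid = f"P{i + 1:03d}"

        def obs(cond: str, dct: float) -> CtObservation:
            ref = 16.0 + rng.normal(0.0, ct_noise_sd, size=n_reps)
            tgt = 16.0 + dct + rng.normal(0.0, ct_noise_sd, size=n_reps)
            return CtObservation(sid, cond, tgt, ref)

        pairs.append((obs("tumor", tum_delta_ct), obs("adjacent", adj_delta_ct)))
    return pairs


# ---------------------------------------------------------------------------
# Assay tables
# ---------------------------------------------------------------------------

@dataclass
class AssayEffects:
    """True effects for the assay-table generator (treatment vs control)."""

    viability_effect: float = 0.5       # treated OD / vehicle OD
    od_vehicle_mean: float = 0.8
    od_noise_sd: float = 0.04
    n_od_reps: int = 3
    apoptosis_control: float = 0.025    # annexin+ fraction
    apoptosis_treated: float = 0.30
    apoptosis_noise_sd: float = 0.02
    n_apoptosis_reps: int = 3
    colony_mean_a: float = 100.0
    colony_mean_b: float = 50.0
    colony_sd: float = 5.0
    n_colony_reps: int = 3
    volume_ratio: float = 2.0           # arm A endpoint volume / arm B
    caliper_sigma: float = 0.2          # lognormal sd on volumes
    n_mice: int = 5
    days: tuple[int, ...] = (7, 10, 14, 17, 21)
    base_volume_day0: float = 30.0      # mm^3
    growth_rate: float = 0.12           # per day, exponential

    def __post_init__(self) -> None:
        for name in ("viability_effect", "volume_ratio"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")


def _axes_from_volume(volume: float, aspect: float = 1.5) -> tuple[float, float]:
    # invert v = pi/6 * (aspect*minor) * minor^2
    minor = (6.0 * volume / (math.pi * aspect)) ** (1.0 / 3.0)
    return aspect * minor, minor


def make_assay_tables(
    effects: AssayEffects | None = None, seed: int = 0
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Generate OD450, apoptosis, colony and caliper tables with known truth."""
    eff = effects or AssayEffects()
    rng = np.random.default_rng(seed)

    od_vehicle = eff.od_vehicle_mean + rng.normal(0, eff.od_noise_sd, eff.n_od_reps)
    od_treated = (
        eff.od_vehicle_mean * eff.viability_effect
        + rng.normal(0, eff.od_noise_sd, eff.n_od_reps)
    )
    viability = pd.DataFrame({
        "assay": "viability_od450",
        "group": ["treated"] * eff.n_od_reps + ["vehicle"] * eff.n_od_reps,
        "replicate": list(range(1, eff.n_od_reps + 1)) * 2,
        "od450": np.concatenate([od_treated, od_vehicle]),
    })

    ap_c = np.clip(
        eff.apoptosis_control + rng.normal(0, eff.apoptosis_noise_sd, eff.n_apoptosis_reps),
        0.0, 1.0,
    )
    ap_t = np.clip(
        eff.apoptosis_treated + rng.normal(0, eff.apoptosis_noise_sd, eff.n_apoptosis_reps),
        0.0, 1.0,
    )
    apoptosis = pd.DataFrame({
        "assay": "apoptosis_fraction",
        "group": ["treated"] * eff.n_apoptosis_reps + ["control"] * eff.n_apoptosis_reps,
        "replicate": list(range(1, eff.n_apoptosis_reps + 1)) * 2,
        "fraction": np.concatenate([ap_t, ap_c]),
    })

    col_a = np.maximum(
        np.round(eff.colony_mean_a + rng.normal(0, eff.colony_sd, eff.n_colony_reps)), 0
    ).astype(int)
    col_b = np.maximum(
        np.round(eff.colony_mean_b + rng.normal(0, eff.colony_sd, eff.n_colony_reps)), 0
    ).astype(int)
    colony = pd.DataFrame({
        "assay": "colony_count",
        "group": ["A"] * eff.n_colony_reps + ["B"] * eff.n_colony_reps,
        "replicate": list(range(1, eff.n_colony_reps + 1)) * 2,
        "count": np.concatenate([col_a, col_b]),
    })

    caliper_rows = []
    for arm, ratio in (("A", eff.volume_ratio), ("B", 1.0)):
        for mouse in range(1, eff.n_mice + 1):
            for day in eff.days:
                v_true = eff.base_volume_day0 * ratio * math.exp(eff.growth_rate * day)
                v = v_true * (
                    math.exp(rng.normal(0.0, eff.caliper_sigma))
                    if eff.caliper_sigma > 0 else 1.0
                )
                major, minor = _axes_from_volume(v)
                caliper_rows.append({
                    "assay": "caliper", "group": arm,
                    "replicate": mouse, "mouse": f"{arm}{mouse}",
                    "day": day, "major_mm": major, "minor_mm": minor,
                })
    caliper = pd.DataFrame(caliper_rows)

    truth = {
        "viability_effect": eff.viability_effect,
        "apoptosis_control": eff.apoptosis_control,
        "apoptosis_treated": eff.apoptosis_treated,
        "colony_mean_a": eff.colony_mean_a,
        "colony_mean_b": eff.colony_mean_b,
        "volume_ratio": eff.volume_ratio,
        "seed": seed,
    }
    return (
        {"viability": viability, "apoptosis": apoptosis,
         "colony": colony, "caliper": caliper},
        truth,
    )


def write_assay_tables(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out / f"assay_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
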