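"""Dual fold-change / patient-frequency overexpression screen.

For each gene in each dataset the screen computes, on log2 values:

* a reference level over normal-liver (or adjacent) samples;
* per-tumor-sample linear folds ``2^(x_s - ref)`` and overexpression
  calls at an inclusive fold threshold ("no less than" 2-fold);
* the dataset-level fold ``2^(mean tumor - ref)``, the overexpression
  frequency (#calls / #tumors with a measurement), and a two-tailed
  equal-variance Student's t p value, tumor vs reference;

and then combines per-dataset passes (fold AND frequency gates) into a
"markedly overexpressed" consensus flag under one of three rules
(pass everywhere present, pass in a majority of present datasets, or a
pooled recomputation across all tumors).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ConfigError,
    GeneMatrix,
    InsufficientDataError,
    InsufficientReferenceError,
    ScreenConfig,
    ScreenResult,
)
from .preprocess import median_normalize, subset_genes
from .stats import TTestResult, bh_adjust, pooled_ttest, pooled_ttest_rows

logger = logging.getLogger("mitoscreen")

__all__ = [
    "normal_reference",
    "sample_fold_calls",
    "gene_dataset_summary",
    "screen_collection",
    "mark_overexpressed",
    "tumor_vs_adjacent_test",
    "export_screen_tables",
    "read_screen_tables",
    "recompute_marked",
]


# ---------------------------------------------------------------------------
# Per-gene operations
# ---------------------------------------------------------------------------

def _gene_values(gm: GeneMatrix, gene: int, samples: Sequence[str]) -> pd.Series:
    if gene not in gm.values.index:
        return pd.Series(dtype=float)
    return gm.values.loc[gene, list(samples)].astype(float)


def normal_reference(gm: GeneMatrix, gene: int, cfg: ScreenConfig | None = None) -> float:
    """Reference log2 level of a gene over the reference-group samples."""
    cfg = cfg or ScreenConfig()
    ref_samples = gm.samples_in_group(cfg.reference_group)
    vals = _gene_values(gm, gene, ref_samples).dropna()
    if len(vals) < 2:
        raise InsufficientReferenceError(
            f"gene {gene}: {len(vals)} usable {cfg.reference_group} sample(s) "
            f"in dataset {gm.dataset_id!r}; need >=2"
        )
    return float(vals.mean() if cfg.reference_stat == "mean" else vals.median())


def sample_fold_calls(
    gm: GeneMatrix, gene: int, cfg: ScreenConfig | None = None
) -> pd.DataFrame:
    """Per-tumor-sample linear fold over the reference and the call flag.

    Tumor samples with a missing measurement are excluded (they appear
    in neither the calls nor the frequency denominator).
    """
    cfg = cfg or ScreenConfig()
    ref = normal_reference(gm, gene, cfg)
    tumor = _gene_values(gm, gene, gm.samples_in_group("tumor")).dropna()
    fold = np.power(2.0, tumor - ref)
    return pd.DataFrame({"fold": fold, "call": fold >= cfg.fold_threshold})


def gene_dataset_summary(
    gm: GeneMatrix, gene: int, cfg: ScreenConfig | None = None
) -> dict:
    """Fold, frequency, t-test p value and presence for one gene/dataset."""
    cfg = cfg or ScreenConfig()
    absent = {
        "fold": np.nan, "freq": np.nan, "p_value": np.nan,
        "present": False, "zero_variance": False,
    }
    if gene not in gm.values.index:
        return absent
    tumor = _gene_values(gm, gene, gm.samples_in_group("tumor")).dropna()
    ref_vals = _gene_values(gm, gene, gm.samples_in_group(cfg.reference_group)).dropna()
    if tumor.empty and ref_vals.empty:
        return absent
    ref = normal_reference(gm, gene, cfg)
    calls = sample_fold_calls(gm, gene, cfg)
    fold = float(np.power(2.0, tumor.mean() - ref)) if len(tumor) else np.nan
    freq = float(calls["call"].mean()) if len(calls) else np.nan
    try:
        t: TTestResult = pooled_ttest(tumor, ref_vals)
        p, zero = t.p_value, t.zero_variance
    except InsufficientDataError:
        p, zero = np.nan, False
    return {"fold": fold, "freq": freq, "p_value": p, "present": True,
            "zero_variance": zero}


def tumor_vs_adjacent_test(
    gm: GeneMatrix, gene: int, paired: bool = False
) -> TTestResult:
    """Two-tailed t test of a gene's log2 values, tumor vs adjacent liver.

    Unpaired (pooled-variance) by default; the paired variant uses the
    dataset's tumor<->adjacent pairing metadata and a one-sample t on
    the per-pair differences.
    """
    tumor = _gene_values(gm, gene, gm.samples_in_group("tumor")).dropna()
    adj = _gene_values(gm, gene, gm.samples_in_group("adjacent_nontumor")).dropna()
    if not paired:
        if len(tumor) < 2 or len(adj) < 2:
            raise InsufficientDataError(
                f"gene {gene}: {len(tumor)} tumor / {len(adj)} adjacent usable "
                "samples; need >=2 in each group"
            )
        return pooled_ttest(tumor, adj)
    if not gm.pairing:
        raise ConfigError(f"dataset {gm.dataset_id!r} has no pairing metadata")
    diffs = np.array([
        tumor[t] - adj[a]
        for t, a in gm.pairing.items()
        if t in tumor.index and a in adj.index
    ])
    if len(diffs) < 2:
        raise InsufficientDataError(
            f"gene {gene}: {len(diffs)} usable pairs; need >=2"
        )
    sd = diffs.std(ddof=1)
    df = len(diffs) - 1
    if sd == 0.0:
        same = diffs.mean() == 0.0
        return TTestResult(0.0 if same else np.inf, 1.0 if same else 0.0, df, True)
    from scipy import stats as sps
    t = diffs.mean() / (sd / np.sqrt(len(diffs)))
    return TTestResult(float(t), float(2 * sps.t.sf(abs(t), df)), df, False)


# ---------------------------------------------------------------------------
# Collection-level screen (vectorised over genes)
# ---------------------------------------------------------------------------

def _dataset_frames(
    gm: GeneMatrix, genes: Sequence[int], cfg: ScreenConfig
) -> pd.DataFrame:
    """Per-gene fold/freq/p/present for one dataset, vectorised."""
    sub = subset_genes(gm, genes).values
    tumor_cols = gm.samples_in_group("tumor")
    ref_cols = gm.samples_in_group(cfg.reference_group)
    tumor = sub[tumor_cols]
    ref = sub[ref_cols]

    n_ref = ref.notna().sum(axis=1)
    if cfg.reference_stat == "mean":
        ref_level = ref.mean(axis=1, skipna=True)
    else:
        ref_level = ref.median(axis=1, skipna=True)
    n_tumor = tumor.notna().sum(axis=1)

    folds_per_sample = np.power(2.0, tumor.sub(ref_level, axis=0))
    calls = folds_per_sample >= cfg.fold_threshold
    freq = calls.sum(axis=1) / n_tumor.where(n_tumor > 0)
    fold = np.power(2.0, tumor.mean(axis=1, skipna=True) - ref_level)
    p, zero, _valid = pooled_ttest_rows(tumor.to_numpy(), ref.to_numpy())

    # evaluable: gene measured with a usable reference and >=1 tumor value
    present = (n_ref >= 2) & (n_tumor >= 1)
    out = pd.DataFrame({
        "fold": fold.where(present),
        "freq": freq.where(present),
        "p_value": pd.Series(p, index=sub.index).where(present),
        "present": present,
        "zero_variance": pd.Series(zero, index=sub.index) & present,
    })
    return out


def _pooled_matrix(
    gene_matrices: Mapping[str, GeneMatrix], genes: Sequence[int]
) -> GeneMatrix:
    """Concatenate per-dataset-normalized matrices into one pooled matrix."""
    frames, groups = [], []
    for ds_id, gm in gene_matrices.items():
        norm = gm if gm.normalized else median_normalize(gm)
        sub = subset_genes(norm, genes)
        renamed = sub.values.rename(columns=lambda s: f"{ds_id}:{s}")
        frames.append(renamed)
        groups.append(sub.sample_group.rename(index=lambda s: f"{ds_id}:{s}"))
    values = pd.concat(frames, axis=1)
    group = pd.concat(groups)
    return GeneMatrix(
        dataset_id="pooled", values=values, sample_group=group, normalized=True
    )


def _dual_gate(fold, freq, present, cfg: ScreenConfig):
    """Per-dataset pass: overexpressed (>= fold_threshold) in at least
    freq_threshold of the patient population.

    The fold threshold acts per tumor sample inside ``freq``; with
    ``require_dataset_fold`` the dataset-level mean fold must clear the
    threshold as well.
    """
    passed = (freq >= cfg.freq_threshold) & present
    if cfg.require_dataset_fold:
        passed = passed & (fold >= cfg.fold_threshold)
    return passed.fillna(False) if hasattr(passed, "fillna") else passed


def mark_overexpressed(
    summaries: Mapping[str, pd.DataFrame],
    cfg: ScreenConfig | None = None,
    pooled_pass: pd.Series | None = None,
) -> ScreenResult:
    """Combine per-dataset summaries into the consensus overexpression flag.

    ``summaries`` maps dataset id -> frame with columns fold, freq,
    p_value, present, zero_variance indexed by gene.  For the pooled
    rule the caller supplies ``pooled_pass`` (see screen_collection).
    """
    cfg = cfg or ScreenConfig()
    if not summaries:
        raise ConfigError("need >=1 dataset")
    ids = list(summaries)
    fold = pd.DataFrame({d: summaries[d]["fold"] for d in ids})
    freq = pd.DataFrame({d: summaries[d]["freq"] for d in ids})
    p = pd.DataFrame({d: summaries[d]["p_value"] for d in ids})
    present = pd.DataFrame({d: summaries[d]["present"] for d in ids}).fillna(False)
    zero = pd.DataFrame({d: summaries[d]["zero_variance"] for d in ids}).fillna(False)

    passed = _dual_gate(fold, freq, present, cfg)
    n_present = present.sum(axis=1)
    n_pass = passed.sum(axis=1)
    if cfg.min_datasets_rule == "all_present":
        marked = (n_present > 0) & (n_pass == n_present)
    elif cfg.min_datasets_rule == "majority_present":
        marked = (n_present > 0) & (n_pass > n_present / 2.0)
    else:  # pooled
        if pooled_pass is None:
            raise ConfigError("pooled rule needs the pooled recomputation")
        marked = pooled_pass.reindex(fold.index).fillna(False) & (n_present > 0)
    return ScreenResult(
        fold=fold, freq=freq, p_value=p, present=present, zero_variance=zero,
        passed=passed, marked=marked.astype(bool), config=cfg,
    )


def screen_collection(
    gene_matrices: Mapping[str, GeneMatrix],
    genes: Sequence[int],
    cfg: ScreenConfig | None = None,
) -> ScreenResult:
    """Run the dual fold/frequency screen over a collection of datasets."""
    cfg = cfg or ScreenConfig()
    if not gene_matrices:
        raise ConfigError("need >=1 dataset")
    summaries = {
        ds_id: _dataset_frames(gm, genes, cfg)
        for ds_id, gm in gene_matrices.items()
    }
    pooled_pass = None
    if cfg.min_datasets_rule == "pooled":
        pooled = _pooled_matrix(gene_matrices, genes)
        pf = _dataset_frames(pooled, genes, cfg)
        pooled_pass = _dual_gate(pf["fold"], pf["freq"], pf["present"], cfg)
    result = mark_overexpressed(summaries, cfg, pooled_pass)
    logger.info(
        "screen: %d genes x %d datasets, %d marked",
        len(result.genes), len(result.dataset_ids), int(result.marked.sum()),
    )
    return result


def recompute_marked(result: ScreenResult) -> pd.Series:
    """Re-derive the consensus flag from the stored per-dataset records.

    Only meaningful for the all_present / majority_present rules (the
    pooled rule needs the underlying matrices); used to verify that the
    stored flag matches its definition.
    """
    cfg = result.config
    if cfg.min_datasets_rule == "pooled":
        raise ConfigError("pooled rule cannot be recomputed from summaries alone")
    passed = _dual_gate(result.fold, result.freq, result.present, cfg)
    n_present = result.present.sum(axis=1)
    n_pass = passed.sum(axis=1)
    if cfg.min_datasets_rule == "all_present":
        return ((n_present > 0) & (n_pass == n_present)).astype(bool)
    return ((n_present > 0) & (n_pass > n_present / 2.0)).astype(bool)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_MATRIX_FILES = {
    "fold": "fold_matrix.tsv",
    "freq": "freq_matrix.tsv",
    "p_value": "pvalue_matrix.tsv",
}


def export_screen_tables(
    result: ScreenResult, out_dir: str | Path, heatmap: bool = False
) -> list[Path]:
    """Write fold/freq/p matrices (NA for absent) and the marked-gene list.

    ``marked_genes.tsv`` carries the per-rule flags plus a
    Benjamini-Hochberg column (``min_p_bh``) provided for convenience on
    top of the raw per-dataset p values the screen itself uses.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for attr, fname in _MATRIX_FILES.items():
        path = out / fname
        getattr(result, attr).to_csv(
            path, sep="\t", na_rep="NA", index_label="entrez_id"
        )
        written.append(path)

    n_present = result.present.sum(axis=1)
    n_pass = result.passed.sum(axis=1)
    min_p = result.p_value.min(axis=1)
    genes_table = pd.DataFrame({
        "entrez_id": result.fold.index,
        "n_present": n_present.values,
        "n_pass": n_pass.values,
        "marked_all_present": ((n_present > 0) & (n_pass == n_present)).values,
        "marked_majority_present": ((n_present > 0) & (n_pass > n_present / 2.0)).values,
        "marked": result.marked.values,
        "min_p": min_p.values,
        "min_p_bh": bh_adjust(min_p.values),
    })
    gpath = out / "marked_genes.tsv"
    genes_table.to_csv(gpath, sep="\t", na_rep="NA", index=False)
    written.append(gpath)

    if heatmap:
        written.append(_write_heatmap(result, out / "screen_heatmap.png"))
    return written


def _write_heatmap(result: ScreenResult, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, 2, figsize=(2 + 0.6 * len(result.dataset_ids) * 2, 1 + 0.25 * len(result.genes)),
        squeeze=False,
    )
    for ax, (frame, title) in zip(
        axes[0],
        [(np.log2(result.fold), "log2 fold"), (result.freq, "frequency")],
    ):
        masked = np.ma.masked_invalid(frame.to_numpy(dtype=float))
        cmap = plt.get_cmap("RdBu_r").copy()
        cmap.set_bad("lightgray")  # missing data in gray
        im = ax.imshow(masked, aspect="auto", cmap=cmap)
        ax.set_xticks(range(len(frame.columns)), frame.columns, rotation=90)
        ax.set_yticks(range(len(frame.index)), frame.index, fontsize=6)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def read_screen_tables(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read back the exported fold/freq/p matrices and the gene list."""
    out = Path(out_dir)
    frames = {
        attr: pd.read_csv(out / fname, sep="\t", index_col=0, na_values=["NA"])
        for attr, fname in _MATRIX_FILES.items()
    }
    frames["marked_genes"] = pd.read_csv(
        out / "marked_genes.tsv", sep="\t", na_values=["NA"]
    )
    return frames
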