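"""Domain types and tab-delimited readers/writers.

The screening pipeline works on probe-level expression matrices
(probes x samples, log2 units after ingestion) annotated with sample
groups (tumor, normal liver, adjacent non-tumorous liver) and an
optional tumor<->adjacent pairing, plus a probe -> Entrez GeneID map
used to collapse probes to genes.

All on-disk formats are plain UTF-8 TSV with ``NA`` for missing values:

* expression matrix: header ``probe_id<TAB>sample1<TAB>...``;
* sample metadata: columns ``sample_id``, ``group``, optional ``pair_with``;
* probe annotation: columns ``probe_id``, ``entrez_id`` (blank/NA allowed).

A minimal read-only parser for GEO series-matrix files is included for
convenience; it never touches the network.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mitoscreen")

SAMPLE_GROUPS = ("tumor", "normal_liver", "adjacent_nontumor")

ScaleFlag = Literal["log2", "linear"]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class MitoscreenError(Exception):
    """Base class for all package errors."""


class FormatError(MitoscreenError):
    """A file does not conform to the expected dialect."""


class MetadataError(MitoscreenError):
    """Sample metadata is missing, inconsistent, or uses unknown labels."""


class PairingError(MitoscreenError):
    """Tumor/adjacent pairing information is invalid or unmatched."""


class ConfigError(MitoscreenError):
    """An invalid configuration value or request."""


class ValidationError(MitoscreenError):
    """A domain-type invariant is violated."""


class InsufficientDataError(MitoscreenError):
    """Too few usable observations for the requested statistic."""


class InsufficientReferenceError(InsufficientDataError):
    """Fewer than two usable reference-group values for a gene."""


class NetworkDisabledError(MitoscreenError):
    """A remote fetch was requested but network use is disabled."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _check_unique(ids: Sequence, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dup}")


@dataclass
class ExpressionDataset:
    """One study's probe-level log2 expression matrix with sample metadata.

    ``values`` is a probes x samples DataFrame in log2 units (ingestion
    converts linear intensities).  ``sample_group`` assigns each sample to
    tumor / normal_liver / adjacent_nontumor; entries may be left missing
    (e.g. straight after GEO ingestion) but group-dependent operations
    will refuse to run until they are annotated.  ``pairing`` maps tumor
    sample ids to their adjacent non-tumorous partner, injectively.
    """

    dataset_id: str
    values: pd.DataFrame
    sample_group: pd.Series
    pairing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        self.sample_group = self.sample_group.reindex(self.values.columns)
        bad = self.sample_group.dropna()[~self.sample_group.dropna().isin(SAMPLE_GROUPS)]
        if len(bad):
            raise MetadataError(
                f"unknown sample group label(s) {sorted(set(bad))}; "
                f"expected one of {SAMPLE_GROUPS}"
            )
        self._validate_pairing()

    def _validate_pairing(self) -> None:
        seen_partners: set[str] = set()
        for t, a in self.pairing.items():
            if t not in self.values.columns or a not in self.values.columns:
                raise PairingError(f"pairing ({t} -> {a}) references unknown sample")
            if self.sample_group.get(t) != "tumor":
                raise PairingError(f"pairing key {t!r} is not a tumor sample")
            if self.sample_group.get(a) != "adjacent_nontumor":
                raise PairingError(f"pairing partner {a!r} is not adjacent_nontumor")
            if a in seen_partners:
                raise PairingError(f"adjacent sample {a!r} paired to multiple tumors")
            seen_partners.add(a)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        if group not in SAMPLE_GROUPS:
            raise ConfigError(f"unknown group {group!r}")
        return list(self.sample_group[self.sample_group == group].index)


@dataclass
class GeneMatrix:
    """Gene-level (Entrez-collapsed) log2 expression matrix.

    Row index holds Entrez GeneIDs (ints, ascending after collapsing);
    sample metadata is inherited from the source :class:`ExpressionDataset`.
    """

    dataset_id: str
    values: pd.DataFrame
    sample_group: pd.Series
    pairing: dict[str, str] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        self.sample_group = self.sample_group.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[int]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        if group not in SAMPLE_GROUPS:
            raise ConfigError(f"unknown group {group!r}")
        return list(self.sample_group[self.sample_group == group].index)


@dataclass
class ScreenConfig:
    """Thresholds and rules for the dual fold/frequency screen.

    fold_threshold
        Linear fold-change gate relative to the reference group; a tumor
        sample is called overexpressed at >= this ratio (inclusive).
    freq_threshold
        Minimum fraction of tumor samples called overexpressed (inclusive).
    min_datasets_rule
        How per-dataset passes combine into the "markedly overexpressed"
        flag: pass in every dataset where the gene is present
        (``all_present``), in more than half of them
        (``majority_present``, default), or recompute fold and frequency
        on all tumors pooled after per-dataset normalization (``pooled``).
    reference_stat
        Summary of the reference group's log2 values (mean or median).
    reference_group
        Which group anchors the fold change (normal_liver by default).
    require_dataset_fold
        The defining gate applies the fold threshold per patient, inside
        the frequency (a gene is overexpressed at >= fold_threshold in
        >= freq_threshold of tumors).  Set True to additionally require
        the dataset-level mean fold to clear fold_threshold.
    """

    fold_threshold: float = 2.0
    freq_threshold: float = 0.30
    min_datasets_rule: Literal["all_present", "majority_present", "pooled"] = "majority_present"
    require_dataset_fold: bool = False
    reference_stat: Literal["mean", "median"] = "mean"
    reference_group: Literal["normal_liver", "adjacent_nontumor"] = "normal_liver"
    test: Literal["student_equal_var"] = "student_equal_var"

    def __post_init__(self) -> None:
        if not self.fold_threshold > 0:
            raise ConfigError("fold_threshold must be > 0")
        if not (0 < self.freq_threshold <= 1):
            raise ConfigError("freq_threshold must be in (0, 1]")
        if self.min_datasets_rule not in ("all_present", "majority_present", "pooled"):
            raise ConfigError(f"unknown min_datasets_rule {self.min_datasets_rule!r}")
        if self.reference_stat not in ("mean", "median"):
            raise ConfigError(f"unknown reference_stat {self.reference_stat!r}")
        if self.reference_group not in ("normal_liver", "adjacent_nontumor"):
            raise ConfigError(f"unknown reference_group {self.reference_group!r}")


@dataclass
class ScreenResult:
    """Per-gene x per-dataset screen summaries plus the consensus flag.

    ``fold``, ``freq`` and ``p_value`` are genes x datasets frames with NA
    where a gene is absent from a dataset (``present`` False); ``passed``
    records the per-dataset dual-gate outcome and ``marked`` the
    cross-dataset "markedly overexpressed" flag under ``config``.
    """

    fold: pd.DataFrame
    freq: pd.DataFrame
    p_value: pd.DataFrame
    present: pd.DataFrame
    zero_variance: pd.DataFrame
    passed: pd.DataFrame
    marked: pd.Series
    config: ScreenConfig

    @property
    def genes(self) -> list[int]:
        return list(self.fold.index)

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.fold.columns)


# ---------------------------------------------------------------------------
# Probe-level matrix I/O
# ---------------------------------------------------------------------------

def _ingest_scale(values: pd.DataFrame, scale_flag: ScaleFlag) -> pd.DataFrame:
    if scale_flag == "log2":
        return values.astype(float)
    if scale_flag == "linear":
        v = values.astype(float)
        # background-corrected intensities can go nonpositive; treat as
        # missing rather than fabricating -inf
        v = v.where(v > 0)
        return np.log2(v)
    raise ConfigError(f"unknown scale_flag {scale_flag!r}")


def read_sample_metadata(path: str | Path) -> tuple[pd.Series, dict[str, str]]:
    """Read sample metadata TSV -> (group Series, pairing dict)."""
    meta = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=True)
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise FormatError(f"{path}: metadata needs columns sample_id, group")
    _check_unique(meta["sample_id"], "metadata sample ids")
    group = pd.Series(meta["group"].values, index=meta["sample_id"].values, name="group")
    pairing: dict[str, str] = {}
    if "pair_with" in meta.columns:
        for sid, grp, partner in zip(meta["sample_id"], meta["group"], meta["pair_with"]):
            if isinstance(partner, str) and partner:
                if grp == "tumor":
                    pairing[sid] = partner
                elif grp == "adjacent_nontumor":
                    pairing.setdefault(partner, sid)
                else:
                    raise PairingError(
                        f"sample {sid!r} with group {grp!r} cannot carry a pairing"
                    )
    return group, pairing


def read_expression_dataset(
    matrix_path: str | Path,
    metadata_path: str | Path,
    scale_flag: ScaleFlag = "log2",
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Read a probe x sample TSV matrix plus its sample metadata.

    Linear-scale input is log2-transformed on ingestion with nonpositive
    values set missing.  Every sample column in the matrix must appear in
    the metadata with a valid group label.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA"])
    _check_unique(raw.index, "probe ids")
    _check_unique(raw.columns, "sample ids")
    group, pairing = read_sample_metadata(metadata_path)
    missing = [s for s in raw.columns if s not in group.index]
    if missing:
        raise MetadataError(f"samples in matrix but not metadata: {missing}")
    values = _ingest_scale(raw, scale_flag)
    ds_id = dataset_id or Path(matrix_path).stem
    return ExpressionDataset(
        dataset_id=ds_id,
        values=values,
        sample_group=group.reindex(values.columns),
        pairing={t: a for t, a in pairing.items() if t in values.columns},
    )


def write_expression_dataset(
    ds: ExpressionDataset, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write the matrix and metadata TSVs read back by read_expression_dataset."""
    ds.values.to_csv(matrix_path, sep="\t", na_rep="NA", index_label="probe_id")
    inverse = {a: t for t, a in ds.pairing.items()}
    rows = []
    for sid in ds.sample_ids:
        partner = ds.pairing.get(sid, inverse.get(sid, ""))
        grp = ds.sample_group.get(sid)
        rows.append((sid, grp if isinstance(grp, str) else "NA", partner))
    pd.DataFrame(rows, columns=["sample_id", "group", "pair_with"]).to_csv(
        metadata_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Probe annotation
# ---------------------------------------------------------------------------

def read_probe_annotation(path: str | Path) -> dict[str, int]:
    """Read a two-column probe_id / entrez_id TSV into a probe -> gene map.

    Rows with blank/NA Entrez ids are dropped (unmapped probes); a probe
    listed twice with conflicting genes is an error, non-integer Entrez
    ids are a format error.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=True)
    if list(ann.columns[:2]) != ["probe_id", "entrez_id"]:
        raise FormatError(f"{path}: annotation needs columns probe_id, entrez_id")
    mapping: dict[str, int] = {}
    for probe, entrez in zip(ann["probe_id"], ann["entrez_id"]):
        if not isinstance(entrez, str) or entrez == "":
            continue
        try:
            gid = int(entrez)
        except ValueError:
            raise FormatError(f"non-integer entrez id {entrez!r} for probe {probe!r}")
        if gid <= 0:
            raise FormatError(f"entrez id must be positive, got {gid} for {probe!r}")
        if probe in mapping and mapping[probe] != gid:
            raise FormatError(
                f"probe {probe!r} maps to conflicting genes {mapping[probe]} and {gid}"
            )
        mapping[probe] = gid
    return mapping


def write_probe_annotation(mapping: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["probe_id", "entrez_id"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GEO series-matrix (read-only, offline)
# ---------------------------------------------------------------------------

_GEO_ACCESSION_RE = re.compile(r"^GSE\d+$", re.IGNORECASE)


def load_geo_series_matrix(
    accession_or_path: str | Path, scale_flag: ScaleFlag = "log2"
) -> ExpressionDataset:
    """Parse a local GEO series-matrix file into an ExpressionDataset.

    Sample groups are left unannotated for the caller to fill in (GEO
    metadata does not carry the tumor/normal assignment this analysis
    needs).  Passing a bare accession raises: network use is disabled.
    """
    p = Path(accession_or_path)
    if not p.exists():
        if _GEO_ACCESSION_RE.match(str(accession_or_path)):
            raise NetworkDisabledError(
                f"network disabled: cannot fetch {accession_or_path}; "
                "download the series-matrix file and pass its path"
            )
        raise FormatError(f"no such file: {accession_or_path}")
    lines = p.read_text().splitlines()
    try:
        begin = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")
        )
    except StopIteration:
        raise FormatError(f"{p}: missing !series_matrix_table_begin marker")
    try:
        end = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")
        )
    except StopIteration:
        raise FormatError(f"{p}: missing !series_matrix_table_end marker")
    table = lines[begin + 1 : end]
    if not table:
        raise FormatError(f"{p}: empty series-matrix table")
    rows = [[c.strip('"') for c in l.split("\t")] for l in table]
    header, body = rows[0], rows[1:]
    df = pd.DataFrame(body, columns=header).set_index(header[0])
    df = df.apply(pd.to_numeric, errors="coerce")
    values = _ingest_scale(df, scale_flag)
    accession = next(
        (l.split("\t")[1].strip('"') for l in lines if l.startswith("!Series_geo_accession")),
        p.stem,
    )
    group = pd.Series(pd.NA, index=values.columns, dtype=object, name="group")
    return ExpressionDataset(dataset_id=accession, values=values, sample_group=group)
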