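"""Normalization and probe-to-gene collapsing.

The pipeline order is fixed: log2 ingestion -> per-sample median
centering at probe level -> probe-to-gene collapsing by arithmetic mean
on the log2 scale (i.e. geometric mean of intensities).  Median
centering removes per-array loading offsets before probes are averaged;
no rescaling of spread is applied.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ConfigError,
    ExpressionDataset,
    GeneMatrix,
    ValidationError,
)

logger = logging.getLogger("mitoscreen")

__all__ = ["median_normalize", "collapse_probes", "subset_genes"]


def median_normalize(data: ExpressionDataset | GeneMatrix) -> ExpressionDataset | GeneMatrix:
    """Center each sample column at median 0 (over non-missing entries).

    Idempotent; missing entries are preserved.  A sample with no usable
    values cannot be centered and raises.
    """
    values = data.values
    all_missing = values.columns[values.isna().all(axis=0)]
    if len(all_missing):
        raise ValidationError(
            f"sample(s) with all values missing: {list(all_missing)}"
        )
    centered = values.sub(values.median(axis=0, skipna=True), axis=1)
    logger.info(
        "median_normalize[%s]: %d x %d", data.dataset_id, *centered.shape
    )
    if isinstance(data, GeneMatrix):
        return GeneMatrix(
            dataset_id=data.dataset_id,
            values=centered,
            sample_group=data.sample_group,
            pairing=dict(data.pairing),
            normalized=True,
        )
    return ExpressionDataset(
        dataset_id=data.dataset_id,
        values=centered,
        sample_group=data.sample_group,
        pairing=dict(data.pairing),
    )


def collapse_probes(
    dataset: ExpressionDataset, annotation: Mapping[str, int]
) -> GeneMatrix:
    """Average multi-probe signals into one log2 value per Entrez gene.

    Unmapped probes are dropped; per sample, the mean is taken over the
    gene's non-missing probe values.  Gene rows come out in ascending
    Entrez order.
    """
    mapped = [p for p in dataset.values.index if p in annotation]
    if not mapped:
        raise ValidationError(
            f"annotation maps none of the {len(dataset.values.index)} probes "
            f"in dataset {dataset.dataset_id!r}"
        )
    sub = dataset.values.loc[mapped]
    genes = pd.Index([annotation[p] for p in mapped], name="entrez_id")
    collapsed = sub.groupby(genes).mean().sort_index()
    logger.info(
        "collapse_probes[%s]: %d probes -> %d genes",
        dataset.dataset_id, len(mapped), len(collapsed),
    )
    return GeneMatrix(
        dataset_id=dataset.dataset_id,
        values=collapsed,
        sample_group=dataset.sample_group,
        pairing=dict(dataset.pairing),
    )


def subset_genes(gm: GeneMatrix, gene_list: Sequence[int]) -> GeneMatrix:
    """Restrict rows to the requested genes, preserving request order.

    Genes absent from the matrix get all-missing rows (reported as not
    present downstream); duplicate requests are de-duplicated with a
    logged warning.
    """
    if len(gene_list) == 0:
        raise ConfigError("empty gene request")
    seen: dict[int, None] = {}
    dupes = []
    for g in gene_list:
        if g in seen:
            dupes.append(g)
        seen[int(g)] = None
    if dupes:
        logger.warning("subset_genes: duplicate gene ids de-duplicated: %s", dupes)
    requested = pd.Index(list(seen), name=gm.values.index.name or "entrez_id")
    values = gm.values.reindex(requested)
    return GeneMatrix(
        dataset_id=gm.dataset_id,
        values=values,
        sample_group=gm.sample_group,
        pairing=dict(gm.pairing),
        normalized=gm.normalized,
    )
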