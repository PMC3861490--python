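"""Probe-level filtering and collapse to a gene-level matrix.

Three row-wise rules turn a raw probe matrix into one row per pathway-
mappable gene:

1. drop probes whose gene is not a member of any set in the collection;
2. drop probes whose interquartile range (IQR) across ALL samples (case
   and control pooled) is strictly below a threshold (default 0.5 log2
   units) — the standard nonspecific variance filter;
3. where several probes hit one gene, keep only the most variable one
   (largest IQR), re-keying the surviving row by the gene symbol.

Quantiles use linear interpolation between order statistics at positions
1 + (n-1)q; ties in the collapse step are broken by the lexicographically
smallest probe id so the output is deterministic.  The rules are row-
independent, so steps 1 and 2 commute; the composed order follows the
list above.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io_formats import ExpressionDataset, GeneSetCollection

__all__ = [
    "PreprocessParams",
    "probe_iqr",
    "filter_unmapped",
    "filter_low_iqr",
    "collapse_probes",
    "preprocess_dataset",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PreprocessParams:
    """iqr_threshold: probes with IQR strictly below it are removed;
    exactly-equal survives."""

    iqr_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.iqr_threshold < 0:
            raise ValueError("iqr_threshold must be >= 0")


def probe_iqr(values: pd.DataFrame) -> pd.Series:
    """Per-row IQR (Q3 - Q1, linear-interpolation quantiles) over all samples."""
    arr = values.to_numpy(dtype=float)
    q1, q3 = np.percentile(arr, [25, 75], axis=1, method="linear")
    return pd.Series(q3 - q1, index=values.index, name="iqr")


def filter_unmapped(
    dataset: ExpressionDataset, collection: GeneSetCollection
) -> ExpressionDataset:
    """Keep exactly the probes whose gene belongs to at least one set."""
    universe = collection.universe
    keep = [p for p in dataset.probe_ids if dataset.gene_of_probe[p] in universe]
    if not keep:
        raise ValueError(
            f"{dataset.dataset_id}: no mappable probes — no probe's gene "
            "occurs in any set of the collection"
        )
    return dataset.subset_probes(keep)


def filter_low_iqr(
    dataset: ExpressionDataset, params: PreprocessParams | None = None
) -> ExpressionDataset:
    """Remove probes with IQR < threshold (strict; equality survives)."""
    params = params or PreprocessParams()
    iqr = probe_iqr(dataset.values)
    keep = list(dataset.probe_ids[(iqr >= params.iqr_threshold).to_numpy()])
    # an empty survivor list is a legal intermediate state; the composed
    # pipeline errors later if nothing survives
    return dataset.subset_probes(keep)


def collapse_probes(dataset: ExpressionDataset) -> ExpressionDataset:
    """One row per gene: the probe with maximal IQR wins; ties go to the
    lexicographically smallest probe id.  Rows are re-keyed by gene symbol
    and sorted by it."""
    iqr = probe_iqr(dataset.values)
    table = pd.DataFrame(
        {
            "probe_id": dataset.probe_ids,
            "gene": dataset.gene_of_probe.to_numpy(),
            "iqr": iqr.to_numpy(),
        }
    )
    # max IQR first, then smallest probe_id; stable pick per gene
    table = table.sort_values(
        ["gene", "iqr", "probe_id"], ascending=[True, False, True]
    )
    winners = table.drop_duplicates("gene", keep="first")
    values = dataset.values.loc[winners["probe_id"]].copy()
    values.index = pd.Index(winners["gene"].to_numpy(), name="gene")
    return ExpressionDataset(
        dataset_id=dataset.dataset_id,
        values=values,
        gene_of_probe=pd.Series(values.index, index=values.index, name="gene"),
        group_of_sample=dataset.group_of_sample,
    )


def preprocess_dataset(
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    params: PreprocessParams | None = None,
    counts: dict[str, int] | None = None,
) -> ExpressionDataset:
    """Compose the three rules; idempotent on its own output.

    ``counts``, if given, receives the probe/gene counts after each step
    (keys: input_probes, mapped_probes, high_iqr_probes, genes).
    """
    params = params or PreprocessParams()
    n0 = len(dataset.probe_ids)
    mapped = filter_unmapped(dataset, collection)
    variable = filter_low_iqr(mapped, params)
    if len(variable.probe_ids) == 0:
        raise ValueError(
            f"{dataset.dataset_id}: no probes left after the IQR filter "
            f"(threshold {params.iqr_threshold})"
        )
    gene_level = collapse_probes(variable)
    step_counts = {
        "input_probes": n0,
        "mapped_probes": len(mapped.probe_ids),
        "high_iqr_probes": len(variable.probe_ids),
        "genes": len(gene_level.probe_ids),
    }
    if counts is not None:
        counts.update(step_counts)
    logger.info(
        "%s: %d probes -> %d mapped -> %d past IQR filter -> %d genes",
        dataset.dataset_id,
        *step_counts.values(),
    )
    return gene_level
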