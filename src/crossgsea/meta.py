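"""Gene-level cross-study meta-analysis by Fisher's combined probability.

Each dataset contributes a two-sided equal-variance Student t-test p-value
per gene (df = n1 + n2 - 2).  For a gene observed in k datasets the
p-values are combined as

    chi2 = sum_i (-2 * ln p_i),   chi2 ~ ChiSquare(df = 2k) under the null,

and the combined p is the upper tail of that chi-square.  A gene is
"selected" when its combined p falls below alpha (default 0.05) and it was
observed in at least k_min datasets (default 2 — platforms measure
different gene subsets, so requiring presence everywhere would discard
most of the universe).

An optional per-dataset pre-filter (keep only p_i < threshold before
combining) mirrors a common two-stage screening practice; it biases the
Fisher null towards small combined p-values and is therefore off by
default — the default is the statistically valid variant.

p-values are floored (default 1e-300) before taking logs so the statistic
stays finite.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .gsea import gene_t_statistics
from .io_formats import ExpressionDataset

__all__ = ["MetaGeneResult", "MetaResult", "per_gene_pvalues", "fisher_combine", "run_meta"]

P_FLOOR_DEFAULT = 1e-300


@dataclasses.dataclass(frozen=True)
class MetaGeneResult:
    gene: str
    per_dataset_p: dict[str, float]
    k: int
    chi2: float | None
    df: int | None
    combined_p: float | None
    selected: bool


@dataclasses.dataclass
class MetaResult:
    """Full meta-analysis output.

    ``table``: one row per gene; per-dataset p columns named
    ``p_<dataset_id>`` (NaN where the gene was not observed), then k, chi2,
    df, combined_p, selected.  ``selected_genes``: genes with
    combined_p < alpha and k >= k_min, in table order.
    """

    table: pd.DataFrame
    selected_genes: list[str]
    k_min: int
    alpha: float


def per_gene_pvalues(dataset: ExpressionDataset) -> pd.Series:
    """Two-sided p per gene from the equal-variance t (df = n1 + n2 - 2).

    Degenerate genes with zero pooled SD and equal means get p = 1; zero
    pooled SD with unequal means is dropped (with a warning) upstream in
    gene_t_statistics.
    """
    t = gene_t_statistics(dataset)
    df = dataset.n_case + dataset.n_control - 2
    p = 2.0 * stats.t.sf(np.abs(t.to_numpy()), df)
    return pd.Series(np.minimum(p, 1.0), index=t.index, name="p")


def fisher_combine(p_list) -> tuple[float, int, float]:
    """Fisher's method: chi2 = sum(-2 ln p_i), df = 2k, upper-tail p.

    Every p must lie in (0, 1]; a p of exactly 0 is rejected — the caller
    must floor first.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        bad = p[(p <= 0.0) | (p > 1.0)]
        raise ValueError(f"p-values must lie in (0, 1]; got {bad[:5]}")
    chi2 = float(np.sum(-2.0 * np.log(p)))
    df = 2 * p.size
    combined_p = float(stats.chi2.sf(chi2, df))
    return chi2, df, max(combined_p, 0.0)


def run_meta(
    datasets: list[ExpressionDataset],
    k_min: int = 2,
    alpha: float = 0.05,
    prefilter_p: float | None = None,
    p_floor: float = P_FLOOR_DEFAULT,
) -> MetaResult:
    """Combine per-gene p-values over the datasets in which each gene was
    observed (k = that count); genes with k < k_min are reported with an
    empty combined p and never selected.  ``prefilter_p`` keeps only
    per-dataset p-values strictly below the threshold before combining
    (screening variant; biases the null, off by default)."""
    if len(datasets) < 2:
        raise ValueError("meta-analysis needs at least 2 datasets")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if p_floor <= 0:
        raise ValueError("p_floor must be > 0")

    per_ds: dict[str, pd.Series] = {
        ds.dataset_id: per_gene_pvalues(ds) for ds in datasets
    }
    all_genes: list[str] = []
    seen: set[str] = set()
    for ds in datasets:
        for g in per_ds[ds.dataset_id].index:
            if g not in seen:
                seen.add(g)
                all_genes.append(g)

    rows = []
    selected_genes: list[str] = []
    for gene in all_genes:
        pvals: dict[str, float] = {}
        for ds_id, series in per_ds.items():
            if gene in series.index:
                pvals[ds_id] = float(series.loc[gene])
        contributing = {
            d: p
            for d, p in pvals.items()
            if prefilter_p is None or p < prefilter_p
        }
        k = len(contributing)
        row: dict[str, object] = {"gene": gene}
        for ds_id in per_ds:
            row[f"p_{ds_id}"] = pvals.get(ds_id, math.nan)
        row["k"] = k
        if k >= k_min:
            floored = [max(p, p_floor) for p in contributing.values()]
            chi2, df, combined_p = fisher_combine(floored)
            combined_p = max(combined_p, 0.0)
            selected = combined_p < alpha
            row.update(chi2=chi2, df=df, combined_p=combined_p, selected=selected)
            if selected:
                selected_genes.append(gene)
        else:
            row.update(chi2=math.nan, df=math.nan, combined_p=math.nan, selected=False)
        rows.append(row)

    table = pd.DataFrame(rows).set_index("gene")
    return MetaResult(
        table=table, selected_genes=selected_genes, k_min=k_min, alpha=alpha
    )
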