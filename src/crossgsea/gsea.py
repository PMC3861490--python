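"""Per-dataset gene-set analysis by mean t-statistic and label permutation.

For one preprocessed (gene-level) dataset:

* every gene gets an equal-variance two-sample Student t statistic
  t = (mean_case - mean_control) / (s_p * sqrt(1/n1 + 1/n2)), s_p the
  pooled standard deviation;
* every set is scored by the mean t over its member genes present in the
  dataset; sets with fewer than ``min_set_size`` present genes (default 10)
  are excluded;
* significance comes from shuffling the case/control labels (preserving
  group sizes) B times (default 1000): the same shuffles feed all sets, so
  inter-gene correlation is preserved and the permutation stream is shared.
  Directional p-values count ties and are add-one corrected,
      p_up   = (#{b : mean_t_b >= observed} + 1) / (B + 1),
      p_down = (#{b : mean_t_b <= observed} + 1) / (B + 1),
  so p in (0, 1] always and p_up + p_down >= 1;
* a set is called up if p_up <= alpha, down if p_down <= alpha (the
  smaller-p tail wins if both), ns otherwise.

Degenerate genes: pooled SD zero with equal group means gives t = 0; pooled
SD zero with unequal means is undefined and the gene is dropped with a
warning.  A gene dropped under a particular shuffled labeling is simply
absent from set means for that shuffle.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .io_formats import ExpressionDataset, GeneSetCollection

__all__ = [
    "GseaParams",
    "DatasetGseaResult",
    "gene_t_statistics",
    "set_scores",
    "permutation_test",
    "classify_sets",
]

logger = logging.getLogger(__name__)

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "ns"
CALL_EXCLUDED = "excluded"

_ZERO_SS_ATOL = 1e-12


@dataclasses.dataclass(frozen=True)
class GseaParams:
    n_permutations: int = 1000
    alpha: float = 0.05
    min_set_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")


@dataclasses.dataclass
class DatasetGseaResult:
    """Per-set GSEA outcome for one dataset.

    ``table`` is indexed by set name with columns n_genes (member genes
    present in the filtered dataset), mean_t (observed; NaN when no member
    gene is present), p_up, p_down (NaN for excluded sets) and call.
    """

    dataset_id: str
    table: pd.DataFrame
    n_permutations: int
    alpha: float
    min_set_size: int

    def calls(self) -> pd.Series:
        return self.table["call"]


def _t_from_groups(
    values: np.ndarray, case_cols: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Equal-variance t per row for one or many labelings.

    ``case_cols``: (n_samples, B) 0/1 indicator of case membership per
    labeling; returns (n_rows, B) t with NaN marking dropped rows (zero
    pooled SD, unequal means).
    """
    ctrl_cols = 1.0 - case_cols
    sum1 = values @ case_cols
    sum2 = values @ ctrl_cols
    mean1 = sum1 / n1
    mean2 = sum2 / n2
    sq = values**2
    ss1 = sq @ case_cols - n1 * mean1**2
    ss2 = sq @ ctrl_cols - n2 * mean2**2
    ss = np.maximum(ss1 + ss2, 0.0)  # clip tiny negative rounding
    scale = np.maximum(np.max(sq, axis=1, keepdims=True), 1.0)
    zero_ss = ss <= _ZERO_SS_ATOL * scale
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp = np.sqrt(ss / df)
        t = (mean1 - mean2) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    diff = mean1 - mean2
    same_mean = np.isclose(diff, 0.0, atol=1e-9 * np.sqrt(scale))
    t = np.where(zero_ss & same_mean, 0.0, t)
    t = np.where(zero_ss & ~same_mean, np.nan, t)
    return t


def gene_t_statistics(dataset: ExpressionDataset) -> pd.Series:
    """Observed per-gene t statistics for a gene-level dataset.

    Genes with zero pooled SD and unequal group means are dropped with a
    warning; zero pooled SD with equal means gives t = 0.
    """
    if dataset.n_case < 2 or dataset.n_control < 2:
        raise ValueError(
            f"{dataset.dataset_id}: need >=2 samples per group for a t-test"
        )
    case = dataset.case_mask().astype(float)[:, None]
    t = _t_from_groups(
        dataset.values.to_numpy(dtype=float), case, dataset.n_case, dataset.n_control
    )[:, 0]
    # keyed by gene symbol: the input is a gene-level matrix (one row per
    # gene after probe collapse)
    out = pd.Series(t, index=pd.Index(dataset.gene_of_probe.to_numpy(), name="gene"),
                    name="t")
    dropped = out.index[out.isna()]
    if len(dropped):
        warnings.warn(
            f"{dataset.dataset_id}: dropped {len(dropped)} gene(s) with zero "
            f"pooled SD but unequal group means: {list(dropped[:5])}...",
            stacklevel=2,
        )
        out = out.dropna()
    return out


@dataclasses.dataclass(frozen=True)
class SetScore:
    n_genes: int
    mean_t: float | None
    excluded: bool


def set_scores(
    t_map: pd.Series, collection: GeneSetCollection, min_set_size: int = 10
) -> dict[str, SetScore]:
    """Mean t over each set's member genes present in ``t_map``; sets with
    fewer than ``min_set_size`` present genes are marked excluded."""
    if len(t_map) == 0:
        raise ValueError("t_map is empty")
    out: dict[str, SetScore] = {}
    for s in collection:
        present = [g for g in s.members if g in t_map.index]
        n = len(present)
        mean_t = float(t_map.loc[present].mean()) if n else None
        out[s.name] = SetScore(n_genes=n, mean_t=mean_t, excluded=n < min_set_size)
    return out


def _membership_matrix(
    collection: GeneSetCollection, genes: pd.Index
) -> tuple[np.ndarray, list[str]]:
    """(n_sets, n_genes) 0/1 membership over the dataset's gene order."""
    pos = {g: i for i, g in enumerate(genes)}
    names = list(collection.names)
    m = np.zeros((len(names), len(genes)))
    for i, name in enumerate(names):
        for g in collection.members(name):
            j = pos.get(g)
            if j is not None:
                m[i, j] = 1.0
    return m, names


def permutation_test(
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    params: GseaParams | None = None,
) -> DatasetGseaResult:
    """Label-permutation GSEA on one preprocessed dataset (see module doc)."""
    from math import comb

    params = params or GseaParams()
    n1, n2 = dataset.n_case, dataset.n_control
    if comb(n1 + n2, n1) < 2:
        raise ValueError(
            f"{dataset.dataset_id}: fewer than 2 distinct label assignments"
        )

    t_obs = gene_t_statistics(dataset)
    scores = set_scores(t_obs, collection, params.min_set_size)

    gene_idx = pd.Index(dataset.gene_of_probe.to_numpy())
    keep = gene_idx.isin(t_obs.index)
    values = dataset.values.to_numpy(dtype=float)[keep]
    membership, set_names = _membership_matrix(collection, gene_idx[keep])

    n_samples = n1 + n2
    base_labels = dataset.case_mask().astype(float)
    rng = np.random.default_rng(params.seed)
    B = params.n_permutations
    perm_cols = np.empty((n_samples, B))
    for b in range(B):
        perm_cols[:, b] = base_labels[rng.permutation(n_samples)]

    # evaluate the observed labeling as column 0 of the very same batched
    # matrix computation as the permutations: identical columns then give
    # bit-identical set means, so a re-drawn observed labeling ties exactly
    all_cols = np.concatenate([base_labels[:, None], perm_cols], axis=1)
    t_all = _t_from_groups(values, all_cols, n1, n2)
    valid = ~np.isnan(t_all)
    sums = membership @ np.where(valid, t_all, 0.0)
    counts = membership @ valid.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = sums / counts  # NaN where a set loses all genes
    obs_means = means[:, 0]
    set_means = means[:, 1:]

    rows = []
    for i, name in enumerate(set_names):
        sc = scores[name]
        if sc.excluded:
            rows.append((name, sc.n_genes, sc.mean_t, np.nan, np.nan, CALL_EXCLUDED))
            continue
        obs = obs_means[i]
        perm = set_means[i]
        perm = perm[~np.isnan(perm)]
        n_ge = int(np.sum(perm >= obs))
        n_le = int(np.sum(perm <= obs))
        p_up = (n_ge + 1) / (B + 1)
        p_down = (n_le + 1) / (B + 1)
        if p_up <= params.alpha and (p_up <= p_down or p_down > params.alpha):
            call = CALL_UP
        elif p_down <= params.alpha:
            call = CALL_DOWN
        else:
            call = CALL_NS
        rows.append((name, sc.n_genes, obs, p_up, p_down, call))

    table = pd.DataFrame(
        rows, columns=["set", "n_genes", "mean_t", "p_up", "p_down", "call"]
    ).set_index("set")
    return DatasetGseaResult(
        dataset_id=dataset.dataset_id,
        table=table,
        n_permutations=B,
        alpha=params.alpha,
        min_set_size=params.min_set_size,
    )


def classify_sets(
    result: DatasetGseaResult, alpha: float | None = None
) -> tuple[list[str], list[str], list[str], list[str]]:
    """Partition set names into (up, down, ns, excluded) lists.

    Up/down/ns are sorted by the relevant p-value then name; excluded by
    name.  Passing ``alpha`` re-thresholds the stored p-values.
    """
    alpha = result.alpha if alpha is None else alpha
    up, down, ns, excluded = [], [], [], []
    for name, row in result.table.iterrows():
        if row["call"] == CALL_EXCLUDED:
            excluded.append((name,))
            continue
        p_up, p_down = row["p_up"], row["p_down"]
        if p_up <= alpha and (p_up <= p_down or p_down > alpha):
            up.append((p_up, name))
        elif p_down <= alpha:
            down.append((p_down, name))
        else:
            ns.append((min(p_up, p_down), name))
    return (
        [n for _, n in sorted(up)],
        [n for _, n in sorted(down)],
        [n for _, n in sorted(ns)],
        sorted(n for (n,) in excluded),
    )
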