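"""Over-representation analysis (ORA) of a gene list against a collection.

For each set, the overlap between the query list and the set's members
(both restricted to a background universe) is tested against the
hypergeometric upper tail: with background size M, set size K in the
background, list size N and overlap x,

    p_hyper = P(X >= x),   X ~ Hypergeometric(M, K, N).

The EASE variant — the conservative score popularised by the DAVID web
service — recomputes the tail after removing one gene from the observed
overlap (floored at zero), so p_ease >= p_hyper, with equality only at
x = 0.  EASE is the default, matching the convention of DAVID-style
functional annotation.

The natural background here is the union of genes that survived
preprocessing across all datasets (the meta-analysis's tested universe),
not the whole genome; it is an explicit argument.  Benjamini-Hochberg
adjusted values are available but off by default.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = ["EnrichmentRow", "ora_test", "enrich_all"]

METHOD_HYPER = "hyper"
METHOD_EASE = "ease"


@dataclasses.dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    n_list: int
    n_background: int
    n_set_in_background: int
    n_overlap: int
    p_hyper: float
    p_ease: float
    q: float | None = None


def _hyper_upper_tail(
    n_overlap: int, n_list: int, n_set_in_background: int, n_background: int
) -> float:
    p = float(
        stats.hypergeom.sf(
            n_overlap - 1, n_background, n_set_in_background, n_list
        )
    )
    return min(max(p, 0.0), 1.0)


def ora_test(
    n_overlap: int,
    n_list: int,
    n_set_in_background: int,
    n_background: int,
    method: str = METHOD_EASE,
) -> float:
    """Upper-tail over-representation p for one set.

    ``method='hyper'``: P(X >= n_overlap) for X hypergeometric with
    ``n_background`` total genes, ``n_set_in_background`` marked, and
    ``n_list`` drawn.  ``method='ease'``: the same tail evaluated at
    max(n_overlap - 1, 0).
    """
    if method not in (METHOD_HYPER, METHOD_EASE):
        raise ValueError(f"unknown method {method!r}; use 'hyper' or 'ease'")
    if n_background < 1:
        raise ValueError("n_background must be >= 1")
    for label, v, bound in (
        ("n_list", n_list, n_background),
        ("n_set_in_background", n_set_in_background, n_background),
    ):
        if not (0 <= v <= n_background):
            raise ValueError(f"{label}={v} must lie in 0..{n_background}")
    if not (0 <= n_overlap <= min(n_list, n_set_in_background)):
        raise ValueError(
            f"n_overlap={n_overlap} must lie in 0..min(n_list, "
            f"n_set_in_background)={min(n_list, n_set_in_background)}"
        )
    if n_overlap < n_list + n_set_in_background - n_background:
        raise ValueError(
            "n_overlap smaller than forced minimum "
            f"{n_list + n_set_in_background - n_background}"
        )
    x = n_overlap if method == METHOD_HYPER else max(n_overlap - 1, 0)
    return _hyper_upper_tail(x, n_list, n_set_in_background, n_background)


def enrich_all(
    gene_list: Sequence[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    method: str = METHOD_EASE,
    alpha: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """ORA of ``gene_list`` against every set with >=1 background member.

    Set membership and the list are both restricted to ``background``; a
    query gene absent from the background is an error naming it.  Rows are
    sorted ascending by the chosen method's p (ties by set name); columns
    follow EnrichmentRow, plus ``significant`` (chosen p < alpha) and, with
    ``bh=True``, a Benjamini-Hochberg ``q`` over the tested sets.
    """
    bg = set(background)
    genes = list(dict.fromkeys(gene_list))
    missing = [g for g in genes if g not in bg]
    if missing:
        raise ValueError(
            f"gene(s) in list absent from background: {missing[:10]}"
        )
    gene_set = set(genes)
    n_background = len(bg)
    n_list = len(genes)

    rows = []
    for s in collection:
        members_bg = [g for g in s.members if g in bg]
        if not members_bg:
            continue
        overlap = sum(1 for g in members_bg if g in gene_set)
        p_hyper = ora_test(overlap, n_list, len(members_bg), n_background, METHOD_HYPER)
        p_ease = ora_test(overlap, n_list, len(members_bg), n_background, METHOD_EASE)
        rows.append(
            {
                "set": s.name,
                "n_list": n_list,
                "n_background": n_background,
                "n_set_in_background": len(members_bg),
                "n_overlap": overlap,
                "p_hyper": p_hyper,
                "p_ease": p_ease,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "set",
            "n_list",
            "n_background",
            "n_set_in_background",
            "n_overlap",
            "p_hyper",
            "p_ease",
        ],
    )
    p_col = "p_hyper" if method == METHOD_HYPER else "p_ease"
    if method not in (METHOD_HYPER, METHOD_EASE):
        raise ValueError(f"unknown method {method!r}")
    if len(table):
        if bh:
            table["q"] = multipletests(table[p_col], method="fdr_bh")[1]
        table["significant"] = table[p_col] < alpha
        table = table.sort_values([p_col, "set"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        if bh:
            table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table
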