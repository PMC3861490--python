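"""Cross-study consensus of per-dataset gene-set calls.

A pathway reaches k-of-n consensus in a direction when at least k of the n
datasets call it in that direction.  A dataset where the set was excluded
(too few measured member genes) still counts in the denominator n — the
strict "coexists in all n datasets" reading — but cannot contribute a call.
A set called up somewhere and down somewhere else is flagged as a
direction conflict.
"""

from __future__ import annotations

import dataclasses
import math

import pandas as pd

from .gsea import CALL_DOWN, CALL_EXCLUDED, CALL_NS, CALL_UP, DatasetGseaResult

__all__ = ["ConsensusTable", "RecoveryReport", "build_consensus", "recover_planted"]


@dataclasses.dataclass
class ConsensusTable:
    """Per-set cross-dataset tallies.

    ``table`` is indexed by set name with columns n_datasets_tested, n_up,
    n_down, n_ns, n_excluded, consensus_up_at_<k> / consensus_down_at_<k>
    for each requested k, and conflict.
    """

    table: pd.DataFrame
    ks: tuple[int, ...]

    def consensus_sets(self, direction: str, k: int) -> list[str]:
        col = f"consensus_{direction}_at_{k}"
        return list(self.table.index[self.table[col]])


@dataclasses.dataclass(frozen=True)
class RecoveryReport:
    """How well consensus recovered the planted truth (synthetic runs)."""

    sensitivity_up: float
    sensitivity_down: float
    sensitivity: float
    false_consensus: int


def build_consensus(
    results: list[DatasetGseaResult], ks: list[int] | tuple[int, ...]
) -> ConsensusTable:
    """Tally up/down/ns/excluded calls per set across datasets and flag
    k-of-n consensus for every requested k."""
    if not results:
        raise ValueError("need at least one dataset result")
    n = len(results)
    ks = tuple(sorted(set(int(k) for k in ks)))
    for k in ks:
        if k < 1 or k > n:
            raise ValueError(f"consensus level k={k} out of range 1..{n} datasets")

    names: list[str] = []
    for r in results:
        for name in r.table.index:
            if name not in names:
                names.append(name)

    rows = []
    for name in names:
        counts = {CALL_UP: 0, CALL_DOWN: 0, CALL_NS: 0, CALL_EXCLUDED: 0}
        tested = 0
        for r in results:
            if name in r.table.index:
                tested += 1
                counts[r.table.loc[name, "call"]] += 1
        row = {
            "set": name,
            "n_datasets_tested": tested,
            "n_up": counts[CALL_UP],
            "n_down": counts[CALL_DOWN],
            "n_ns": counts[CALL_NS],
            "n_excluded": counts[CALL_EXCLUDED],
        }
        for k in ks:
            row[f"consensus_up_at_{k}"] = counts[CALL_UP] >= k
            row[f"consensus_down_at_{k}"] = counts[CALL_DOWN] >= k
        row["conflict"] = counts[CALL_UP] >= 1 and counts[CALL_DOWN] >= 1
        rows.append(row)
    table = pd.DataFrame(rows).set_index("set").sort_index()
    return ConsensusTable(table=table, ks=ks)


def recover_planted(
    consensus: ConsensusTable, truth: dict[str, str], k: int | None = None
) -> RecoveryReport:
    """Sensitivity per planted direction and false-consensus count among
    null sets, at consensus level ``k`` (default: the strictest level the
    table was built with)."""
    if k is None:
        k = max(consensus.ks)
    if k not in consensus.ks:
        raise ValueError(f"k={k} was not among the table's levels {consensus.ks}")
    up_col = f"consensus_up_at_{k}"
    down_col = f"consensus_down_at_{k}"
    t = consensus.table

    def _hit(name: str, col: str) -> bool:
        return name in t.index and bool(t.loc[name, col])

    planted_up = [s for s, d in truth.items() if d == "up"]
    planted_down = [s for s, d in truth.items() if d == "down"]
    nulls = [s for s, d in truth.items() if d == "null"]

    hits_up = sum(_hit(s, up_col) for s in planted_up)
    hits_down = sum(_hit(s, down_col) for s in planted_down)
    sens_up = hits_up / len(planted_up) if planted_up else math.nan
    sens_down = hits_down / len(planted_down) if planted_down else math.nan
    n_planted = len(planted_up) + len(planted_down)
    sens = (hits_up + hits_down) / n_planted if n_planted else math.nan
    false_consensus = sum(
        _hit(s, up_col) or _hit(s, down_col) for s in nulls
    )
    return RecoveryReport(
        sensitivity_up=sens_up,
        sensitivity_down=sens_down,
        sensitivity=sens,
        false_consensus=int(false_consensus),
    )
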