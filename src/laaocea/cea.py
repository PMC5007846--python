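"""Incremental cost-effectiveness analysis over a set of strategy outcomes.

Builds the ranked cost-effectiveness table: absolute dominance (costlier
and no more effective), extended dominance (a higher incremental
cost-effectiveness ratio than a more effective alternative), the efficiency
frontier with ICERs versus the next-best frontier member, and the pairwise
ICER matrix.  Also the net-monetary-benefit decision rule used by the
acceptability curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .markov import StrategyOutcome
from .parameters import DISPLAY_NAMES

__all__ = [
    "DominanceLabel",
    "IcerCode",
    "CEATable",
    "compute_icer",
    "icer_value",
    "efficiency_frontier",
    "net_monetary_benefit",
]


class DominanceLabel(str, Enum):
    ON_FRONTIER = "on_frontier"
    ABSOLUTELY_DOMINATED = "absolutely_dominated"
    EXTENDED_DOMINATED = "extended_dominated"


class IcerCode(str, Enum):
    """Non-numeric outcomes of an incremental comparison of a versus b."""

    DOMINANT = "dominant"        # a less costly and more effective than b
    DOMINATED = "dominated"      # a costlier and less effective than b
    COST_ONLY = "cost_only"      # equal QALYs: compare on cost alone


IcerResult = Union[float, IcerCode]


def icer_value(a: StrategyOutcome, b: StrategyOutcome) -> float:
    """Raw incremental ratio (cost_a - cost_b) / (qaly_a - qaly_b).

    Negative values are meaningful in one-way sweeps (one arm cheaper but
    less effective); infinite when the QALY difference is zero.
    """
    dq = a.qaly - b.qaly
    dc = a.cost - b.cost
    if dq == 0:
        return float(np.inf) if dc > 0 else (float(-np.inf) if dc < 0 else 0.0)
    return dc / dq


def compute_icer(a: StrategyOutcome, b: StrategyOutcome) -> IcerResult:
    """ICER of a versus b, or a dominance code where the ratio is not meaningful.

    Returns ``IcerCode.DOMINANT`` when a is less costly *and* more effective,
    ``IcerCode.DOMINATED`` for the reverse, ``IcerCode.COST_ONLY`` at equal
    QALYs, and the full-precision ratio otherwise (round for display).
    """
    dq = a.qaly - b.qaly
    dc = a.cost - b.cost
    if dq == 0:
        return IcerCode.COST_ONLY
    if dc < 0 and dq > 0:
        return IcerCode.DOMINANT
    if dc > 0 and dq < 0:
        return IcerCode.DOMINATED
    return dc / dq


def net_monetary_benefit(outcome: StrategyOutcome, wtp: float):
    """``wtp * QALYs - cost`` (broadcasts over a draw dimension)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * np.asarray(outcome.discounted_qaly) \
        - np.asarray(outcome.discounted_cost)


@dataclass
class CEATable:
    """All strategies ranked with dominance labels and frontier ICERs."""

    names: list[str]                       # sorted by ascending cost
    costs: dict[str, float]
    qalys: dict[str, float]
    labels: dict[str, DominanceLabel]
    frontier: list[str]                    # frontier members, ascending cost
    icer_vs_next_best: dict[str, float]    # frontier members after the first
    pairwise: dict[tuple[str, str], IcerResult]

    def frame(self) -> pd.DataFrame:
        rows = []
        for name in self.names:
            cost, qaly = self.costs[name], self.qalys[name]
            rows.append({
                "strategy": name,
                "display_name": DISPLAY_NAMES.get(name, name),
                "discounted_cost": cost,
                "discounted_qaly": qaly,
                "cost_per_qaly": cost / qaly if qaly else np.nan,
                "label": self.labels[name].value,
                "icer_vs_next_best": self.icer_vs_next_best.get(name, np.nan),
            })
        return pd.DataFrame(rows)

    def pairwise_frame(self) -> pd.DataFrame:
        """Pairwise ICER matrix; numeric entries rounded to whole dollars."""
        data = {}
        for col in self.names:
            column = {}
            for row in self.names:
                if row == col:
                    column[row] = "-"
                else:
                    res = self.pairwise[(row, col)]
                    column[row] = res.value if isinstance(res, IcerCode) \
                        else f"{res:,.0f}"
            data[col] = column
        return pd.DataFrame(data)


def _as_outcome_list(outcomes) -> list[StrategyOutcome]:
    if isinstance(outcomes, Mapping):
        return list(outcomes.values())
    return list(outcomes)


def efficiency_frontier(
        outcomes: Mapping[str, StrategyOutcome] | Sequence[StrategyOutcome],
) -> CEATable:
    """Rank strategies, mark dominance, and extract the efficiency frontier.

    Strategies are sorted by cost; absolutely dominated strategies
    (costlier, no more effective than some other strategy) are marked
    first; the remainder are swept in cost order, removing extended-dominated
    members (whose ICER versus the previous frontier member exceeds that of
    the next, more effective alternative) until the frontier's ICERs are
    strictly increasing.

    Equal-cost ties keep the higher-QALY strategy; exact cost-and-QALY ties
    are co-listed on the frontier.
    """
    outs = _as_outcome_list(outcomes)
    if len(outs) < 2:
        raise ValueError("frontier analysis needs at least two strategies")
    by_name = {o.strategy: o for o in outs}
    names = sorted(by_name, key=lambda n: (by_name[n].cost, -by_name[n].qaly))

    labels: dict[str, DominanceLabel] = {}
    for n in names:
        o = by_name[n]
        dominated = any(
            (p.cost <= o.cost and p.qaly > o.qaly)
            or (p.cost < o.cost and p.qaly >= o.qaly)
            for p in outs if p.strategy != n
        )
        if dominated:
            labels[n] = DominanceLabel.ABSOLUTELY_DOMINATED

    candidates = [n for n in names if n not in labels]
    frontier: list[str] = []
    for n in candidates:
        frontier.append(n)
        while len(frontier) >= 3:
            a, b, c = (by_name[x] for x in frontier[-3:])
            icer_cb = icer_value(c, b)
            icer_ba = icer_value(b, a)
            if icer_cb <= icer_ba:
                mid = frontier.pop(-2)
                labels[mid] = DominanceLabel.EXTENDED_DOMINATED
            else:
                break
    # co-listed exact ties survive as consecutive frontier members with the
    # same coordinates; drop neither
    for n in frontier:
        labels[n] = DominanceLabel.ON_FRONTIER

    icer_next: dict[str, float] = {}
    for prev, cur in zip(frontier, frontier[1:]):
        icer_next[cur] = icer_value(by_name[cur], by_name[prev])

    pairwise = {
        (r, c): compute_icer(by_name[r], by_name[c])
        for r in names for c in names if r != c
    }
    return CEATable(
        names=names,
        costs={n: by_name[n].cost for n in names},
        qalys={n: by_name[n].qaly for n in names},
        labels=labels,
        frontier=frontier,
        icer_vs_next_best=icer_next,
        pairwise=pairwise,
    )
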