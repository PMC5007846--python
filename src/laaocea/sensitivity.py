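"""One-way sweeps, tornado ranking, and the four published scenario axes.

Scenario axes: stroke risk by CHADS2 score (0-6), bleeding risk by
HAS-BLED score (0-5), time horizon (5/10/15/20 years), and the device
procedure cost.  Each scenario rebuilds a modified parameter book and
re-runs every strategy, so the base-case row of any sweep is bit-identical
to the unmodified base-case run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cea import IcerCode, compute_icer, icer_value
from .markov import StrategyOutcome, run_all_strategies, run_cohort
from .parameters import ModelConfig, ParameterBook, STRATEGY_ORDER

__all__ = [
    "CHADS2_STROKE_RATES",
    "HASBLED_HEM_RATES",
    "CHADS2_REFERENCE_RATE",
    "ScenarioTable",
    "TornadoEntry",
    "one_way",
    "tornado",
    "scenario_chads2",
    "scenario_hasbled",
    "scenario_horizon",
    "scenario_laao_cost",
]

#: Untreated annual ischemic stroke rate (%/yr) by CHADS2 score 0..6.
CHADS2_STROKE_RATES = (0.8, 2.2, 4.5, 8.6, 10.9, 12.3, 13.7)

#: Annual major-hemorrhage rate (%/yr) by HAS-BLED score 0..5.
HASBLED_HEM_RATES = (1.13, 1.02, 1.88, 3.74, 8.7, 12.5)

#: Reference untreated stroke rate dividing the CHADS2 per-score rates into
#: multiplicative factors on each arm's treated rate.  2.8 %/yr (the
#: aspirin-alone rate, between the score-1 and score-2 population rates)
#: places the base case between scores 1 and 2, matching the published
#: scenario tables' bracketing of the base-case results.
CHADS2_REFERENCE_RATE = 2.8

#: Anticoagulant-containing arms whose hemorrhage rates scale with HAS-BLED.
ANTICOAGULANT_ARMS = ("warfarin", "dabigatran_110", "dabigatran_150",
                      "apixaban", "rivaroxaban")


@dataclass
class ScenarioTable:
    """Per-strategy outcomes and device-arm ICERs along one scenario axis."""

    axis_name: str
    axis_values: list
    outcomes: dict                     # axis value -> {strategy: StrategyOutcome}
    icers: dict                        # axis value -> {strategy: float | IcerCode}

    def frame(self) -> pd.DataFrame:
        rows = []
        for val in self.axis_values:
            for name, o in self.outcomes[val].items():
                icer = self.icers[val].get(name)
                rows.append({
                    self.axis_name: val,
                    "strategy": name,
                    "discounted_cost": o.cost,
                    "discounted_qaly": o.qaly,
                    "laao_icer_vs_strategy": (
                        icer.value if isinstance(icer, IcerCode) else icer),
                })
        return pd.DataFrame(rows)


@dataclass
class TornadoEntry:
    """ICER swing of the device-vs-comparator comparison for one parameter."""

    param_id: str
    low: float
    high: float
    icer_low: float
    icer_high: float
    crosses_threshold: bool

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _laao_icers(outcomes: dict[str, StrategyOutcome]) -> dict:
    laao = outcomes["laao"]
    return {name: compute_icer(laao, o)
            for name, o in outcomes.items() if name != "laao"}


def _scenario(book_for, axis_name: str, axis_values: Sequence,
              config: Optional[ModelConfig] = None) -> ScenarioTable:
    outcomes, icers = {}, {}
    for val in axis_values:
        book = book_for(val)
        outs = run_all_strategies(book, config)
        outcomes[val] = outs
        icers[val] = _laao_icers(outs)
    return ScenarioTable(axis_name, list(axis_values), outcomes, icers)


# ---------------------------------------------------------------------------
# one-way sweeps / tornado
# ---------------------------------------------------------------------------

def one_way(book: ParameterBook, param_id: str,
            low: Optional[float] = None, high: Optional[float] = None,
            comparator: str = "warfarin") -> tuple[float, float]:
    """Device-vs-comparator ICERs with one parameter at its low/high bound.

    Everything else stays at base.  Returns the raw incremental ratios
    (negative values are meaningful: the device arm may be cheaper but less
    effective at an extreme).  Bounds default to the parameter's published
    range.
    """
    pr = book.get_param(param_id)   # raises KeyError for unknown ids
    low = pr.low if low is None else low
    high = pr.high if high is None else high
    results = []
    for bound in (low, high):
        b = book.copy()
        b.set_base(param_id, bound)
        laao = run_cohort(b.strategies["laao"], b)
        comp = run_cohort(b.strategies[comparator], b)
        results.append(icer_value(laao, comp))
    return results[0], results[1]


def tornado(book: ParameterBook, param_ids: Optional[Sequence[str]] = None,
            comparator: str = "warfarin",
            threshold: Optional[float] = None) -> list[TornadoEntry]:
    """One-way sweep of every ranged parameter, sorted by bar width.

    ``param_ids`` defaults to every book entry with a non-degenerate range.
    Entries whose ICER range crosses the willingness-to-pay threshold are
    flagged.
    """
    if param_ids is None:
        param_ids = [pid for pid, pr in book.walk() if pr.low < pr.high]
    if not param_ids:
        raise ValueError("tornado needs at least one parameter")
    threshold = book.config.wtp_threshold if threshold is None else threshold
    entries = []
    for pid in param_ids:
        pr = book.get_param(pid)
        icer_lo, icer_hi = one_way(book, pid, comparator=comparator)
        lo, hi = sorted((icer_lo, icer_hi))
        entries.append(TornadoEntry(
            param_id=pid, low=pr.low, high=pr.high,
            icer_low=icer_lo, icer_high=icer_hi,
            crosses_threshold=(lo <= threshold <= hi),
        ))
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.param_id,
        "param_low": e.low,
        "param_high": e.high,
        "icer_at_low": e.icer_low,
        "icer_at_high": e.icer_high,
        "width": e.width,
        "crosses_threshold": e.crosses_threshold,
    } for e in entries])


# ---------------------------------------------------------------------------
# published scenario axes
# ---------------------------------------------------------------------------

def scenario_chads2(book: ParameterBook,
                    scores: Sequence[int] = range(7)) -> ScenarioTable:
    """Stroke risk varied by CHADS2 score.

    The published per-score rates are untreated-population stroke rates;
    each strategy's treated stroke rate is scaled by
    ``chads_rate(score) / CHADS2_REFERENCE_RATE``.
    """
    for s in scores:
        if not 0 <= s <= 6:
            raise ValueError(f"CHADS2 score {s} outside 0..6")

    def book_for(score: int) -> ParameterBook:
        factor = CHADS2_STROKE_RATES[score] / CHADS2_REFERENCE_RATE
        b = book.copy()
        for strat in b.strategies.values():
            for rates in (strat.rates, strat.first_year_rates):
                if rates is not None:
                    rates.stroke.base = rates.stroke.base * factor
        return b

    return _scenario(book_for, "chads2_score", list(scores))


def scenario_hasbled(book: ParameterBook,
                     scores: Sequence[int] = range(6)) -> ScenarioTable:
    """Bleeding risk varied by HAS-BLED score.

    Major-hemorrhage, intracranial-hemorrhage and fatal-hemorrhage rates of
    the anticoagulant-containing arms (and the first post-implant year of
    the device arm) are scaled by the ratio of the per-score rate to the
    warfarin base major-hemorrhage rate; antiplatelet arms are untouched,
    as are minor-hemorrhage rates.
    """
    for s in scores:
        if not 0 <= s <= 5:
            raise ValueError(f"HAS-BLED score {s} outside 0..5")
    ref = book.strategies["warfarin"].rates.major_hem.base

    def book_for(score: int) -> ParameterBook:
        factor = HASBLED_HEM_RATES[score] / ref
        b = book.copy()
        for name in ANTICOAGULANT_ARMS:
            if name not in b.strategies:
                continue
            rates = b.strategies[name].rates
            for field_name in ("major_hem", "ich", "fatal_hem"):
                pr = getattr(rates, field_name)
                pr.base = pr.base * factor
        laao = b.strategies.get("laao")
        if laao is not None and laao.first_year_rates is not None:
            for field_name in ("major_hem", "ich", "fatal_hem"):
                pr = getattr(laao.first_year_rates, field_name)
                pr.base = pr.base * factor
        return b

    return _scenario(book_for, "hasbled_score", list(scores))


def scenario_horizon(book: ParameterBook,
                     horizons: Sequence[int] = (5, 10, 15, 20)) -> ScenarioTable:
    """Time horizon truncated to the given cycle counts."""
    for h in horizons:
        if h < 1:
            raise ValueError(f"horizon {h} must be >= 1")
    outcomes, icers = {}, {}
    for h in horizons:
        config = replace(book.config, horizon_cycles=int(h))
        outs = run_all_strategies(book, config)
        outcomes[h] = outs
        icers[h] = _laao_icers(outs)
    return ScenarioTable("horizon_years", list(horizons), outcomes, icers)


def scenario_laao_cost(book: ParameterBook,
                       costs: Optional[Sequence[float]] = None) -> ScenarioTable:
    """Device procedure+device cost replaced; only the device arm changes."""
    if costs is None:
        pr = book.strategies["laao"].laao_extras.total_cost
        costs = (pr.low, pr.base, pr.high)
    for c in costs:
        if c <= 0:
            raise ValueError(f"device cost {c} must be positive")

    def book_for(cost: float) -> ParameterBook:
        b = book.copy()
        b.strategies["laao"].laao_extras.total_cost.base = float(cost)
        return b

    return _scenario(book_for, "laao_cost", list(costs))
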