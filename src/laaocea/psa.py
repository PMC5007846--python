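"""Probabilistic sensitivity analysis and cost-effectiveness acceptability.

Each Monte-Carlo draw samples one complete parameter book (beta draws for
probabilities and utilities, gamma for costs) and evaluates all eight
strategies on that same book, so within-draw comparisons share common
parameters.  The optimal strategy per draw at a willingness-to-pay
threshold maximizes net monetary benefit; the acceptability curve is the
fraction of draws each strategy is optimal across a threshold grid.

Draw ``i`` is seeded by ``(master_seed, i)``, so any draw is reproducible
in isolation and the whole analysis is reproducible from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .markov import run_all_strategies
from .parameters import ParameterBook, fit_distributions
from .synthetic_data import random_book

__all__ = ["PsaDraw", "CEACCurve", "PsaResult", "run_psa",
           "probability_cost_effective", "default_wtp_grid"]


def default_wtp_grid() -> np.ndarray:
    """$0 to $150,000 in $5,000 steps (includes the $50,000 threshold)."""
    return np.arange(0.0, 150_000.0 + 1.0, 5_000.0)


@dataclass
class PsaDraw:
    """One Monte-Carlo draw: seed-reproducible per-strategy (cost, QALY)."""

    index: int
    outcomes: dict[str, tuple[float, float]]


@dataclass
class CEACCurve:
    """Probability each strategy is optimal as a function of willingness-to-pay."""

    wtp: np.ndarray                     # (n_wtp,)
    strategies: list[str]
    probabilities: np.ndarray           # (n_wtp, n_strategies), rows sum to 1

    def probability(self, strategy: str, wtp: float) -> float:
        j = self.strategies.index(strategy)
        i = np.flatnonzero(np.isclose(self.wtp, wtp))
        if i.size == 0:
            raise ValueError(f"wtp {wtp} not on the curve grid")
        return float(self.probabilities[i[0], j])

    def frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.probabilities, columns=self.strategies)
        frame.insert(0, "wtp", self.wtp)
        return frame


@dataclass
class PsaResult:
    """All draw-level outcomes plus the acceptability curve."""

    master_seed: int
    n_draws: int
    strategies: list[str]
    costs: np.ndarray                   # (n_strategies, n_draws)
    qalys: np.ndarray                   # (n_strategies, n_draws)
    ceac: CEACCurve
    draws: list[PsaDraw] = field(repr=False, default_factory=list)

    def draws_frame(self) -> pd.DataFrame:
        """Per-draw (cost, QALY) pairs for cost-effectiveness-plane plots."""
        cols: dict[str, np.ndarray] = {"draw": np.arange(self.n_draws)}
        for j, name in enumerate(self.strategies):
            cols[f"{name}_cost"] = self.costs[j]
            cols[f"{name}_qaly"] = self.qalys[j]
        return pd.DataFrame(cols)

    def optimal_share(self, wtp: float) -> dict[str, float]:
        """Fraction of draws each strategy maximizes NMB at ``wtp``."""
        share = _optimal_share(self.costs, self.qalys, wtp)
        return dict(zip(self.strategies, share))

    def probability_pairwise_acceptable(self, strategy: str, comparator: str,
                                        wtp: float) -> float:
        """Secondary statistic: share of draws where the strategy's pairwise
        incremental comparison against one comparator is acceptable at
        ``wtp`` (equivalently, where its pairwise incremental net monetary
        benefit is non-negative)."""
        i = self.strategies.index(strategy)
        j = self.strategies.index(comparator)
        dc = self.costs[i] - self.costs[j]
        dq = self.qalys[i] - self.qalys[j]
        return float(np.mean(wtp * dq - dc >= 0.0))


def _optimal_share(costs: np.ndarray, qalys: np.ndarray, wtp: float) -> np.ndarray:
    """Per-strategy probability of maximal NMB; exact ties split equally."""
    nmb = wtp * qalys - costs                    # (n_strategies, n_draws)
    best = nmb.max(axis=0, keepdims=True)
    is_best = nmb == best
    credit = is_best / is_best.sum(axis=0, keepdims=True)
    return credit.mean(axis=1)


def _stacked_book(base: ParameterBook, values: dict[str, np.ndarray]) -> ParameterBook:
    book = base.copy()
    for pid, arr in values.items():
        pr = book.get_param(pid)
        pr.base = arr
        pr.low = arr
        pr.high = arr
    return book


def run_psa(book: Optional[ParameterBook] = None, n_draws: int = 10_000,
            master_seed: int = 0,
            wtp_grid: Optional[Sequence[float]] = None,
            keep_draw_objects: bool = False) -> PsaResult:
    """Monte-Carlo propagation of parameter uncertainty.

    Samples ``n_draws`` parameter books (draw ``i`` seeded by
    ``(master_seed, i)``, matching :func:`laaocea.random_book`), evaluates
    every strategy on each book through the vectorized cohort engine, and
    builds the acceptability curve over ``wtp_grid``.
    """
    from .synthetic_data import canonical_book
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    base = book if book is not None else canonical_book()
    dists = fit_distributions(base)
    if not dists:
        raise ValueError("no fitted distributions for this book")
    wtp = np.asarray(wtp_grid if wtp_grid is not None else default_wtp_grid(),
                     dtype=float)

    pids = [pid for pid, _ in base.walk()]
    values = {pid: np.empty(n_draws) for pid in pids}
    for i in range(n_draws):
        rng = np.random.default_rng(np.random.SeedSequence((master_seed, i)))
        for pid in pids:
            values[pid][i] = dists[pid].sample(rng)

    stacked = _stacked_book(base, values)
    outcomes = run_all_strategies(stacked)
    names = list(outcomes)
    costs = np.stack([np.asarray(outcomes[n].discounted_cost) for n in names])
    qalys = np.stack([np.asarray(outcomes[n].discounted_qaly) for n in names])

    probs = np.stack([_optimal_share(costs, qalys, w) for w in wtp])
    ceac = CEACCurve(wtp=wtp, strategies=names, probabilities=probs)

    draws = []
    if keep_draw_objects:
        draws = [PsaDraw(i, {n: (float(costs[j, i]), float(qalys[j, i]))
                             for j, n in enumerate(names)})
                 for i in range(n_draws)]
    return PsaResult(master_seed=master_seed, n_draws=n_draws, strategies=names,
                     costs=costs, qalys=qalys, ceac=ceac, draws=draws)


def probability_cost_effective(result: PsaResult, strategy: str,
                               wtp: float) -> float:
    """Fraction of draws where ``strategy`` maximizes net monetary benefit
    at ``wtp`` (exact ties split equally)."""
    if result.n_draws < 1:
        raise ValueError("no draws")
    return result.optimal_share(wtp)[strategy]
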