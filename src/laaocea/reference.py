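"""Published reference results of the analysis this package re-implements.

These are the reported lifetime totals, scenario ICERs and probabilistic
headline of the original published model.  They serve two purposes: the
incremental-analysis layer can be exercised directly on the reported
cost/QALY pairs (the ICER arithmetic and dominance structure are exactly
reproducible from them), and the cohort engine's structural calibration is
scored against them (see docs/calibration.md).  They are *reference data*,
never model inputs.
"""

from __future__ import annotations

from .markov import StrategyOutcome

__all__ = [
    "REPORTED_BASE_CASE",
    "REPORTED_ICERS",
    "REPORTED_FRONTIER",
    "REPORTED_EXTENDED_DOMINATED",
    "REPORTED_ABSOLUTELY_DOMINATED",
    "REPORTED_5Y_ICER_VS_WARFARIN",
    "REPORTED_PSA_LAAO_PROBABILITY",
    "reported_outcomes",
]

#: Reported total discounted lifetime cost (US$) and QALYs per strategy.
REPORTED_BASE_CASE: dict[str, tuple[float, float]] = {
    "aspirin": (12_877.0, 6.12),
    "clopidogrel_aspirin": (26_287.0, 6.29),
    "warfarin": (28_090.0, 9.45),
    "laao": (37_789.0, 10.99),
    "dabigatran_110": (42_712.0, 8.76),
    "dabigatran_150": (43_946.0, 9.00),
    "rivaroxaban": (51_064.0, 9.86),
    "apixaban": (53_315.0, 9.40),
}

#: Reported whole-dollar ICERs for selected pairs (a versus b).
REPORTED_ICERS: dict[tuple[str, str], int] = {
    ("laao", "aspirin"): 5_115,
    ("laao", "clopidogrel_aspirin"): 2_447,
    ("laao", "warfarin"): 6_298,
    ("dabigatran_150", "dabigatran_110"): 5_142,
    ("apixaban", "dabigatran_110"): 16_567,
}

REPORTED_FRONTIER = ["aspirin", "warfarin", "laao"]
REPORTED_EXTENDED_DOMINATED = ["clopidogrel_aspirin"]
REPORTED_ABSOLUTELY_DOMINATED = [
    "dabigatran_110", "dabigatran_150", "rivaroxaban", "apixaban",
]

#: Device versus warfarin at a 5-year horizon (US$/QALY).
REPORTED_5Y_ICER_VS_WARFARIN = 74_422.0

#: Probability the device arm is optimal at $50,000/QALY (10,000 draws), %.
REPORTED_PSA_LAAO_PROBABILITY = 86.24


def reported_outcomes() -> dict[str, StrategyOutcome]:
    """The reported cost/QALY pairs wrapped as outcome objects (no trace)."""
    return {
        name: StrategyOutcome(strategy=name, discounted_cost=cost,
                              discounted_qaly=qaly, life_years=float("nan"))
        for name, (cost, qaly) in REPORTED_BASE_CASE.items()
    }
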