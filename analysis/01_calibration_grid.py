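"""Structural calibration of the cohort engine against the published totals.

The transition topology behind the published model is under-specified, so
the engine exposes a small set of structural switches (mortality
composition, accrual timing, death-cost and stroke-hospitalization
charging, INR-visit frequency, transient-disutility duration, device-cost
branch).  This driver scores every combination against the published
anchors -- per-strategy lifetime cost within ±10 % and QALYs within ±0.5,
plus the 5-year device-vs-warfarin ICER within ±15 % -- and reports the
ranking.  The frozen package defaults are the margin-maximizing
combination that also passes the qualitative scenario patterns (the
margin-tied runner-up fails NOAC dominance in the high-stroke-risk
scenarios); see docs/calibration.md.

Writes results/calibration_grid.csv.
"""

import dataclasses
import itertools
from pathlib import Path

import pandas as pd

import laaocea as L
from laaocea.parameters import ModelConfig
from laaocea.reference import REPORTED_5Y_ICER_VS_WARFARIN, REPORTED_BASE_CASE

OUT = Path(__file__).resolve().parent.parent / "results"

GRID = {
    "mortality_mode": ["background_plus_vascular", "additive_fatal"],
    "accrual": ["start", "half_cycle"],
    "death_cost_mode": ["none", "background"],
    "inr_visits_per_year": [12.0, 24.0, 26.0],
    "event_disutility_days": [0.0, 30.0, 60.0, 90.0, 365.0],
    "device_cost_branches": ["success_only", "both"],
    "charge_stroke_hospitalization": [True, False],
}


def score(book) -> tuple[float, float]:
    """Worst-case margin (1 = perfect, <0 = outside a band) and 5-y ICER."""
    errs = []
    outs = L.run_all_strategies(book)
    for name, (ref_cost, ref_qaly) in REPORTED_BASE_CASE.items():
        errs.append(abs(outs[name].cost / ref_cost - 1.0) / 0.10)
        errs.append(abs(outs[name].qaly - ref_qaly) / 0.5)
    cfg5 = dataclasses.replace(book.config, horizon_cycles=5)
    w5 = L.run_cohort(book.strategies["warfarin"], book, cfg5)
    l5 = L.run_cohort(book.strategies["laao"], book, cfg5)
    icer5 = (l5.cost - w5.cost) / (l5.qaly - w5.qaly)
    errs.append(abs(icer5 / REPORTED_5Y_ICER_VS_WARFARIN - 1.0) / 0.15)
    return 1.0 - max(errs), icer5


def main() -> None:
    OUT.mkdir(exist_ok=True)
    base = L.canonical_book()
    rows = []
    for combo in itertools.product(*GRID.values()):
        settings = dict(zip(GRID, combo))
        book = base.copy()
        book.config = dataclasses.replace(base.config, **settings)
        margin, icer5 = score(book)
        rows.append({**settings, "worst_case_margin": margin, "icer_5y": icer5})
    frame = pd.DataFrame(rows).sort_values("worst_case_margin", ascending=False)
    frame.to_csv(OUT / "calibration_grid.csv", index=False)

    print(f"{len(frame)} structural configurations scored; top 5 by margin:")
    print(frame.head(5).to_string(index=False))

    defaults = {k: getattr(ModelConfig(), k) for k in GRID}
    frozen = frame[(frame[list(GRID)] == pd.Series(defaults)).all(axis=1)]
    print("\nFrozen package defaults score:")
    print(frozen.to_string(index=False))
    print("\nThe frozen defaults are the top-ranked configuration that also "
          "passes the qualitative scenario patterns (NOAC dominance across "
          "all stroke-risk scores); the margin-tied runner-up does not.")


if __name__ == "__main__":
    main()
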