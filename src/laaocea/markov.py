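"""Yearly-cycle Markov cohort engine for one strategy and one parameter book.

A cohort starts entirely in the well state at age 65 and moves between
eight health states each one-year cycle:

======================  =====================================================
state                   meaning
======================  =====================================================
``WELL``                atrial fibrillation, no prior modelled event
``POST_MILD_STROKE``    survived ischemic stroke, mild sequelae
``POST_MOD_SEV_STROKE`` survived ischemic stroke, moderate-to-severe sequelae
``POST_ICH``            survived intracranial hemorrhage
``POST_MI``             survived myocardial infarction
``POST_TIA``            prior transient ischemic attack
``DEAD_VASCULAR``       death from vascular cause or fatal modelled event
``DEAD_OTHER``          death from other (background) causes
======================  =====================================================

All living states face the same annual event rates (recurrent events are
allowed, with no post-event rate escalation).  Minor and major hemorrhage
are transient: they cost money and a short utility decrement but do not
move the cohort.  Fatal stroke (the fatal fraction of the severity split)
and fatal hemorrhage flow to ``DEAD_VASCULAR``.

Mortality composition (structural switch, see ``ModelConfig``): in the
calibrated default ``background_plus_vascular`` the total annual death
probability is the printed all-cause rate plus the printed vascular-death
rate, with fatal-event flows routed to ``DEAD_VASCULAR`` but debited from
the all-cause flow (they are taken as already counted there).  The
``additive_fatal`` variant adds fatal-event flows on top.

Every arithmetic path broadcasts over a leading draw dimension, so a
10,000-draw probabilistic sensitivity analysis runs through the same code
as a single base-case evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np
import pandas as pd

from .parameters import (
    DAYS_PER_YEAR,
    ModelConfig,
    ParameterBook,
    StrategySpec,
)

__all__ = [
    "HealthState",
    "N_STATES",
    "StrategyOutcome",
    "rate_to_probability",
    "build_cycle_transitions",
    "run_cohort",
    "run_all_strategies",
    "closed_form_no_event_value",
]


class HealthState(IntEnum):
    WELL = 0
    POST_MILD_STROKE = 1
    POST_MOD_SEV_STROKE = 2
    POST_ICH = 3
    POST_MI = 4
    POST_TIA = 5
    DEAD_VASCULAR = 6
    DEAD_OTHER = 7


N_STATES = len(HealthState)
_LIVING = slice(0, 6)
_MASS_TOL = 1e-10


def rate_to_probability(rate: float | np.ndarray, mode: str = "direct"):
    """Convert an annual rate in %/yr to a per-cycle probability.

    ``direct`` (default): rate/100 clamped to [0, 1].  ``exponential``:
    ``1 - exp(-rate/100)``, the constant-hazard conversion.  At the rate
    magnitudes in this model the two differ by well under one part in fifty.
    """
    r = np.asarray(rate, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative annual rate")
    if mode == "direct":
        return np.clip(r / 100.0, 0.0, 1.0)
    if mode == "exponential":
        return 1.0 - np.exp(-r / 100.0)
    raise ValueError(f"unknown rate conversion mode {mode!r}")


def _mix_fractions(mix) -> dict[str, np.ndarray]:
    raw = {k: np.asarray(getattr(mix, k).base, dtype=float)
           for k in ("fatal", "mod_severe", "mild", "none")}
    total = sum(raw.values())
    if np.any(total <= 0):
        # all-zero mix (e.g. a no-event degenerate book): no strokes happen,
        # the split is immaterial
        return {k: np.zeros_like(v) for k, v in raw.items()}
    return {k: v / total for k, v in raw.items()}


def _cycle_components(strategy: StrategySpec, book: ParameterBook,
                      config: ModelConfig, first_year: bool) -> dict:
    """Per-cycle event probabilities and flows for one arm."""
    rates = strategy.rates
    if first_year and strategy.first_year_rates is not None:
        rates = strategy.first_year_rates
    conv = config.rate_conversion
    p = {
        "stroke": rate_to_probability(rates.stroke.base, conv),
        "minor_hem": rate_to_probability(rates.minor_hem.base, conv),
        "major_hem": rate_to_probability(rates.major_hem.base, conv),
        "ich": rate_to_probability(rates.ich.base, conv),
        "fatal_hem": rate_to_probability(rates.fatal_hem.base, conv),
        "mi": rate_to_probability(rates.mi.base, conv),
        "all_cause": rate_to_probability(rates.all_cause_death.base, conv),
        "vascular": (rate_to_probability(rates.vascular_death.base, conv)
                     if rates.vascular_death is not None else np.asarray(0.0)),
    }
    mix = _mix_fractions(book.severity_mixes[strategy.severity_class])
    p["stroke_fatal"] = p["stroke"] * mix["fatal"]
    p["stroke_mod_severe"] = p["stroke"] * mix["mod_severe"]
    p["stroke_mild"] = p["stroke"] * mix["mild"]
    p["stroke_none"] = p["stroke"] * mix["none"]

    ts = np.asarray(book.tia_share.base, dtype=float) / 100.0
    ts = np.clip(ts, 0.0, 0.999)
    p["tia"] = p["stroke"] * ts / (1.0 - ts)

    fatal_events = p["stroke_fatal"] + p["fatal_hem"]
    if config.mortality_mode == "additive_fatal":
        p["death_vascular"] = p["vascular"] + fatal_events
        p["death_other"] = p["all_cause"]
    else:  # background_plus_vascular: fatal events debit the all-cause flow
        p["death_vascular"] = p["vascular"] + fatal_events
        p["death_other"] = np.maximum(p["all_cause"] - fatal_events, 0.0)
    return p


def _transition_matrix(p: dict, cycle_index: int,
                       strategy_name: str) -> np.ndarray:
    moves = {
        HealthState.POST_MOD_SEV_STROKE: p["stroke_mod_severe"],
        HealthState.POST_MILD_STROKE: p["stroke_mild"],
        HealthState.POST_ICH: p["ich"],
        HealthState.POST_MI: p["mi"],
        HealthState.POST_TIA: p["tia"],
        HealthState.DEAD_VASCULAR: p["death_vascular"],
        HealthState.DEAD_OTHER: p["death_other"],
    }
    total_out = sum(np.asarray(v, dtype=float) for v in moves.values())
    if np.any(total_out > 1.0 + 1e-12):
        raise ValueError(
            f"competing event probabilities exceed 1 for strategy "
            f"{strategy_name!r} at cycle {cycle_index} "
            f"(max {float(np.max(total_out)):.4f})")
    batch = np.broadcast(total_out).shape
    P = np.zeros(batch + (N_STATES, N_STATES))
    remain = 1.0 - total_out
    for s in range(_LIVING.stop):
        P[..., s, s] += remain
        for dest, prob in moves.items():
            P[..., s, int(dest)] += prob
    P[..., HealthState.DEAD_VASCULAR, HealthState.DEAD_VASCULAR] = 1.0
    P[..., HealthState.DEAD_OTHER, HealthState.DEAD_OTHER] = 1.0
    return P


def build_cycle_transitions(strategy: StrategySpec, cycle_index: int,
                            book: ParameterBook,
                            config: Optional[ModelConfig] = None) -> np.ndarray:
    """The (8, 8) per-state outgoing probability table for one cycle.

    Row ``i`` gives the distribution over next-cycle states for a cohort
    member currently in state ``i``; every row sums to 1 (residual mass
    remains in state).  For the device arm the first-year regimen rates
    apply iff ``cycle_index == 0``.
    """
    config = config or book.config
    p = _cycle_components(strategy, book, config, first_year=(cycle_index == 0))
    return _transition_matrix(p, cycle_index, strategy.name)


def _state_utilities(strategy: StrategySpec, book: ParameterBook) -> np.ndarray:
    """Utility weight per living state, broadcast over draws.

    Post-event states use ``min(baseline, sequela utility)``; the ICH state
    reuses the moderate-to-severe stroke weight (no ICH utility is
    published); the TIA state carries the baseline weight.
    """
    u_base = np.asarray(strategy.utility.base, dtype=float)
    u = book.utilities
    per_state = [
        u_base,
        np.minimum(u_base, np.asarray(u.mild_stroke.base, dtype=float)),
        np.minimum(u_base, np.asarray(u.mod_severe_stroke.base, dtype=float)),
        np.minimum(u_base, np.asarray(u.mod_severe_stroke.base, dtype=float)),
        np.minimum(u_base, np.asarray(u.mi.base, dtype=float)),
        u_base,
    ]
    return np.stack(np.broadcast_arrays(*per_state), axis=-1)


def _drug_and_monitoring(strategy: StrategySpec, book: ParameterBook,
                         config: ModelConfig, first_year: bool) -> np.ndarray:
    """Per-living-person annual drug + monitoring cost for one cycle."""
    inr_cost = np.asarray(book.costs.inr_visit.base, dtype=float)
    if strategy.is_laao:
        ex = strategy.laao_extras
        if first_year:
            # 45 d warfarin + 180 d clopidogrel/aspirin + aspirin, pro-rata,
            # with INR monitoring while on warfarin
            asa_days = DAYS_PER_YEAR - ex.warfarin_days - ex.dual_days
            try:
                c_warf = np.asarray(
                    book.strategies["warfarin"].annual_drug_cost.base, dtype=float)
                c_dual = np.asarray(
                    book.strategies["clopidogrel_aspirin"].annual_drug_cost.base,
                    dtype=float)
                c_asa = np.asarray(
                    book.strategies["aspirin"].annual_drug_cost.base, dtype=float)
            except KeyError:
                c_warf = c_dual = c_asa = np.asarray(
                    strategy.annual_drug_cost.base, dtype=float)
            drug = (ex.warfarin_days * c_warf + ex.dual_days * c_dual
                    + asa_days * c_asa) / DAYS_PER_YEAR
            inr = (ex.warfarin_days / DAYS_PER_YEAR) \
                * config.inr_visits_per_year * inr_cost
            return drug + inr
        if "aspirin" in book.strategies:
            return np.asarray(book.strategies["aspirin"].annual_drug_cost.base,
                              dtype=float)
        return np.asarray(strategy.annual_drug_cost.base, dtype=float)
    cost = np.asarray(strategy.annual_drug_cost.base, dtype=float)
    if strategy.inr_monitoring:
        cost = cost + config.inr_visits_per_year * inr_cost
    return cost


@dataclass
class StrategyOutcome:
    """Discounted lifetime cost and QALYs for one strategy (plus the trace).

    ``discounted_cost`` / ``discounted_qaly`` are scalars for a base-case
    run and arrays over draws for a vectorized run.  ``trace`` maps
    ``occupancy`` to a ``(cycles, ..., states)`` array and each event name
    to its per-cycle cohort incidence, with per-cycle undiscounted cost and
    utility under ``cycle_cost`` / ``cycle_utility``.
    """

    strategy: str
    discounted_cost: np.ndarray
    discounted_qaly: np.ndarray
    life_years: np.ndarray
    trace: dict = field(default_factory=dict, repr=False)

    @property
    def cost(self) -> float:
        return float(np.asarray(self.discounted_cost).reshape(-1)[0]) \
            if np.asarray(self.discounted_cost).size == 1 else self.discounted_cost

    @property
    def qaly(self) -> float:
        return float(np.asarray(self.discounted_qaly).reshape(-1)[0]) \
            if np.asarray(self.discounted_qaly).size == 1 else self.discounted_qaly

    def trace_frame(self) -> pd.DataFrame:
        """Scalar-run trace as a tidy per-cycle DataFrame (CSV-exportable)."""
        occ = np.asarray(self.trace["occupancy"])
        if occ.ndim != 2:
            raise ValueError("trace_frame is only available for scalar runs")
        frame = pd.DataFrame(occ, columns=[s.name.lower() for s in HealthState])
        frame.insert(0, "cycle", np.arange(len(frame)))
        for key in ("stroke_mild", "stroke_mod_severe", "stroke_fatal", "tia",
                    "minor_hem", "major_hem", "ich", "fatal_hem", "mi",
                    "deaths", "cycle_cost", "cycle_utility", "discount"):
            frame[key] = np.asarray(self.trace[key])
        return frame


def _run_single_arm(strategy: StrategySpec, book: ParameterBook,
                    config: ModelConfig) -> StrategyOutcome:
    T = config.horizon_cycles
    d = config.discount_rate

    comp_first = _cycle_components(strategy, book, config, first_year=True)
    comp_rest = _cycle_components(strategy, book, config, first_year=False)
    P_first = _transition_matrix(comp_first, 0, strategy.name)
    P_rest = _transition_matrix(comp_rest, 1, strategy.name) if T > 1 else None

    batch = P_first.shape[:-2]
    occ = np.zeros(batch + (N_STATES,))
    occ[..., HealthState.WELL] = 1.0

    u_states = _state_utilities(strategy, book)
    costs = book.costs
    lt = {
        HealthState.POST_MOD_SEV_STROKE: np.asarray(
            costs.long_term["mod_severe_stroke"].base, dtype=float),
        HealthState.POST_MILD_STROKE: np.asarray(
            costs.long_term["mild_stroke"].base, dtype=float),
        HealthState.POST_TIA: np.asarray(costs.long_term["tia"].base, dtype=float),
        HealthState.POST_ICH: np.asarray(costs.long_term["ich"].base, dtype=float),
    }
    event_u = {
        "minor_hem": np.asarray(book.utilities.minor_hem.base, dtype=float),
        "major_hem": np.asarray(book.utilities.major_hem.base, dtype=float),
        "mi": np.asarray(book.utilities.mi.base, dtype=float),
    }
    ev_dur = config.event_disutility_days / DAYS_PER_YEAR

    total_cost = np.zeros(batch)
    total_qaly = np.zeros(batch)
    life_years = np.zeros(batch)
    trace: dict[str, list] = {k: [] for k in (
        "occupancy", "stroke_mild", "stroke_mod_severe", "stroke_fatal", "tia",
        "minor_hem", "major_hem", "ich", "fatal_hem", "mi", "deaths",
        "cycle_cost", "cycle_utility", "discount")}

    for t in range(T):
        first = (t == 0)
        p = comp_first if first else comp_rest
        P = P_first if first else P_rest
        occ_living = occ[..., _LIVING]
        A = occ_living.sum(axis=-1)

        # state-membership accrual (utility, drug, long-term sequela costs)
        U_state = np.einsum("...s,...s->...", occ_living, u_states)
        drug = _drug_and_monitoring(strategy, book, config, first)
        C_state = A * drug
        for state, lt_cost in lt.items():
            C_state = C_state + occ[..., int(state)] * lt_cost

        # transient event-cycle utility decrement, pro-rated by duration
        dU = np.zeros(batch)
        for ev in ("minor_hem", "major_hem", "mi"):
            delta = np.minimum(event_u[ev][..., None], u_states) - u_states
            dU = dU + p[ev] * np.einsum("...s,...s->...", occ_living, delta) * ev_dur

        # per-event costs on this cycle's incidence
        C_event = A * (
            p["minor_hem"] * np.asarray(costs.minor_bleed.base, dtype=float)
            + p["major_hem"] * np.asarray(costs.major_bleed.base, dtype=float)
            + p["ich"] * np.asarray(costs.short_term["ich"].base, dtype=float)
            + p["mi"] * np.asarray(costs.mi.base, dtype=float)
            + p["stroke_mod_severe"] * np.asarray(
                costs.short_term["mod_severe_stroke"].base, dtype=float)
            + p["stroke_mild"] * np.asarray(
                costs.short_term["mild_stroke"].base, dtype=float)
            + p["tia"] * np.asarray(costs.short_term["tia"].base, dtype=float)
        )
        if config.charge_stroke_hospitalization:
            C_event = C_event + A * p["stroke_mod_severe"] * np.asarray(
                costs.hosp_stroke.base, dtype=float)
        death_cost = np.asarray(costs.death_nonstroke.base, dtype=float)
        if config.death_cost_mode == "background":
            C_event = C_event + A * p["death_other"] * death_cost
        elif config.death_cost_mode == "all":
            C_event = C_event + A * (p["death_other"] + p["death_vascular"]) \
                * death_cost

        occ_next = np.einsum("...s,...st->...t", occ, P)
        mass = occ_next.sum(axis=-1)
        if np.any(np.abs(mass - 1.0) > _MASS_TOL):
            raise AssertionError("cohort mass not conserved")

        df_start = (1.0 + d) ** (-t)
        df_end = (1.0 + d) ** (-(t + 1))
        if config.accrual == "start":
            U_acc = U_state * df_start
            C_cont = C_state * df_start
        elif config.accrual == "end":
            occ_next_living = occ_next[..., _LIVING]
            U_acc = np.einsum("...s,...s->...", occ_next_living, u_states) * df_end
            A_end = occ_next_living.sum(axis=-1)
            C_cont = (A_end * drug) * df_end
            for state, lt_cost in lt.items():
                C_cont = C_cont + occ_next[..., int(state)] * lt_cost * df_end
        else:  # half_cycle: average of the two accrual conventions
            occ_next_living = occ_next[..., _LIVING]
            U_end = np.einsum("...s,...s->...", occ_next_living, u_states)
            A_end = occ_next_living.sum(axis=-1)
            C_end = A_end * drug
            for state, lt_cost in lt.items():
                C_end = C_end + occ_next[..., int(state)] * lt_cost
            U_acc = 0.5 * (U_state * df_start + U_end * df_end)
            C_cont = 0.5 * (C_state * df_start + C_end * df_end)

        cycle_cost = C_cont + C_event * df_start  # events discounted at cycle start
        cycle_qaly = U_acc + dU * df_start

        total_cost = total_cost + cycle_cost
        total_qaly = total_qaly + cycle_qaly
        life_years = life_years + A

        deaths = A * (p["death_other"] + p["death_vascular"])
        trace["occupancy"].append(occ.copy())
        trace["stroke_mild"].append(A * p["stroke_mild"])
        trace["stroke_mod_severe"].append(A * p["stroke_mod_severe"])
        trace["stroke_fatal"].append(A * p["stroke_fatal"])
        trace["tia"].append(A * p["tia"])
        trace["minor_hem"].append(A * p["minor_hem"])
        trace["major_hem"].append(A * p["major_hem"])
        trace["ich"].append(A * p["ich"])
        trace["fatal_hem"].append(A * p["fatal_hem"])
        trace["mi"].append(A * p["mi"])
        trace["deaths"].append(deaths)
        trace["cycle_cost"].append(C_state + C_event)
        trace["cycle_utility"].append(U_state + dU)
        trace["discount"].append(np.broadcast_to(df_start, batch).copy())

        occ = occ_next

    trace_arrays = {}
    for k, vs in trace.items():
        shape = batch + (N_STATES,) if k == "occupancy" else batch
        trace_arrays[k] = np.stack(
            [np.broadcast_to(np.asarray(v), shape) for v in vs], axis=0)
    return StrategyOutcome(
        strategy=strategy.name,
        discounted_cost=total_cost if batch else float(total_cost),
        discounted_qaly=total_qaly if batch else float(total_qaly),
        life_years=life_years if batch else float(life_years),
        trace=trace_arrays,
    )


def _laao_one_off_costs(strategy: StrategySpec, book: ParameterBook,
                        config: ModelConfig, branch: str):
    """Cycle-0 procedure costs for one branch of the implant mixture."""
    ex = strategy.laao_extras
    tee = np.asarray(book.costs.tee.base, dtype=float) * ex.tee_exams
    peric = np.asarray(ex.pericardial_effusion.base, dtype=float) / 100.0 \
        * np.asarray(book.costs.hosp_pericardial.base, dtype=float)
    device = np.asarray(ex.total_cost.base, dtype=float)
    if config.device_cost_branches == "success_only" and branch == "failure":
        device = np.zeros_like(device)
    return device + tee + peric


def run_cohort(strategy: StrategySpec, book: ParameterBook,
               config: Optional[ModelConfig] = None) -> StrategyOutcome:
    """Run the cohort model for one strategy.

    For the device arm the result is the implant-success mixture: with
    probability ``implant_success`` the cohort follows the occlusion branch
    (first-year regimen rates, then lifelong aspirin rates) and otherwise
    it continues on warfarin; procedure, echocardiography and
    pericardial-effusion costs are charged to cycle 0 (device cost per the
    ``device_cost_branches`` switch).  Deterministic: identical inputs give
    bit-identical outputs.
    """
    config = config or book.config
    config.validate()
    if not strategy.is_laao:
        return _run_single_arm(strategy, book, config)

    if "warfarin" not in book.strategies:
        raise ValueError("device arm requires a warfarin strategy as the "
                         "failed-implant branch")
    success = _run_single_arm(strategy, book, config)
    failure = _run_single_arm(book.strategies["warfarin"], book, config)
    s = np.asarray(strategy.laao_extras.implant_success.base, dtype=float)

    cost_a = success.discounted_cost + _laao_one_off_costs(
        strategy, book, config, "success")
    cost_b = failure.discounted_cost + _laao_one_off_costs(
        strategy, book, config, "failure")
    cost = s * cost_a + (1.0 - s) * cost_b
    qaly = s * success.discounted_qaly + (1.0 - s) * failure.discounted_qaly
    ly = s * success.life_years + (1.0 - s) * failure.life_years

    trace = {}
    for key in success.trace:
        a, b = success.trace[key], failure.trace[key]
        if key == "discount":
            trace[key] = a
        else:
            w = np.asarray(s)[..., None] if key == "occupancy" else np.asarray(s)
            trace[key] = w * a + (1.0 - w) * b
    batch = np.asarray(s).shape or np.asarray(success.discounted_cost).shape
    scalar = np.asarray(cost).ndim == 0
    return StrategyOutcome(
        strategy=strategy.name,
        discounted_cost=float(cost) if scalar else cost,
        discounted_qaly=float(qaly) if scalar else qaly,
        life_years=float(ly) if scalar else ly,
        trace=trace,
    )


def run_all_strategies(book: ParameterBook,
                       config: Optional[ModelConfig] = None,
                       ) -> dict[str, StrategyOutcome]:
    """Run every strategy in the book against the same parameter set."""
    from .parameters import STRATEGY_ORDER
    order = [s for s in STRATEGY_ORDER if s in book.strategies]
    order += [s for s in book.strategies if s not in order]
    return {name: run_cohort(book.strategies[name], book, config)
            for name in order}


def closed_form_no_event_value(u: float, m: float, d: float, T: int) -> float:
    """Analytic discounted QALYs for a no-event cohort (start-cycle accrual).

    ``u * sum_{t=0}^{T-1} (1-m)^t (1+d)^{-t}`` -- the annuity a cohort with
    constant total annual death probability ``m``, baseline utility ``u``
    and discount rate ``d`` accrues over ``T`` one-year cycles.
    """
    if not (0.0 <= m <= 1.0):
        raise ValueError("m must be a probability")
    if d < 0:
        raise ValueError("d must be >= 0")
    q = (1.0 - m) / (1.0 + d)
    if abs(q - 1.0) < 1e-15:
        return u * T
    return u * (1.0 - q ** T) / (1.0 - q)
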