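"""Typed parameter book for the stroke-prophylaxis decision model.

The model compares transcatheter left atrial appendage occlusion (LAAO)
against seven antithrombotic drug strategies in non-valvular atrial
fibrillation.  Every model input -- annual clinical event rates, stroke
severity splits, health-state utilities and US$ costs -- lives in a
:class:`ParameterBook`, loaded from a YAML "book" whose canonical content
transcribes the published base-case values and ranges.

Each scalar input is a :class:`ParamRange` ``(base, low, high)``; the range
is interpreted as a 95 % interval when fitting probabilistic-sensitivity
distributions (beta for probabilities and utilities, gamma for costs).
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "ParamRange",
    "EventRates",
    "SeverityMix",
    "UtilitySet",
    "CostSet",
    "LaaoExtras",
    "StrategySpec",
    "ModelConfig",
    "ParameterBook",
    "DistributionSpec",
    "BookValidationError",
    "load_parameter_book",
    "save_parameter_book",
    "validate_book",
    "beta_from_mean_range",
    "gamma_from_mean_range",
    "pro_rata_first_year_rate",
    "fit_distributions",
    "STRATEGY_ORDER",
    "DISPLAY_NAMES",
]

#: Canonical strategy keys, cheapest-drug first (display order).
STRATEGY_ORDER = (
    "aspirin",
    "clopidogrel_aspirin",
    "warfarin",
    "dabigatran_110",
    "dabigatran_150",
    "apixaban",
    "rivaroxaban",
    "laao",
)

DISPLAY_NAMES = {
    "aspirin": "Aspirin",
    "clopidogrel_aspirin": "Clopidogrel + aspirin",
    "warfarin": "Warfarin",
    "dabigatran_110": "Dabigatran 110 mg",
    "dabigatran_150": "Dabigatran 150 mg",
    "apixaban": "Apixaban",
    "rivaroxaban": "Rivaroxaban",
    "laao": "LAA occlusion",
}

# Days in the phased post-implant drug regimen (warfarin, then dual
# antiplatelet therapy, then aspirin for the remainder of the year).
DAYS_PER_YEAR = 365


class BookValidationError(ValueError):
    """A parameter book failed a hard validation check."""


@dataclass
class ParamRange:
    """A base-case value with its published (low, high) range."""

    base: float
    low: float
    high: float

    @classmethod
    def point(cls, value: float) -> "ParamRange":
        return cls(value, value, value)

    def as_tuple(self) -> list[float]:
        return [self.base, self.low, self.high]


@dataclass
class EventRates:
    """Annual event rates for one strategy, each in %/yr."""

    stroke: ParamRange
    minor_hem: ParamRange
    major_hem: ParamRange
    ich: ParamRange
    fatal_hem: ParamRange
    mi: ParamRange
    all_cause_death: ParamRange
    vascular_death: Optional[ParamRange] = None
    hospitalization: Optional[ParamRange] = None


@dataclass
class SeverityMix:
    """Ischemic-stroke severity split (% of strokes) for one drug class."""

    fatal: ParamRange
    mod_severe: ParamRange
    mild: ParamRange
    none: ParamRange

    def fractions(self) -> dict[str, float]:
        """Severity fractions renormalized to sum exactly to 1.

        The published antiplatelet split sums to 99.9 %, so proportional
        renormalization is applied unconditionally: the engine requires
        probability mass conservation.
        """
        raw = {f.name: getattr(self, f.name).base for f in fields(self)}
        total = sum(raw.values())
        return {k: v / total for k, v in raw.items()}


@dataclass
class UtilitySet:
    """Health-state utilities shared across strategies (fractions in [0,1])."""

    mild_stroke: ParamRange
    mod_severe_stroke: ParamRange
    mi: ParamRange
    minor_hem: ParamRange
    major_hem: ParamRange


@dataclass
class CostSet:
    """Event and monitoring costs in US$ (per event, per visit or per year)."""

    inr_visit: ParamRange
    short_term: dict[str, ParamRange]  # mod_severe_stroke, mild_stroke, tia, ich
    long_term: dict[str, ParamRange]   # same keys, $/yr while in the state
    tee: ParamRange
    major_bleed: ParamRange
    minor_bleed: ParamRange
    death_nonstroke: ParamRange
    mi: ParamRange
    hosp_stroke: ParamRange
    hosp_pericardial: ParamRange


@dataclass
class LaaoExtras:
    """One-off device-arm inputs: implant mixture and procedure events."""

    implant_success: ParamRange        # fraction of implants allowing warfarin stop
    pericardial_effusion: ParamRange   # % with serious effusion within 7 days
    total_cost: ParamRange             # procedure + device, US$
    warfarin_days: int = 45
    dual_days: int = 180
    tee_exams: int = 2


@dataclass
class StrategySpec:
    """One treatment arm of the model."""

    name: str
    severity_class: str                 # 'antiplatelet' | 'anticoagulant'
    rates: EventRates
    utility: ParamRange
    annual_drug_cost: ParamRange
    first_year_rates: Optional[EventRates] = None
    inr_monitoring: bool = False
    laao_extras: Optional[LaaoExtras] = None

    @property
    def is_laao(self) -> bool:
        return self.laao_extras is not None


@dataclass
class ModelConfig:
    """Run settings: cohort, discounting, and the structural switches.

    The structural switches (accrual timing, mortality composition, rate
    conversion, one-off cost charging, INR-visit frequency, transient-event
    disutility duration, device-cost branch) form the documented calibration
    surface of the model; the defaults below are the frozen calibrated
    values (see docs/calibration.md).
    """

    start_age: float = 65.0
    horizon_cycles: int = 20
    cycle_length_years: float = 1.0
    discount_rate: float = 0.03
    wtp_threshold: float = 50_000.0

    # -- structural switches (calibration surface) --------------------------
    rate_conversion: str = "direct"              # 'direct' | 'exponential'
    accrual: str = "start"                       # 'start' | 'end' | 'half_cycle'
    mortality_mode: str = "background_plus_vascular"  # | 'additive_fatal'
    death_cost_mode: str = "background"          # 'none' | 'background' | 'all'
    charge_stroke_hospitalization: bool = False
    inr_visits_per_year: float = 26.0
    event_disutility_days: float = 90.0
    device_cost_branches: str = "success_only"   # | 'both'

    def validate(self) -> None:
        if self.horizon_cycles < 1:
            raise BookValidationError("horizon_cycles must be >= 1")
        if self.discount_rate < 0:
            raise BookValidationError("discount_rate must be >= 0")
        if self.rate_conversion not in ("direct", "exponential"):
            raise BookValidationError(f"unknown rate_conversion {self.rate_conversion!r}")
        if self.accrual not in ("start", "end", "half_cycle"):
            raise BookValidationError(f"unknown accrual {self.accrual!r}")
        if self.mortality_mode not in ("background_plus_vascular", "additive_fatal"):
            raise BookValidationError(f"unknown mortality_mode {self.mortality_mode!r}")
        if self.death_cost_mode not in ("none", "background", "all"):
            raise BookValidationError(f"unknown death_cost_mode {self.death_cost_mode!r}")
        if self.device_cost_branches not in ("success_only", "both"):
            raise BookValidationError(
                f"unknown device_cost_branches {self.device_cost_branches!r}"
            )


@dataclass
class ParameterBook:
    """All model inputs: strategies, severity mixes, utilities, costs."""

    strategies: dict[str, StrategySpec]
    severity_mixes: dict[str, SeverityMix]
    utilities: UtilitySet
    costs: CostSet
    tia_share: ParamRange              # % of neurological ischemic events
    config: ModelConfig = field(default_factory=ModelConfig)
    validation_warnings: list[str] = field(default_factory=list, compare=False)

    # -- parameter addressing ------------------------------------------------

    def walk(self) -> Iterator[tuple[str, ParamRange]]:
        """Yield every (parameter id, ParamRange) in a stable order."""
        yield "tia_share", self.tia_share
        for cls_name, mix in self.severity_mixes.items():
            for f in fields(mix):
                yield f"severity_mixes.{cls_name}.{f.name}", getattr(mix, f.name)
        for f in fields(self.utilities):
            yield f"utilities.{f.name}", getattr(self.utilities, f.name)
        for f in fields(self.costs):
            value = getattr(self.costs, f.name)
            if isinstance(value, dict):
                for key, pr in value.items():
                    yield f"costs.{f.name}.{key}", pr
            else:
                yield f"costs.{f.name}", value
        for name in STRATEGY_ORDER:
            if name not in self.strategies:
                continue
            strat = self.strategies[name]
            for group, rates in (("rates", strat.rates),
                                 ("first_year_rates", strat.first_year_rates)):
                if rates is None:
                    continue
                for f in fields(rates):
                    pr = getattr(rates, f.name)
                    if pr is not None:
                        yield f"strategies.{name}.{group}.{f.name}", pr
            yield f"strategies.{name}.utility", strat.utility
            yield f"strategies.{name}.annual_drug_cost", strat.annual_drug_cost
            if strat.laao_extras is not None:
                ex = strat.laao_extras
                yield f"strategies.{name}.laao_extras.implant_success", ex.implant_success
                yield f"strategies.{name}.laao_extras.pericardial_effusion", ex.pericardial_effusion
                yield f"strategies.{name}.laao_extras.total_cost", ex.total_cost

    def get_param(self, param_id: str) -> ParamRange:
        obj: object = self
        for part in param_id.split("."):
            if isinstance(obj, dict):
                try:
                    obj = obj[part]
                except KeyError:
                    raise KeyError(f"unknown parameter id {param_id!r}") from None
            else:
                try:
                    obj = getattr(obj, part)
                except AttributeError:
                    raise KeyError(f"unknown parameter id {param_id!r}") from None
            if obj is None:
                raise KeyError(f"unknown parameter id {param_id!r}")
        if not isinstance(obj, ParamRange):
            raise KeyError(f"{param_id!r} does not address a parameter")
        return obj

    def set_base(self, param_id: str, value: float) -> None:
        """Overwrite the base-case value of one parameter in place."""
        self.get_param(param_id).base = float(value)

    def copy(self) -> "ParameterBook":
        return copy.deepcopy(self)

    # -- serialization -------------------------------------------------------

    def to_mapping(self) -> dict:
        def rates_map(rates: EventRates) -> dict:
            out = {}
            for f in fields(rates):
                pr = getattr(rates, f.name)
                if pr is not None:
                    out[f.name] = pr.as_tuple()
            return out

        m: dict = {
            "model": {
                "start_age": self.config.start_age,
                "horizon_cycles": self.config.horizon_cycles,
                "cycle_length_years": self.config.cycle_length_years,
                "discount_rate": self.config.discount_rate,
                "wtp_threshold": self.config.wtp_threshold,
            },
            "tia_share": self.tia_share.as_tuple(),
            "severity_mixes": {
                cls_name: {f.name: getattr(mix, f.name).as_tuple() for f in fields(mix)}
                for cls_name, mix in self.severity_mixes.items()
            },
            "utilities": {
                f.name: getattr(self.utilities, f.name).as_tuple()
                for f in fields(self.utilities)
            },
            "costs": {},
            "strategies": {},
        }
        for f in fields(self.costs):
            value = getattr(self.costs, f.name)
            if isinstance(value, dict):
                m["costs"][f.name] = {k: pr.as_tuple() for k, pr in value.items()}
            else:
                m["costs"][f.name] = value.as_tuple()
        for name in STRATEGY_ORDER:
            if name not in self.strategies:
                continue
            s = self.strategies[name]
            sm: dict = {
                "severity_class": s.severity_class,
                "rates": rates_map(s.rates),
                "utility": s.utility.as_tuple(),
                "annual_drug_cost": s.annual_drug_cost.as_tuple(),
            }
            if s.first_year_rates is not None:
                sm["first_year_rates"] = rates_map(s.first_year_rates)
            if s.inr_monitoring:
                sm["inr_monitoring"] = True
            if s.laao_extras is not None:
                ex = s.laao_extras
                sm["laao_extras"] = {
                    "implant_success": ex.implant_success.as_tuple(),
                    "pericardial_effusion": ex.pericardial_effusion.as_tuple(),
                    "total_cost": ex.total_cost.as_tuple(),
                    "warfarin_days": ex.warfarin_days,
                    "dual_days": ex.dual_days,
                    "tee_exams": ex.tee_exams,
                }
            m["strategies"][name] = sm
        return m


# ---------------------------------------------------------------------------
# loading / validation
# ---------------------------------------------------------------------------

_REQUIRED_RATES = ("stroke", "minor_hem", "major_hem", "ich", "fatal_hem", "mi",
                   "all_cause_death")


def _parse_range(node: object, where: str) -> ParamRange:
    if isinstance(node, (int, float)):
        return ParamRange.point(float(node))
    if not (isinstance(node, Sequence) and len(node) == 3):
        raise BookValidationError(f"{where}: expected a [base, low, high] triple")
    base, low, high = (float(v) for v in node)
    return ParamRange(base, low, high)


def _parse_rates(node: Mapping, where: str) -> EventRates:
    missing = [k for k in _REQUIRED_RATES if k not in node]
    if missing:
        raise BookValidationError(f"{where}: missing required rate(s) {missing}")
    kwargs = {k: _parse_range(node[k], f"{where}.{k}") for k in _REQUIRED_RATES}
    for opt in ("vascular_death", "hospitalization"):
        if opt in node:
            kwargs[opt] = _parse_range(node[opt], f"{where}.{opt}")
    return EventRates(**kwargs)


def book_from_mapping(m: Mapping) -> ParameterBook:
    """Build a ParameterBook from the parsed YAML mapping (no validation)."""
    model = m.get("model", {})
    config = ModelConfig(
        start_age=float(model.get("start_age", 65.0)),
        horizon_cycles=int(model.get("horizon_cycles", 20)),
        cycle_length_years=float(model.get("cycle_length_years", 1.0)),
        discount_rate=float(model.get("discount_rate", 0.03)),
        wtp_threshold=float(model.get("wtp_threshold", 50_000.0)),
    )
    mixes = {
        cls_name: SeverityMix(**{
            k: _parse_range(v, f"severity_mixes.{cls_name}.{k}")
            for k, v in node.items()
        })
        for cls_name, node in m["severity_mixes"].items()
    }
    utilities = UtilitySet(**{
        k: _parse_range(v, f"utilities.{k}") for k, v in m["utilities"].items()
    })
    costs_node = dict(m["costs"])
    costs = CostSet(
        inr_visit=_parse_range(costs_node["inr_visit"], "costs.inr_visit"),
        short_term={k: _parse_range(v, f"costs.short_term.{k}")
                    for k, v in costs_node["short_term"].items()},
        long_term={k: _parse_range(v, f"costs.long_term.{k}")
                   for k, v in costs_node["long_term"].items()},
        tee=_parse_range(costs_node["tee"], "costs.tee"),
        major_bleed=_parse_range(costs_node["major_bleed"], "costs.major_bleed"),
        minor_bleed=_parse_range(costs_node["minor_bleed"], "costs.minor_bleed"),
        death_nonstroke=_parse_range(costs_node["death_nonstroke"], "costs.death_nonstroke"),
        mi=_parse_range(costs_node["mi"], "costs.mi"),
        hosp_stroke=_parse_range(costs_node["hosp_stroke"], "costs.hosp_stroke"),
        hosp_pericardial=_parse_range(costs_node["hosp_pericardial"], "costs.hosp_pericardial"),
    )
    strategies: dict[str, StrategySpec] = {}
    for name, node in m["strategies"].items():
        where = f"strategies.{name}"
        extras = None
        if "laao_extras" in node:
            ex = node["laao_extras"]
            extras = LaaoExtras(
                implant_success=_parse_range(ex["implant_success"], f"{where}.implant_success"),
                pericardial_effusion=_parse_range(
                    ex["pericardial_effusion"], f"{where}.pericardial_effusion"),
                total_cost=_parse_range(ex["total_cost"], f"{where}.total_cost"),
                warfarin_days=int(ex.get("warfarin_days", 45)),
                dual_days=int(ex.get("dual_days", 180)),
                tee_exams=int(ex.get("tee_exams", 2)),
            )
        strategies[name] = StrategySpec(
            name=name,
            severity_class=str(node["severity_class"]),
            rates=_parse_rates(node["rates"], f"{where}.rates"),
            first_year_rates=(_parse_rates(node["first_year_rates"],
                                           f"{where}.first_year_rates")
                              if "first_year_rates" in node else None),
            utility=_parse_range(node["utility"], f"{where}.utility"),
            annual_drug_cost=_parse_range(node["annual_drug_cost"],
                                          f"{where}.annual_drug_cost"),
            inr_monitoring=bool(node.get("inr_monitoring", False)),
            laao_extras=extras,
        )
    book = ParameterBook(
        strategies=strategies,
        severity_mixes=mixes,
        utilities=utilities,
        costs=costs,
        tia_share=_parse_range(m["tia_share"], "tia_share"),
        config=config,
    )
    return book


def validate_book(book: ParameterBook,
                  require_all_strategies: bool = True) -> list[str]:
    """Hard-validate a book; return soft warnings (range anomalies).

    Hard failures (raise :class:`BookValidationError`): missing strategies,
    out-of-[0,1] utilities or fractions, negative costs, rates outside
    [0, 100].  Soft warnings: rows whose printed range does not bracket the
    base case (``low <= base <= high`` violated).
    """
    report: list[str] = []
    if require_all_strategies:
        missing = [s for s in STRATEGY_ORDER if s not in book.strategies]
        if missing:
            raise BookValidationError(f"missing strategies: {missing}")
    n_laao = sum(1 for s in book.strategies.values() if s.is_laao)
    if require_all_strategies and n_laao != 1:
        raise BookValidationError(
            f"exactly one strategy must carry laao_extras (found {n_laao})")
    for s in book.strategies.values():
        if s.severity_class not in book.severity_mixes:
            raise BookValidationError(
                f"strategies.{s.name}: unknown severity_class {s.severity_class!r}")
    book.config.validate()

    for pid, pr in book.walk():
        vals = np.asarray([pr.base, pr.low, pr.high], dtype=float)
        if np.any(np.isnan(vals)):
            raise BookValidationError(f"{pid}: NaN value")
        is_cost = pid.startswith("costs.") or pid.endswith(
            (".annual_drug_cost", ".total_cost"))
        is_fraction = ".utility" in pid or pid.startswith("utilities.") \
            or pid.endswith(".implant_success")
        if is_fraction:
            if not (0.0 <= pr.base <= 1.0):
                raise BookValidationError(f"{pid}: utility {pr.base} outside [0, 1]")
        elif is_cost:
            if pr.base < 0 or pr.low < 0 or pr.high < 0:
                raise BookValidationError(f"{pid}: negative cost")
        else:  # annual percentage rate / percentage share
            if not (0.0 <= pr.base <= 100.0):
                raise BookValidationError(f"{pid}: rate {pr.base} outside [0, 100]")
        if not (pr.low <= pr.base <= pr.high):
            report.append(
                f"{pid}: range ({pr.low}, {pr.high}) does not bracket base {pr.base}")
    book.validation_warnings = report
    return report


def load_parameter_book(path: str | Path,
                        require_all_strategies: bool = True) -> ParameterBook:
    """Load and validate a parameter book from YAML.

    By default all eight canonical strategies must be present; pass
    ``require_all_strategies=False`` to analyse a reduced strategy set (the
    CLI does, so a book with an arm removed still yields a ranked table).
    """
    with open(path, "r") as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping) or "strategies" not in mapping:
        raise BookValidationError(f"{path}: not a parameter book")
    book = book_from_mapping(mapping)
    validate_book(book, require_all_strategies=require_all_strategies)
    return book


def save_parameter_book(book: ParameterBook, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(book.to_mapping(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# PSA distributions
# ---------------------------------------------------------------------------

#: sd of a quantity whose (low, high) range is read as a 95 % interval
_Z95_SPAN = 3.92


@dataclass
class DistributionSpec:
    """A fitted sampling distribution for one parameter.

    ``family`` is ``'beta'`` (support [0,1], used for probabilities and
    utilities), ``'gamma'`` (support [0,inf), used for costs) or ``'point'``
    (degenerate range).  ``scale`` converts a draw on the distribution's
    native support back to the book's units (100 for percent rates).
    """

    family: str
    a: float          # beta alpha / gamma shape; unused for point
    b: float          # beta beta  / gamma scale; unused for point
    mean: float       # analytic mean on native support
    scale: float = 1.0

    @property
    def is_point(self) -> bool:
        return self.family == "point"

    def frozen(self):
        if self.family == "beta":
            return stats.beta(self.a, self.b)
        if self.family == "gamma":
            return stats.gamma(self.a, scale=self.b)
        raise ValueError("point distributions have no scipy frozen form")

    def sample(self, rng: np.random.Generator, size=None):
        """Draw in the book's native units."""
        if self.family == "point":
            draw = self.mean if size is None else np.full(size, self.mean)
        elif self.family == "beta":
            draw = rng.beta(self.a, self.b, size=size)
        else:
            draw = rng.gamma(self.a, self.b, size=size)
        return draw * self.scale

    def analytic_mean(self) -> float:
        """Mean in the book's native units."""
        return self.mean * self.scale

    def analytic_sd(self) -> float:
        if self.family == "point":
            return 0.0
        if self.family == "beta":
            ab = self.a + self.b
            var = self.a * self.b / (ab * ab * (ab + 1.0))
        else:
            var = self.a * self.b * self.b
        return math.sqrt(var) * self.scale


def beta_from_mean_range(mean: float, low: float, high: float,
                         scale: float = 1.0) -> DistributionSpec:
    """Method-of-moments beta fit from a mean and a 95 % range.

    ``sd = (high - low) / 3.92``.  If the implied variance reaches the
    Bernoulli bound ``mean * (1 - mean)`` the fit falls back to a
    minimum-concentration beta (variance capped at 95 % of the bound) with
    a warning.  A degenerate range returns a point mass.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta fit needs 0 < mean < 1, got {mean}")
    if low > high:
        raise ValueError(f"low {low} > high {high}")
    sd = (high - low) / _Z95_SPAN
    if sd == 0.0:
        return DistributionSpec("point", math.nan, math.nan, mean, scale)
    var = sd * sd
    bound = mean * (1.0 - mean)
    if var >= bound:
        warnings.warn(
            f"beta fit: implied sd {sd:.4g} exceeds the Bernoulli bound for "
            f"mean {mean:.4g}; using a minimum-concentration beta",
            stacklevel=2,
        )
        var = 0.95 * bound
    nu = bound / var - 1.0
    return DistributionSpec("beta", mean * nu, (1.0 - mean) * nu, mean, scale)


def gamma_from_mean_range(mean: float, low: float, high: float,
                          scale: float = 1.0) -> DistributionSpec:
    """Method-of-moments gamma fit from a mean and a 95 % range."""
    if mean <= 0.0:
        raise ValueError(f"gamma fit needs mean > 0, got {mean}")
    if low > high:
        raise ValueError(f"low {low} > high {high}")
    sd = (high - low) / _Z95_SPAN
    if sd == 0.0:
        return DistributionSpec("point", math.nan, math.nan, mean, scale)
    var = sd * sd
    shape = mean * mean / var
    theta = var / mean
    return DistributionSpec("gamma", shape, theta, mean, scale)


def _param_kind(param_id: str) -> str:
    """Classify a parameter id: 'cost', 'fraction' or 'percent'."""
    if param_id.startswith("costs.") or param_id.endswith(
            (".annual_drug_cost", ".total_cost")):
        return "cost"
    if ".utility" in param_id or param_id.startswith("utilities.") \
            or param_id.endswith(".implant_success"):
        return "fraction"
    return "percent"


def fit_distributions(book: ParameterBook) -> dict[str, DistributionSpec]:
    """Fit a PSA distribution to every parameter of the book.

    Beta distributions for every parameter whose native value lies in [0,1]
    (probabilities, severity fractions, utilities; percent rates are fitted
    on the fraction scale and scaled back), gamma for costs.  Parameters
    with a degenerate range or a base of exactly 0 or 1 become point masses.
    """
    out: dict[str, DistributionSpec] = {}
    for pid, pr in book.walk():
        kind = _param_kind(pid)
        if kind == "cost":
            if pr.base <= 0.0 or pr.low == pr.high:
                out[pid] = DistributionSpec("point", math.nan, math.nan, pr.base)
            else:
                out[pid] = gamma_from_mean_range(pr.base, pr.low, pr.high)
        else:
            s = 0.01 if kind == "percent" else 1.0
            mean, low, high = pr.base * s, pr.low * s, pr.high * s
            if mean <= 0.0 or mean >= 1.0 or low == high:
                out[pid] = DistributionSpec("point", math.nan, math.nan, mean, 1.0 / s)
            else:
                out[pid] = beta_from_mean_range(mean, low, high, scale=1.0 / s)
    return out


# ---------------------------------------------------------------------------
# pro-rata first-year rates
# ---------------------------------------------------------------------------

def pro_rata_first_year_rate(days_and_rates: Sequence[tuple[float, float]]) -> float:
    """Duration-weighted annual rate for a phased drug regimen.

    ``days_and_rates`` is a list of ``(days, annual rate %/yr)`` phases that
    must cover exactly 365 days.  Used to check the printed first-year
    bleeding/MI rates of the post-implant regimen (45 days warfarin, 180
    days clopidogrel+aspirin, 140 days aspirin) and to derive rates for
    user-defined regimens.
    """
    total_days = sum(d for d, _ in days_and_rates)
    if total_days != DAYS_PER_YEAR:
        raise ValueError(f"regimen covers {total_days} days, expected {DAYS_PER_YEAR}")
    return sum(d * r for d, r in days_and_rates) / DAYS_PER_YEAR
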