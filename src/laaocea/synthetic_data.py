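"""Parameter-book generators: canonical, randomized and degenerate variants.

``canonical_book`` returns the in-repo transcription of the published
base-case inputs.  ``random_book`` draws every parameter from its fitted
beta/gamma distribution (the probabilistic-sensitivity structure).
``degenerate_book`` produces books engineered so the Markov engine has an
exact closed-form answer (no events, no deaths, zero costs, unit utility)
-- these are first-class oracle fixtures, not test scaffolding.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np

from .parameters import (
    DistributionSpec,
    ParameterBook,
    book_from_mapping,
    fit_distributions,
    load_parameter_book,
    validate_book,
)

__all__ = ["canonical_book", "random_book", "degenerate_book", "DEGENERATE_KINDS"]

DEGENERATE_KINDS = ("no_event", "no_death", "zero_cost", "unit_utility")


@lru_cache(maxsize=1)
def _canonical() -> ParameterBook:
    ref = resources.files("laaocea").joinpath("data/canonical_book.yaml")
    with resources.as_file(ref) as path:
        return load_parameter_book(path)


def canonical_book() -> ParameterBook:
    """The canonical base-case parameter book (fresh copy on every call)."""
    return _canonical().copy()


def random_book(seed: int | tuple[int, ...], scale: float | None = None,
                base: ParameterBook | None = None,
                dists: dict[str, DistributionSpec] | None = None) -> ParameterBook:
    """One Monte-Carlo draw of the whole parameter book.

    Every rate, fraction and utility is drawn from its beta distribution and
    every cost from its gamma distribution, independently across parameters,
    in the stable ``walk`` order (so the draw is fully determined by
    ``seed``).  ``scale`` optionally multiplies every range spread before
    fitting.  Severity-mix fractions are sampled marginally and renormalized
    to the simplex when consumed.

    ``base``/``dists`` let callers reuse a book and pre-fitted distributions
    (the PSA loop does this); by default the canonical book is used.
    """
    if base is None:
        base = _canonical()
    if dists is None:
        dists = _fitted(base, scale)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    book = base.copy()
    for pid, pr in book.walk():
        value = float(dists[pid].sample(rng))
        pr.base = value
        pr.low = value
        pr.high = value
    return book


def _fitted(book: ParameterBook, scale: float | None) -> dict[str, DistributionSpec]:
    if scale is None:
        return fit_distributions(book)
    widened = book.copy()
    for _, pr in widened.walk():
        half_lo = (pr.base - pr.low) * scale
        half_hi = (pr.high - pr.base) * scale
        pr.low = max(pr.base - half_lo, 0.0)
        pr.high = pr.base + half_hi
    return fit_distributions(widened)


def _zero(pr) -> None:
    pr.base = pr.low = pr.high = 0.0


def _one(pr) -> None:
    pr.base = pr.low = pr.high = 1.0


def degenerate_book(*kinds: str, base: ParameterBook | None = None) -> ParameterBook:
    """Canonical book with one or more degenerate overrides applied.

    ``no_event``
        every transient-event rate (stroke, all hemorrhage classes, MI,
        pericardial effusion) set to 0; mortality retained.
    ``no_death``
        all-cause and vascular mortality, fatal hemorrhage and the fatal
        stroke fraction set to 0.
    ``zero_cost``
        every cost (drug, device, monitoring, events) set to 0.
    ``unit_utility``
        every utility (baseline and sequela) set to 1.

    Kinds compose: ``degenerate_book('no_event', 'no_death', 'unit_utility')``
    yields a cohort that never leaves the well state and accrues exactly one
    QALY per undiscounted cycle.
    """
    if not kinds:
        raise ValueError("at least one degenerate kind is required")
    unknown = [k for k in kinds if k not in DEGENERATE_KINDS]
    if unknown:
        raise ValueError(f"unknown degenerate kind(s) {unknown}; "
                         f"valid kinds: {list(DEGENERATE_KINDS)}")
    book = (base or _canonical()).copy()
    for kind in kinds:
        if kind == "no_event":
            for strat in book.strategies.values():
                for rates in (strat.rates, strat.first_year_rates):
                    if rates is None:
                        continue
                    for name in ("stroke", "minor_hem", "major_hem", "ich",
                                 "fatal_hem", "mi"):
                        _zero(getattr(rates, name))
                if strat.laao_extras is not None:
                    _zero(strat.laao_extras.pericardial_effusion)
            _zero(book.tia_share)
        elif kind == "no_death":
            for strat in book.strategies.values():
                for rates in (strat.rates, strat.first_year_rates):
                    if rates is None:
                        continue
                    _zero(rates.all_cause_death)
                    _zero(rates.fatal_hem)
                    if rates.vascular_death is not None:
                        _zero(rates.vascular_death)
            for mix in book.severity_mixes.values():
                _zero(mix.fatal)
        elif kind == "zero_cost":
            for pid, pr in book.walk():
                if pid.startswith("costs.") or pid.endswith(
                        (".annual_drug_cost", ".total_cost")):
                    _zero(pr)
        elif kind == "unit_utility":
            for pid, pr in book.walk():
                if ".utility" in pid or pid.startswith("utilities."):
                    _one(pr)
    validate_book(book)
    return book
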