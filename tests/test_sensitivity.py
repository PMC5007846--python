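"""Scenario sweeps, one-way analysis and the tornado ranking."""

import pytest

from laaocea.cea import IcerCode, icer_value
from laaocea.sensitivity import (
    one_way,
    scenario_chads2,
    scenario_hasbled,
    scenario_horizon,
    scenario_laao_cost,
    tornado,
)

NOACS = ("dabigatran_110", "dabigatran_150", "apixaban", "rivaroxaban")
ANTIPLATELET = ("aspirin", "clopidogrel_aspirin")

@pytest.fixture(scope="module")
def tornado_entries(book):
    return tornado(book)


@pytest.fixture(scope="module")
def chads2_table(book):
    return scenario_chads2(book)


@pytest.fixture(scope="module")
def hasbled_table(book):
    return scenario_hasbled(book)


@pytest.fixture(scope="module")
def horizon_table(book):
    return scenario_horizon(book)


@pytest.fixture(scope="module")
def laao_cost_table(book):
    return scenario_laao_cost(book)



class TestOneWay:
    def test_degenerate_range_returns_base_icer_twice(self, book, base_outcomes):
        base_icer = icer_value(base_outcomes["laao"], base_outcomes["warfarin"])
        lo, hi = one_way(book, "costs.tee", low=334.0, high=334.0)
        assert lo == pytest.approx(base_icer)
        assert hi == pytest.approx(base_icer)

    def test_unknown_parameter_rejected(self, book):
        with pytest.raises(KeyError):
            one_way(book, "strategies.warfarin.rates.no_such_rate")

    def test_warfarin_mortality_sweep_changes_sign_direction(self, book):
        """Low warfarin mortality favors warfarin (higher ICER for the
        device); high mortality favors the device."""
        lo, hi = one_way(book, "strategies.warfarin.rates.all_cause_death")
        assert lo > hi

    def test_laao_mortality_sweep_brackets_base(self, book, base_outcomes):
        lo, hi = one_way(book, "strategies.laao.rates.all_cause_death")
        base_icer = icer_value(base_outcomes["laao"], base_outcomes["warfarin"])
        assert lo < base_icer < hi


class TestTornado:
    def test_sorted_by_descending_width(self, tornado_entries):
        widths = [e.width for e in tornado_entries]
        assert widths == sorted(widths, reverse=True)

    def test_mortality_parameters_dominate(self, tornado_entries):
        top_two = {e.param_id for e in tornado_entries[:2]}
        assert top_two == {"strategies.warfarin.rates.all_cause_death",
                           "strategies.laao.rates.all_cause_death"}

    def test_no_bar_reaches_the_threshold(self, tornado_entries):
        # versus warfarin, no parameter pushes the ICER beyond $50,000/QALY
        assert all(max(abs(e.icer_low), abs(e.icer_high)) < 50_000.0
                   for e in tornado_entries)

    def test_single_parameter_input(self, book):
        single = tornado(book, ["costs.tee"])
        assert len(single) == 1


class TestChads2:
    def test_score_out_of_range_rejected(self, book):
        with pytest.raises(ValueError):
            scenario_chads2(book, scores=[7])

    def test_qalys_non_increasing_in_score(self, chads2_table):
        for name in chads2_table.outcomes[0]:
            qalys = [chads2_table.outcomes[s][name].qaly for s in chads2_table.axis_values]
            assert all(b <= a + 1e-12 for a, b in zip(qalys, qalys[1:])), name

    def test_device_dominates_noacs_at_every_score(self, chads2_table):
        for score in chads2_table.axis_values:
            outs = chads2_table.outcomes[score]
            laao = outs["laao"]
            for name in NOACS:
                assert laao.cost < outs[name].cost, (score, name)
                assert laao.qaly > outs[name].qaly, (score, name)

    def test_costs_increase_with_stroke_risk(self, chads2_table):
        for name in chads2_table.outcomes[0]:
            costs = [chads2_table.outcomes[s][name].cost for s in chads2_table.axis_values]
            assert costs == sorted(costs), name


class TestHasbled:
    def test_score_out_of_range_rejected(self, book):
        with pytest.raises(ValueError):
            scenario_hasbled(book, scores=[6])

    def test_antiplatelet_arms_bit_identical_across_scores(self, hasbled_table):
        for name in ANTIPLATELET:
            ref = hasbled_table.outcomes[hasbled_table.axis_values[0]][name]
            for s in hasbled_table.axis_values[1:]:
                out = hasbled_table.outcomes[s][name]
                assert out.cost == ref.cost and out.qaly == ref.qaly, (s, name)

    def test_anticoagulant_arms_respond(self, hasbled_table):
        costs = [hasbled_table.outcomes[s]["warfarin"].cost for s in hasbled_table.axis_values]
        assert costs[-1] > costs[0]


class TestHorizon:
    def test_totals_non_decreasing_in_horizon(self, horizon_table):
        for name in horizon_table.outcomes[5]:
            costs = [horizon_table.outcomes[h][name].cost for h in horizon_table.axis_values]
            qalys = [horizon_table.outcomes[h][name].qaly for h in horizon_table.axis_values]
            assert costs == sorted(costs), name
            assert qalys == sorted(qalys), name

    def test_full_horizon_equals_base_case(self, horizon_table, base_outcomes):
        for name, base in base_outcomes.items():
            out = horizon_table.outcomes[20][name]
            assert out.cost == base.cost and out.qaly == base.qaly

    def test_frame_reports_device_icers(self, horizon_table):
        frame = horizon_table.frame()
        assert set(frame.columns) >= {"horizon_years", "strategy",
                                      "discounted_cost", "laao_icer_vs_strategy"}
        assert len(frame) == 4 * 8


class TestLaaoCost:
    def test_non_device_arms_bit_identical(self, laao_cost_table, base_outcomes):
        for cost_level in laao_cost_table.axis_values:
            for name, base in base_outcomes.items():
                if name == "laao":
                    continue
                out = laao_cost_table.outcomes[cost_level][name]
                assert out.cost == base.cost and out.qaly == base.qaly

    def test_base_level_equals_base_case(self, laao_cost_table, base_outcomes):
        out = laao_cost_table.outcomes[22_500.0]["laao"]
        assert out.cost == base_outcomes["laao"].cost
        assert out.qaly == base_outcomes["laao"].qaly

    def test_device_cost_moves_device_arm_monotonically(self, laao_cost_table):
        costs = [laao_cost_table.outcomes[c]["laao"].cost for c in laao_cost_table.axis_values]
        assert costs == sorted(costs)
        icers = [laao_cost_table.icers[c]["warfarin"] for c in laao_cost_table.axis_values]
        assert all(not isinstance(i, IcerCode) for i in icers)
        assert icers == sorted(icers)

    def test_nonpositive_cost_rejected(self, book):
        with pytest.raises(ValueError):
            scenario_laao_cost(book, costs=[0.0])
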