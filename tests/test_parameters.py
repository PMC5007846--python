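"""Parameter book loading, validation, distribution fitting, pro-rata rates."""

import copy

import numpy as np
import pytest
import yaml

from laaocea import canonical_book, save_parameter_book
from laaocea.parameters import (
    BookValidationError,
    beta_from_mean_range,
    book_from_mapping,
    fit_distributions,
    gamma_from_mean_range,
    load_parameter_book,
    pro_rata_first_year_rate,
    validate_book,
)


class TestLoading:
    def test_canonical_values(self, book):
        warf = book.strategies["warfarin"].rates.stroke
        assert (warf.base, warf.low, warf.high) == (1.21, 1.05, 1.42)
        laao_cost = book.strategies["laao"].laao_extras.total_cost
        assert (laao_cost.base, laao_cost.low, laao_cost.high) == (22500.0, 20384.0, 24614.0)

    def test_canonical_has_no_range_anomalies(self, book):
        assert validate_book(book.copy()) == []

    def test_out_of_range_utility_names_field(self, book):
        broken = book.copy()
        broken.strategies["warfarin"].utility.base = 1.2
        with pytest.raises(BookValidationError, match="warfarin.utility"):
            validate_book(broken)

    def test_missing_rate_names_field(self, book):
        mapping = book.to_mapping()
        del mapping["strategies"]["apixaban"]["rates"]["stroke"]
        with pytest.raises(BookValidationError, match="apixaban.*stroke"):
            book_from_mapping(mapping)

    def test_missing_strategy_is_hard_error(self, book, tmp_path):
        mapping = book.to_mapping()
        del mapping["strategies"]["rivaroxaban"]
        path = tmp_path / "book.yaml"
        path.write_text(yaml.safe_dump(mapping))
        with pytest.raises(BookValidationError, match="rivaroxaban"):
            load_parameter_book(path)
        # lenient mode admits a reduced strategy set
        reduced = load_parameter_book(path, require_all_strategies=False)
        assert "rivaroxaban" not in reduced.strategies

    def test_round_trip_is_lossless(self, book, tmp_path):
        path = tmp_path / "book.yaml"
        save_parameter_book(book, path)
        reloaded = load_parameter_book(path)
        assert reloaded == canonical_book()

    def test_severity_mix_renormalizes_to_one(self, book):
        # the published antiplatelet split sums to 99.9 %
        mix = book.severity_mixes["antiplatelet"]
        assert sum(getattr(mix, k).base for k in
                   ("fatal", "mod_severe", "mild", "none")) == pytest.approx(99.9)
        assert sum(mix.fractions().values()) == pytest.approx(1.0, abs=1e-12)


class TestBetaFit:
    def test_symmetric_range_gives_equal_shapes(self):
        spec = beta_from_mean_range(0.5, 0.4, 0.6)
        assert spec.a == pytest.approx(spec.b)
        assert spec.analytic_mean() == pytest.approx(0.5, abs=1e-9)

    def test_stroke_rate_fit_mean_and_quantiles(self):
        # warfarin annual stroke rate 1.21 % with range (1.05, 1.42)
        spec = beta_from_mean_range(0.0121, 0.0105, 0.0142)
        assert spec.analytic_mean() == pytest.approx(0.0121, abs=1e-9)
        lo, hi = spec.frozen().ppf([0.025, 0.975])
        half_width = (0.0142 - 0.0105) / 2
        assert lo == pytest.approx(0.0105, abs=0.2 * half_width)
        assert hi == pytest.approx(0.0142, abs=0.2 * half_width)

    def test_monte_carlo_mean_recovery(self):
        spec = beta_from_mean_range(0.0121, 0.0105, 0.0142)
        rng = np.random.default_rng(7)
        draws = spec.sample(rng, size=1_000_000)
        se = spec.analytic_sd() / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.0121) < 3 * se

    def test_excess_variance_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="minimum-concentration"):
            spec = beta_from_mean_range(0.01, 0.0, 0.9)
        assert spec.family == "beta"
        assert spec.analytic_mean() == pytest.approx(0.01, abs=1e-9)

    @pytest.mark.parametrize("mean", [0.0, 1.0, -0.1, 1.5])
    def test_mean_outside_open_interval_rejected(self, mean):
        with pytest.raises(ValueError):
            beta_from_mean_range(mean, 0.1, 0.2)


class TestGammaFit:
    def test_device_cost_fit(self):
        spec = gamma_from_mean_range(22_500.0, 20_384.0, 24_614.0)
        assert spec.analytic_mean() == pytest.approx(22_500.0, abs=1e-9)

    def test_degenerate_range_is_point_mass(self):
        spec = gamma_from_mean_range(500.0, 500.0, 500.0)
        assert spec.is_point
        rng = np.random.default_rng(0)
        assert spec.sample(rng) == 500.0

    def test_monte_carlo_sd_recovery(self):
        spec = gamma_from_mean_range(22_500.0, 20_384.0, 24_614.0)
        rng = np.random.default_rng(11)
        draws = spec.sample(rng, size=1_000_000)
        target_sd = (24_614.0 - 20_384.0) / 3.92
        assert draws.std() == pytest.approx(target_sd, rel=0.05)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_mean_range(0.0, 0.0, 10.0)


class TestFitAllRows:
    def test_analytic_mean_matches_base_case_everywhere(self, book):
        """Method-of-moments fits recover every base-case value to 1e-9."""
        dists = fit_distributions(book)
        for pid, pr in book.walk():
            assert dists[pid].analytic_mean() == pytest.approx(
                pr.base, abs=1e-9), pid

    def test_families_match_parameter_kind(self, book):
        dists = fit_distributions(book)
        assert dists["costs.mi"].family == "gamma"
        assert dists["strategies.warfarin.rates.stroke"].family == "beta"
        assert dists["strategies.warfarin.utility"].family == "beta"
        assert dists["strategies.laao.laao_extras.implant_success"].family == "beta"


class TestProRata:
    # 45 days warfarin, 180 days clopidogrel+aspirin, 140 days aspirin
    REGIMEN_DAYS = (45, 180, 140)

    @pytest.mark.parametrize("rates, printed", [
        ((3.32, 1.50, 1.00), 1.54),   # major hemorrhage: printed agrees
        ((0.75, 0.40, 0.20), 0.37),   # intracranial hemorrhage: printed agrees
    ])
    def test_agreeing_first_year_rows(self, rates, printed):
        value = pro_rata_first_year_rate(list(zip(self.REGIMEN_DAYS, rates)))
        assert value == pytest.approx(printed, abs=0.01)

    @pytest.mark.parametrize("rates, printed, computed", [
        ((18.63, 3.50, 1.40), 4.28, 4.56),  # minor hemorrhage
        ((0.90, 0.30, 0.20), 0.45, 0.34),   # fatal hemorrhage
        ((0.78, 0.70, 0.90), 0.76, 0.79),   # myocardial infarction
    ])
    def test_documented_discrepant_rows(self, rates, printed, computed, book):
        """Three published first-year rows disagree with the naive pro-rata
        computation; the book carries the published values verbatim."""
        value = pro_rata_first_year_rate(list(zip(self.REGIMEN_DAYS, rates)))
        assert value == pytest.approx(computed, abs=0.01)
        assert abs(value - printed) > 0.02
        fy = book.strategies["laao"].first_year_rates
        field = {4.28: "minor_hem", 0.45: "fatal_hem", 0.76: "mi"}[printed]
        assert getattr(fy, field).base == printed

    def test_single_phase_identity(self):
        assert pro_rata_first_year_rate([(365, 2.5)]) == pytest.approx(2.5)

    def test_wrong_day_total_rejected(self):
        with pytest.raises(ValueError, match="364"):
            pro_rata_first_year_rate([(364, 1.0)])
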