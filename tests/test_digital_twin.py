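"""Digital-twin prediction, the overdiagnosis statistic, and its interval."""

import numpy as np
import pandas as pd
import pytest

from crctwin import (
    McmcConfig,
    ModelSpec,
    MortalitySchedule,
    RateParameters,
    ScreeningDesign,
    adenoma_sensitivity_sweep,
    competing_risk_adjustment,
    fit_mcmc,
    overdiagnosis_interval,
    overdiagnosis_proportion,
    predict_screened_twin,
    project_control_incidence,
)
from crctwin import datasets
from crctwin.digital_twin import _clinical_by_T, build_report
from crctwin.synthetic_cohort import SimulationConfig, simulate_cohort


class TestOverdiagnosisProportion:
    @pytest.mark.parametrize(
        "S,U,expected",
        [(931, 856, 8.76), (528, 483, 9.32), (100, 100, 0.0)],
    )
    def test_published_ratio_examples(self, S, U, expected):
        assert overdiagnosis_proportion(S, U) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            overdiagnosis_proportion(10.0, 0.0)


class TestControlProjection:
    def test_one_year_unit_growth(self):
        assert project_control_incidence(1.0, 0.045, 1) == pytest.approx(1.045)

    def test_ten_year_projection(self):
        assert project_control_incidence(100.0, 0.045, 10) == pytest.approx(155.30, abs=0.005)

    def test_zero_growth_identity(self):
        assert project_control_incidence(42.0, 0.0, 25) == 42.0

    def test_multi_year_window_sums_year_by_year(self):
        yearly = project_control_incidence(100.0, 0.045, np.arange(5))
        assert yearly.shape == (5,)
        assert float(yearly.sum()) == pytest.approx(sum(100 * 1.045**k for k in range(5)))

    def test_invalid_growth_rejected(self):
        with pytest.raises(ValueError):
            project_control_incidence(1.0, -1.5, 1)


class TestPredictScreenedTwin:
    def test_uk_published_parameters_recover_published_total(self, spec_od, mort0):
        pub = datasets.published_twin_totals("uk")
        pred = predict_screened_twin(
            spec_od,
            datasets.fitted_rates("uk"),
            mort0,
            datasets.rct_design("nottingham"),
            cohort_size=pub["cohort"],
            followup_T=pub["followup"],
        )
        assert pred.total == pytest.approx(pub["S"], rel=0.05)
        assert pred.total == pytest.approx(sum(pred.components.values()), abs=1e-6)

    def test_funen_published_parameters_recover_published_total(self, spec_od, mort0):
        pub = datasets.published_twin_totals("funen")
        pred = predict_screened_twin(
            spec_od,
            datasets.fitted_rates("funen"),
            mort0,
            datasets.rct_design("funen"),
            cohort_size=pub["cohort"],
            followup_T=pub["followup"],
        )
        assert pred.total == pytest.approx(pub["S"], rel=0.05)

    def test_inert_screening_collapses_to_control_expectation(self, spec_od, mort0):
        r = RateParameters(lambda1=0.00141, lambda2=0.386, sens_crc=0.0)
        d = datasets.taiwan_like_design(1_000_000)
        pred = predict_screened_twin(spec_od, r, mort0, d)
        U = 1_000_000 * _clinical_by_T(spec_od, r, mort0, d)
        assert overdiagnosis_proportion(pred.total, U) == pytest.approx(0.0, abs=1e-6)

    def test_horizon_before_last_screen_rejected(self, spec_od, mort0, taiwan_rates):
        d = datasets.taiwan_like_design(1000)
        with pytest.raises(ValueError, match="horizon"):
            predict_screened_twin(spec_od, taiwan_rates, mort0, d, followup_T=1.0)

    def test_agrees_with_simulation_within_3_mc_se(
        self, spec_od, sim_rates, mort01, small_design, simulated_cohort
    ):
        pred = predict_screened_twin(spec_od, sim_rates, mort01, small_design)
        S_sim = simulated_cohort.truth["n_diagnosed_by_T"]
        se = np.sqrt(S_sim)
        assert abs(pred.total - S_sim) < 3 * se


class TestCompetingRiskAdjustment:
    def test_zero_delta_is_identity(self, spec_od, mort0):
        r = RateParameters(lambda1=0.00141, lambda2=0.386, sens_crc=0.8)
        d = datasets.taiwan_like_design(100_000)
        pred = predict_screened_twin(spec_od, r, mort0, d)
        adj = competing_risk_adjustment(pred, spec_od, r, mort0, d)
        assert adj.u_depletion == 1.0
        assert adj.components == pred.components

    def test_adjustment_raises_percentage_monotonically_in_delta(self, spec_od):
        r = RateParameters(
            lambda1=0.00141, lambda2=0.386, sens_crc=0.8, nonprog_fraction=0.05
        )
        d = datasets.taiwan_like_design(1_000_000)
        U = 14_000.0
        last = None
        for delta in (0.0, 0.01, 0.02, 0.04):
            m = MortalitySchedule.constant(delta)
            pred = predict_screened_twin(spec_od, r, m, d)
            adj = competing_risk_adjustment(pred, spec_od, r, m, d)
            raw = overdiagnosis_proportion(pred.total, U)
            adjusted = overdiagnosis_proportion(adj.total, U * adj.u_depletion)
            assert adjusted >= raw - 1e-9
            if last is not None:
                assert adjusted >= last  # doubling delta never lowers it
            last = adjusted

    def test_adjustment_direction_matches_individual_level_oracle(
        self, spec_od, small_design
    ):
        """Simulated screened subjects dying before their latent surfacing
        are real excess the raw ratio understates when U is death-free."""
        r = RateParameters(
            lambda1=0.002, lambda2=1 / 2.6, sens_crc=0.8, nonprog_fraction=0.05
        )
        m = MortalitySchedule.constant(0.02)
        out = simulate_cohort(
            SimulationConfig(spec=spec_od, rates=r, mort=m, design=small_design, seed=17),
            return_individuals=True,
        )
        died_before_surfacing = (
            out.individuals.screen_detected
            & ~out.individuals.nonprog
            & (out.individuals.death < out.individuals.clinical)
        )
        assert died_before_surfacing.sum() > 0
        pred = predict_screened_twin(spec_od, r, m, small_design)
        adj = competing_risk_adjustment(pred, spec_od, r, m, small_design)
        assert adj.u_depletion < 1.0


@pytest.fixture(scope="module")
def posterior(spec_od):
    counts = datasets.funen_counts()
    d = datasets.rct_design("funen")
    return fit_mcmc(
        counts,
        d,
        spec_od,
        MortalitySchedule.constant(0.0),
        config=McmcConfig(n_iterations=1500, n_burnin=500, n_chains=1, seed=2),
    )


class TestOverdiagnosisInterval:
    def test_degenerate_posterior_gives_zero_width(self, spec_od, mort0, posterior):
        draws = posterior.draws.copy()
        for c in ("lambda1", "lambda2", "sens_crc"):
            draws[c] = draws[c].iloc[0]
        d = datasets.rct_design("funen")
        med, (lo, hi), _ = overdiagnosis_interval(draws, 483.0, spec_od, mort0, d)
        assert lo == hi == pytest.approx(med)

    def test_interval_brackets_point_and_widens_with_posterior(
        self, spec_od, mort0, posterior
    ):
        d = datasets.rct_design("funen")
        med, (lo, hi), pcts = overdiagnosis_interval(
            posterior, 483.0, spec_od, mort0, d
        )
        assert lo <= med <= hi
        # inflate posterior spread around its centre -> wider interval
        draws = posterior.draws.copy()
        for c in ("lambda1", "lambda2", "sens_crc"):
            mid = draws[c].median()
            draws[c] = mid + 1.6 * (draws[c] - mid)
        draws["sens_crc"] = draws["sens_crc"].clip(0.01, 0.99)
        _, (lo2, hi2), _ = overdiagnosis_interval(draws, 483.0, spec_od, mort0, d)
        assert hi2 - lo2 > hi - lo

    def test_report_invariants(self, spec_od, mort0):
        r = datasets.fitted_rates("uk")
        d = datasets.rct_design("nottingham")
        pred = predict_screened_twin(spec_od, r, mort0, d, 74_998, 8.5)
        rep = build_report(pred, 856.0)
        assert rep.percentage == pytest.approx(
            (rep.S_t / rep.U_t - 1) * 100.0, abs=1e-9
        )
        with pytest.raises(ValueError, match="bracket"):
            build_report(pred, 856.0, interval=(0.0, 1.0))


class TestAdenomaVariant:
    def test_sweep_levels_and_smoothness(self, spec_aden, mort01):
        rates = datasets.fitted_rates("taiwan", with_adenoma=True).replace(
            nonprog_fraction=0.05
        )
        d = datasets.taiwan_like_design(1_000_000)
        grid = np.linspace(0.20, 0.63, 8)
        tab = adenoma_sensitivity_sweep(rates, mort01, d, grid, spec=spec_aden)
        spread = tab.overdiagnosis_pct.max() - tab.overdiagnosis_pct.min()
        assert spread < 6.0  # a few percentage points across the whole grid
        diffs = np.diff(tab.overdiagnosis_pct.to_numpy())
        assert (diffs <= 0).all() or (diffs >= 0).all()  # smooth, no sign flips

    def test_single_point_grid_matches_point_analysis(self, spec_aden, mort01):
        rates = datasets.fitted_rates("taiwan", with_adenoma=True)
        d = datasets.taiwan_like_design(500_000)
        tab = adenoma_sensitivity_sweep(rates, mort01, d, [rates.sens_adenoma], spec=spec_aden)
        pred = predict_screened_twin(spec_aden, rates, mort01, d)
        assert tab.S_t.iloc[0] == pytest.approx(pred.total, rel=1e-12)

    def test_grid_outside_unit_interval_rejected(self, spec_aden, mort01):
        rates = datasets.fitted_rates("taiwan", with_adenoma=True)
        d = datasets.taiwan_like_design(1000)
        with pytest.raises(ValueError):
            adenoma_sensitivity_sweep(rates, mort01, d, [0.0, 0.5], spec=spec_aden)

    def test_polypectomy_offset_is_counted_and_positive(self, spec_aden, spec_od, mort01):
        """The removal offset raises the adenoma-variant twin total and keeps
        it within a few percent of the CRC-only twin on the matched published
        scenario (the printed pair differs through its two fitted
        parameterisations, not through a structural inequality)."""
        d = datasets.taiwan_published_design()
        ra = datasets.fitted_rates("taiwan", with_adenoma=True)
        rc = datasets.fitted_rates("taiwan")
        Sa = predict_screened_twin(spec_aden, ra, mort01, d)
        assert Sa.components["adenoma_removal_offset"] > 0
        no_offset = Sa.total - Sa.components["adenoma_removal_offset"]
        assert Sa.total > no_offset
        Sc = predict_screened_twin(spec_od, rc, mort01, d)
        assert Sa.total == pytest.approx(Sc.total, rel=0.10)
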