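"""Detection-mode probabilities and the aggregate-count likelihood."""

import math

import numpy as np
import pytest

from crctwin import (
    DetectionModeCounts,
    ModelSpec,
    MortalitySchedule,
    RateParameters,
    ScreeningDesign,
    expected_counts,
    log_likelihood,
    mode_probabilities,
)
from crctwin import datasets
from crctwin.screening_likelihood import PARTICIPANT_MODES


@pytest.fixture(scope="module")
def base_design():
    return ScreeningDesign(
        screen_times=(0.0, 2.0, 4.0),
        followup_T=10.0,
        cohort_size=100_000,
        participation=0.6,
        confirmation_rate=0.9,
    )


class TestModeProbabilities:
    def test_partitions_sum_to_one(self, spec_od, sim_rates, mort01, base_design):
        probs = mode_probabilities(spec_od, sim_rates, mort01, base_design)
        assert sum(probs.participant.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(probs.refuser.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_sensitivity_moves_all_cases_to_clinical_modes(
        self, spec_od, mort0, base_design
    ):
        r = RateParameters(lambda1=0.002, lambda2=0.4, sens_crc=0.0)
        probs = mode_probabilities(spec_od, r, mort0, base_design)
        assert probs.participant["prevalent_crc"] == 0.0
        assert probs.participant["repeat_crc"] == 0.0
        assert probs.participant["pos_unconf_first"] == 0.0
        # every participant cancer by T now surfaces clinically
        clinical = (
            probs.participant["interval_crc"] + probs.participant["post_program_crc"]
        )
        assert clinical == pytest.approx(probs.refuser["refuser_crc"], rel=1e-9)

    def test_single_screen_no_followup_has_no_interval(self, spec_od, mort0):
        d = ScreeningDesign(
            screen_times=(0.0,), followup_T=0.0, cohort_size=1000, participation=0.5
        )
        r = RateParameters(lambda1=0.002, lambda2=0.4, sens_crc=0.6)
        probs = mode_probabilities(spec_od, r, mort0, d)
        assert probs.participant["interval_crc"] == 0.0

    def test_prevalent_detection_is_prevalence_times_sensitivity(
        self, spec_od, mort0
    ):
        # long lead-in: PCDP prevalence among the cancer-free approaches
        # lambda1/lambda2, so the first-screen yield approaches its product
        # with sensitivity and the confirmation rate
        r = RateParameters(lambda1=0.00147, lambda2=0.3475, sens_crc=0.534)
        d = ScreeningDesign(
            screen_times=(0.0,),
            followup_T=8.5,
            cohort_size=75_280,
            participation=44865 / 75280,
            confirmation_rate=1.0,
            lead_in=200.0,
        )
        probs = mode_probabilities(spec_od, r, mort0, d)
        assert probs.participant["prevalent_crc"] == pytest.approx(
            0.534 * 0.00147 / 0.3475, rel=1e-3
        )
        # 44837 first-screen attenders give about the printed ~101.6 cancers
        assert 44837 * probs.participant["prevalent_crc"] == pytest.approx(101.3, abs=1.0)

    def test_sensitivity_monotonicity(self, spec_od, mort01, base_design):
        lo = mode_probabilities(
            spec_od,
            RateParameters(lambda1=0.002, lambda2=0.4, sens_crc=0.3),
            mort01,
            base_design,
        )
        hi = mode_probabilities(
            spec_od,
            RateParameters(lambda1=0.002, lambda2=0.4, sens_crc=0.7),
            mort01,
            base_design,
        )
        assert hi.participant["prevalent_crc"] > lo.participant["prevalent_crc"]
        assert hi.participant["interval_crc"] < lo.participant["interval_crc"]

    def test_overdiag_reduces_to_progressive_when_fraction_zero(
        self, spec3, spec_od, mort0, base_design
    ):
        r3 = RateParameters(lambda1=0.002, lambda2=0.4, sens_crc=0.6)
        rod = r3.replace(nonprog_fraction=0.0)
        a = mode_probabilities(spec3, r3, mort0, base_design)
        b = mode_probabilities(spec_od, rod, mort0, base_design)
        for k in a.participant:
            assert a.participant[k] == pytest.approx(b.participant[k], abs=1e-12)
        assert a.refuser["refuser_crc"] == pytest.approx(
            b.refuser["refuser_crc"], abs=1e-12
        )

    def test_agrees_with_simulation_within_3_mc_se(
        self, spec_od, sim_rates, mort01, small_design, simulated_cohort
    ):
        probs = mode_probabilities(spec_od, sim_rates, mort01, small_design)
        c = simulated_cohort.counts
        n_part, n_ref = c.n_participants, c.n_refusers
        checks = [
            ("prevalent_crc", n_part, probs.participant["prevalent_crc"]),
            ("repeat_crc", n_part, probs.participant["repeat_crc"]),
            ("interval_crc", n_part, probs.participant["interval_crc"]),
            ("pos_unconf_first", n_part, probs.participant["pos_unconf_first"]),
            ("pos_unconf_repeat", n_part, probs.participant["pos_unconf_repeat"]),
            ("refuser_crc", n_ref, probs.refuser["refuser_crc"]),
        ]
        for mode, n, p in checks:
            se = math.sqrt(p * (1 - p) / n)
            assert abs(c.counts[mode] / n - p) < 3 * se, mode

    def test_expected_counts_track_simulated_normal_cells(
        self, spec_od, sim_rates, mort01, small_design, simulated_cohort
    ):
        probs = mode_probabilities(spec_od, sim_rates, mort01, small_design)
        ec = expected_counts(probs, small_design)
        c = simulated_cohort.counts.counts
        n_part = simulated_cohort.counts.n_participants
        scale = n_part / small_design.n_participants
        assert c["prevalent_normal"] == pytest.approx(
            ec["prevalent_normal"] * scale, rel=0.01
        )
        assert c["repeat_normal"] == pytest.approx(ec["repeat_normal"] * scale, rel=0.01)


class TestDesignAndCountsValidation:
    def test_screen_times_must_increase(self):
        with pytest.raises(ValueError):
            ScreeningDesign(
                screen_times=(0.0, 2.0, 2.0),
                followup_T=10.0,
                cohort_size=100,
                participation=0.5,
            )

    def test_followup_must_reach_last_screen(self):
        with pytest.raises(ValueError):
            ScreeningDesign(
                screen_times=(0.0, 2.0, 4.0),
                followup_T=3.0,
                cohort_size=100,
                participation=0.5,
            )

    def test_missing_cells_are_not_zero(self):
        counts = datasets.funen_counts()
        assert counts.counts["pos_unconf_first"] is None
        assert "pos_unconf_first" not in counts.present()

    def test_counts_csv_roundtrip(self, tmp_path):
        counts = datasets.nottingham_counts()
        p = tmp_path / "counts.csv"
        counts.to_csv(p)
        back = DetectionModeCounts.from_csv(p)
        assert back.counts == counts.counts
        assert back.n_participants == counts.n_participants


class TestLogLikelihood:
    def test_zero_counts_give_zero(self, spec_od, sim_rates, mort01, base_design):
        probs = mode_probabilities(spec_od, sim_rates, mort01, base_design)
        counts = DetectionModeCounts(
            counts={m: 0 for m in PARTICIPANT_MODES} | {"refuser_crc": 0},
            n_participants=0,
            n_refusers=0,
        )
        assert log_likelihood(counts, probs) == 0.0

    def test_maximised_at_expected_counts(self, spec_od, mort01, base_design):
        """Multinomial MLE property: counts equal to expectations make the
        generating probabilities the likelihood maximiser."""
        truth = RateParameters(lambda1=0.002, lambda2=0.4, sens_crc=0.6)
        probs = mode_probabilities(spec_od, truth, mort01, base_design)
        n_part, n_ref = 1_000_000, 600_000
        counts = DetectionModeCounts(
            counts={
                "prevalent_crc": round(n_part * probs.participant["prevalent_crc"]),
                "repeat_crc": round(n_part * probs.participant["repeat_crc"]),
                "interval_crc": round(n_part * probs.participant["interval_crc"]),
                "pos_unconf_first": round(n_part * probs.participant["pos_unconf_first"]),
                "pos_unconf_repeat": round(n_part * probs.participant["pos_unconf_repeat"]),
                "refuser_crc": round(n_ref * probs.refuser["refuser_crc"]),
            },
            n_participants=n_part,
            n_refusers=n_ref,
        )
        ll_truth = log_likelihood(counts, probs)
        rng = np.random.default_rng(0)
        for _ in range(20):
            r = RateParameters(
                lambda1=0.002 * rng.uniform(0.6, 1.6),
                lambda2=0.4 * rng.uniform(0.6, 1.6),
                sens_crc=float(rng.uniform(0.2, 0.95)),
            )
            ll = log_likelihood(counts, mode_probabilities(spec_od, r, mort01, base_design))
            assert ll <= ll_truth + 1e-6

    def test_truth_beats_perturbed_rates_on_simulated_counts(
        self, spec_od, sim_rates, mort01, small_design, simulated_cohort
    ):
        probs_t = mode_probabilities(spec_od, sim_rates, mort01, small_design)
        ll_t = log_likelihood(simulated_cohort.counts, probs_t)
        for factor in (0.5, 1.5):
            r = sim_rates.replace(
                lambda1=sim_rates.lambda1 * factor, lambda2=sim_rates.lambda2 * factor
            )
            ll = log_likelihood(
                simulated_cohort.counts,
                mode_probabilities(spec_od, r, mort01, small_design),
            )
            assert ll < ll_t

    def test_zero_probability_with_count_warns_not_raises(
        self, spec_od, mort0, base_design
    ):
        r = RateParameters(lambda1=0.002, lambda2=0.4, sens_crc=0.0)
        probs = mode_probabilities(spec_od, r, mort0, base_design)
        counts = DetectionModeCounts(
            counts={"prevalent_crc": 5, "refuser_crc": 0},
            n_participants=1000,
            n_refusers=100,
        )
        with pytest.warns(RuntimeWarning):
            assert log_likelihood(counts, probs) == -math.inf
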