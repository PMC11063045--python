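"""Decision curves: closed-form identities, empirical agreement, dominance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundus_dca import (
    ClassifierSpec,
    CohortSpec,
    Strategy,
    build_curves,
    combined_screening,
    default_grid,
    dominance_intervals,
    nb_empirical,
    nb_test_closed,
    nb_treat_all,
    nb_treat_none,
    simulate_cohort,
)
from fundus_dca.dca import TEST, curves_to_frame


class TestClosedForm:
    def test_perfect_test_net_benefit_equals_prevalence(self):
        for p_t in (0.01, 0.3, 0.9):
            pt = nb_test_closed(1.0, 1.0, 0.07, p_t)
            assert pt.net_benefit == pytest.approx(0.07)
            assert pt.false_positive_count == 0.0

    def test_never_positive_test_is_zero(self):
        for p_t in (0.05, 0.5, 0.95):
            assert nb_test_closed(0.0, 1.0, 0.2, p_t).net_benefit == 0.0

    def test_hand_arithmetic_at_reference_operating_point(self):
        # sens .7596, spec .9247, prevalence .05, p_t = 0.10, n = 100k
        pt = nb_test_closed(0.7596, 0.9247, 0.05, 0.10, 100_000)
        tp = 100_000 * 0.05 * 0.7596
        fp = 100_000 * 0.95 * (1 - 0.9247)
        assert pt.true_positive_count == pytest.approx(tp)
        assert pt.false_positive_count == pytest.approx(fp)
        assert pt.net_benefit == pytest.approx(tp / 100_000 - (1 / 9) * fp / 100_000)

    def test_threshold_must_be_interior(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                nb_test_closed(0.9, 0.9, 0.1, bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(sens=st.floats(0, 1), spec=st.floats(0, 1),
           prev=st.floats(0, 1), p_t=st.floats(0.01, 0.99))
    def test_identity_and_n_invariance(self, sens, spec, prev, p_t):
        # NB = TP/n - w*FP/n holds exactly and per-person NB ignores n
        a = nb_test_closed(sens, spec, prev, p_t, 1_000)
        b = nb_test_closed(sens, spec, prev, p_t, 250_000)
        w = p_t / (1 - p_t)
        assert a.net_benefit == pytest.approx(
            a.true_positive_count / a.n - w * a.false_positive_count / a.n, abs=1e-15
        )
        assert a.net_benefit == pytest.approx(b.net_benefit, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(prev1=st.floats(0.01, 0.4), delta=st.floats(0.01, 0.4),
           p_t=st.floats(0.01, 0.99))
    def test_net_benefit_increases_with_prevalence(self, prev1, delta, p_t):
        lo = nb_test_closed(0.76, 0.92, prev1, p_t).net_benefit
        hi = nb_test_closed(0.76, 0.92, prev1 + delta, p_t).net_benefit
        assert hi > lo


class TestReferenceStrategies:
    def test_treat_all_crosses_zero_at_prevalence(self):
        prev = 0.07
        assert nb_treat_all(prev, prev).net_benefit == pytest.approx(0.0, abs=1e-15)
        assert nb_treat_all(prev, prev - 0.01).net_benefit > 0
        assert nb_treat_all(prev, prev + 0.01).net_benefit < 0

    def test_treat_all_small_threshold_limit_is_prevalence(self):
        assert nb_treat_all(0.1, 1e-9).net_benefit == pytest.approx(0.1, abs=1e-8)

    def test_treat_all_direct_arithmetic(self):
        assert nb_treat_all(0.1, 0.2).net_benefit == pytest.approx(-0.125)

    def test_treat_none_is_identically_zero(self):
        for p_t in (0.01, 0.5, 0.99):
            assert nb_treat_none(p_t).net_benefit == 0.0


class TestEmpirical:
    def test_perfect_predictions_give_disease_fraction(self, perfect_records):
        frac = (perfect_records["true_class"] != "normal").mean()
        for p_t in (0.05, 0.4):
            pt = nb_empirical(perfect_records, p_t, positive_class="any")
            assert pt.net_benefit == pytest.approx(frac)

    def test_no_disease_no_false_positives_gives_zero(self):
        records = pd.DataFrame(
            {"record_id": ["a", "b"], "true_class": "normal",
             "predicted_class": "normal", "model_name": "m"}
        )
        assert nb_empirical(records, 0.3, positive_class="any").net_benefit == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            nb_empirical(pd.DataFrame(columns=["true_class", "predicted_class"]), 0.1)

    def test_matches_closed_form_on_simulated_cohort(
        self, simulated_urban_cohort, urban_spec, retfound_clf
    ):
        # Monte-Carlo route vs closed form within 4 propagated binomial SDs
        prev = sum(urban_spec.prevalence_by_disease.values())
        sens, spec, prev_c = combined_screening(
            retfound_clf.sensitivity_by_disease,
            urban_spec.prevalence_by_disease,
            retfound_clf.specificity,
        )
        assert prev_c == pytest.approx(prev)
        n = urban_spec.cohort_size
        p_tp = prev * sens
        p_fp = (1 - prev) * (1 - spec)
        for p_t in (0.02, 0.10, 0.30, 0.70):
            w = p_t / (1 - p_t)
            closed = nb_test_closed(sens, spec, prev, p_t, n).net_benefit
            emp = nb_empirical(simulated_urban_cohort, p_t,
                               positive_class="any").net_benefit
            sd = math.sqrt(
                (p_tp * (1 - p_tp) + w**2 * p_fp * (1 - p_fp)) / n
            )
            assert abs(emp - closed) < 4 * sd


class TestCombinedScreening:
    def test_single_disease_passthrough(self):
        sens, spec, prev = combined_screening({"D": 0.8}, {"D": 0.05}, 0.9)
        assert (sens, spec, prev) == pytest.approx((0.8, 0.9, 0.05))

    def test_equal_prevalence_weights_average_sensitivity(self):
        sens, _, prev = combined_screening(
            {"A": 0.8, "B": 0.6}, {"A": 0.02, "B": 0.02}, 0.9
        )
        assert sens == pytest.approx(0.7)
        assert prev == pytest.approx(0.04)

    def test_reference_operating_points_weighted_mean(self):
        sens_by = {"AMD": 218 / 287, "DR": 321 / 337, "PM": 151 / 151}
        prev_by = {"AMD": 0.05, "DR": 0.03, "PM": 0.01}
        sens, spec, prev = combined_screening(sens_by, prev_by, 1031 / 1115)
        want = (0.05 * sens_by["AMD"] + 0.03 * sens_by["DR"]
                + 0.01 * sens_by["PM"]) / 0.09
        assert sens == pytest.approx(want)
        assert prev == pytest.approx(0.09)
        assert spec == 1031 / 1115

    def test_empty_and_saturated_inputs_rejected(self):
        with pytest.raises(ValueError):
            combined_screening({}, {}, 0.9)
        with pytest.raises(ValueError):
            combined_screening({"A": 0.8, "B": 0.6}, {"A": 0.6, "B": 0.5}, 0.9)


class TestCurves:
    def test_test_curve_nonincreasing_in_threshold(self):
        curves = build_curves(
            [Strategy(TEST, "m", sensitivity=0.76, specificity=0.92)], 0.05
        )
        test_curve = next(c for c in curves if c.strategy.kind == TEST)
        nb = test_curve.net_benefits
        assert (np.diff(nb) <= 1e-15).all()

    def test_references_appended_automatically(self):
        curves = build_curves(
            [Strategy(TEST, "m", sensitivity=1.0, specificity=1.0)], 0.1
        )
        kinds = {c.strategy.kind for c in curves}
        assert kinds == {"test", "treat_all", "treat_none"}

    def test_perfect_test_dominates_treat_all_everywhere(self):
        curves = build_curves(
            [Strategy(TEST, "m", sensitivity=1.0, specificity=1.0)], 0.1
        )
        by_kind = {c.strategy.kind: c for c in curves}
        assert (by_kind["test"].net_benefits
                > by_kind["treat_all"].net_benefits).all()

    def test_grid_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            build_curves([Strategy(TEST, "m", sensitivity=1, specificity=1)],
                         0.1, grid=np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            default_grid(0.0, 0.99, 0.01)

    def test_strategy_requires_matching_performance(self):
        with pytest.raises(ValueError):
            Strategy(TEST, "m")
        with pytest.raises(ValueError):
            Strategy("treat_all", "all", sensitivity=0.9, specificity=0.9)

    def test_curves_frame_layout(self):
        curves = build_curves(
            [Strategy(TEST, "m", sensitivity=0.8, specificity=0.9)], 0.05,
            grid=default_grid(0.1, 0.3, 0.1), setting_label="urban",
        )
        frame = curves_to_frame(curves)
        assert list(frame.columns) == [
            "setting", "strategy", "threshold", "tp", "fp", "n", "net_benefit"
        ]
        assert len(frame) == 3 * 3  # 3 strategies x 3 thresholds


class TestDominance:
    def test_uniform_winner_spans_grid(self):
        grid = default_grid(0.01, 0.2, 0.01)
        curves = build_curves(
            [Strategy(TEST, "good", sensitivity=1.0, specificity=1.0)],
            prevalence=0.1, grid=grid,
        )
        ivs = dominance_intervals(curves)
        winner = [iv for iv in ivs if iv.strategy_label == "good"]
        assert len(winner) == 1
        assert winner[0].lower == pytest.approx(grid[0])
        assert winner[0].upper == pytest.approx(grid[-1])

    def test_identical_curves_yield_no_intervals(self):
        grid = default_grid(0.1, 0.5, 0.1)
        a = build_curves([Strategy(TEST, "a", sensitivity=0.8, specificity=0.9)],
                         0.05, grid=grid)[0]
        b = build_curves([Strategy(TEST, "b", sensitivity=0.8, specificity=0.9)],
                         0.05, grid=grid)[0]
        assert dominance_intervals([a, b]) == []

    def test_crossing_curves_split_at_known_threshold(self):
        # test vs treat-all vs treat-none with prevalence 0.1: treat-all
        # wins below the crossing, the imperfect test wins after it, and
        # nobody beats treat-none far to the right once NB goes negative.
        # verify against a dense brute-force scan of the closed forms.
        prev, sens, spec = 0.1, 0.8, 0.95
        grid = default_grid(0.01, 0.99, 0.01)
        curves = build_curves(
            [Strategy(TEST, "test", sensitivity=sens, specificity=spec)],
            prev, grid=grid,
        )
        ivs = dominance_intervals(curves)

        def winner_at(p_t):
            w = p_t / (1 - p_t)
            nb = {
                "test": prev * sens - w * (1 - prev) * (1 - spec),
                "treat all": prev - w * (1 - prev),
                "treat none": 0.0,
            }
            top = max(nb.values())
            leads = [k for k, v in nb.items() if v == top]
            return leads[0] if len(leads) == 1 else None

        for iv in ivs:
            for p_t in np.round(np.arange(iv.lower, iv.upper + 1e-9, 0.01), 10):
                assert winner_at(float(p_t)) == iv.strategy_label

    def test_mismatched_grids_rejected(self):
        a = build_curves([Strategy(TEST, "a", sensitivity=0.8, specificity=0.9)],
                         0.05, grid=default_grid(0.1, 0.5, 0.1))[0]
        b = build_curves([Strategy(TEST, "b", sensitivity=0.8, specificity=0.9)],
                         0.05, grid=default_grid(0.1, 0.4, 0.1))[0]
        with pytest.raises(ValueError, match="grid"):
            dominance_intervals([a, b])
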