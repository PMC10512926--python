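"""Unit and property tests for renal angina scoring."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from renangia import (
    ConfigurationError,
    InvalidInputError,
    PatientRecord,
    compute_mrai,
    compute_rai,
    delta_scr,
    enumerate_achievable_scores,
    impute_baseline_scr,
    injury_score,
    load_score_config,
    mrai_local,
    percent_fluid_overload,
    rai_original,
    risk_score,
)
from renangia.scoring import ScoreConfig


def make_record(**overrides):
    base = dict(
        patient_id="T1",
        age_years=3.0,
        sex="female",
        height_cm=95.0,
        weight_kg=14.0,
        diagnosis_category="CNS",
        d0_scr_umol_l=30.0,
        d3_scr_umol_l=30.0,
    )
    base.update(overrides)
    return PatientRecord(**base)


class TestBaselineImputation:
    def test_height_equal_to_assumed_clearance_returns_k(self):
        # 36.5 * 120 / 120
        assert impute_baseline_scr(120.0, rai_original()) == pytest.approx(36.5)

    def test_hand_computed_value(self):
        assert impute_baseline_scr(110.0, rai_original()) == pytest.approx(36.5 * 110 / 120)

    @pytest.mark.parametrize("height", [0.0, -10.0])
    def test_nonpositive_height_rejected(self, height):
        with pytest.raises(InvalidInputError, match="height"):
            impute_baseline_scr(height, rai_original())

    @given(
        height=st.floats(40.0, 200.0),
        scale=st.floats(0.5, 3.0),
    )
    def test_linear_in_height_inverse_in_clearance(self, height, scale):
        config = rai_original()
        base = impute_baseline_scr(height, config)
        assert impute_baseline_scr(height * scale, config) == pytest.approx(base * scale)
        rescaled = config.model_copy(update={"assumed_ecrcl": config.assumed_ecrcl * scale})
        assert impute_baseline_scr(height, rescaled) == pytest.approx(base / scale)


class TestDeltaScrAndFluidOverload:
    def test_ratio(self):
        assert delta_scr(48.0, 28.7) == pytest.approx(48.0 / 28.7)
        assert delta_scr(70.2, 35.1) == pytest.approx(2.0)

    @given(x=st.floats(1.0, 500.0))
    def test_identity_ratio(self, x):
        assert delta_scr(x, x) == 1.0

    @pytest.mark.parametrize("enroll,base", [(0, 30), (30, 0), (-1, 30), (30, -1)])
    def test_nonpositive_creatinine_rejected(self, enroll, base):
        with pytest.raises(InvalidInputError):
            delta_scr(enroll, base)

    @pytest.mark.parametrize(
        "fin,fout,w,expected",
        [(1.0, 0.6, 10.0, 4.0), (1.3, 1.3, 9.0, 0.0), (2.0, 0.0, 8.0, 25.0), (0.2, 0.8, 6.0, -10.0)],
    )
    def test_percent_fo(self, fin, fout, w, expected):
        assert percent_fluid_overload(fin, fout, w) == pytest.approx(expected)

    def test_missing_fluid_yields_unavailable_not_zero(self):
        assert percent_fluid_overload(None, 0.5, 10.0) is None
        assert percent_fluid_overload(0.5, None, 10.0) is None

    def test_bad_weight_rejected(self):
        with pytest.raises(InvalidInputError, match="weight"):
            percent_fluid_overload(1.0, 0.5, 0.0)


class TestRiskScore:
    def test_icu_only_is_lowest_stratum(self):
        assert risk_score(make_record(), rai_original()) == 1

    def test_ventilation_and_vasopressors_is_highest_stratum(self):
        r = make_record(mechanical_ventilation_8h=True, vasopressor_support_8h=True)
        assert risk_score(r, rai_original()) == 5

    def test_ventilation_alone_is_not_the_highest_stratum(self):
        r = make_record(mechanical_ventilation_8h=True)
        assert risk_score(r, rai_original()) == 1

    def test_transplant_is_middle_stratum(self):
        assert risk_score(make_record(transplant_history=True), rai_original()) == 3

    def test_original_mode_takes_max_not_sum(self):
        r = make_record(
            transplant_history=True,
            mechanical_ventilation_8h=True,
            vasopressor_support_8h=True,
        )
        assert risk_score(r, rai_original()) == 5

    def test_mrai_mode_sums_applicable_weights(self):
        # icu(1) + sepsis(7) + age<=5(3) under the local preset
        r = make_record(diagnosis_category="sepsis")
        assert risk_score(r, mrai_local()) == 11

    def test_empty_weights_is_configuration_error(self):
        config = rai_original().model_copy(update={"risk_weights": {}})
        with pytest.raises(ConfigurationError):
            risk_score(make_record(), config)


class TestInjuryScore:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0.8, 1), (1.0, 1), (1.0001, 2), (1.2, 2), (1.49, 2), (1.5, 4), (1.7, 4), (1.99, 4), (2.0, 8), (3.5, 8)],
    )
    def test_dscr_tiers_closed_left_open_right(self, delta, expected):
        assert injury_score(delta, None, rai_original()) == expected

    @pytest.mark.parametrize(
        "fo,expected", [(0.0, 1), (4.99, 1), (5.0, 2), (9.9, 2), (10.0, 4), (14.9, 4), (15.0, 8), (30.0, 8)]
    )
    def test_fo_tiers(self, fo, expected):
        assert injury_score(1.0, fo, rai_original()) == expected

    def test_combined_signals_take_max(self):
        assert injury_score(1.2, 16.0, rai_original()) == 8
        assert injury_score(2.4, 6.0, rai_original()) == 8

    def test_mrai_mode_ignores_fluid_overload(self):
        assert injury_score(1.2, 16.0, mrai_local()) == 2

    @given(
        d1=st.floats(0.5, 4.0),
        d2=st.floats(0.5, 4.0),
        fo=st.one_of(st.none(), st.floats(-5.0, 30.0)),
    )
    def test_monotone_in_delta(self, d1, d2, fo):
        config = rai_original()
        lo, hi = sorted([d1, d2])
        assert injury_score(lo, fo, config) <= injury_score(hi, fo, config)

    @given(delta=st.floats(0.5, 4.0), fo=st.floats(-5.0, 30.0))
    def test_two_signal_score_is_the_pairwise_max(self, delta, fo):
        config = rai_original()
        both = injury_score(delta, fo, config)
        assert both == max(injury_score(delta, None, config), injury_score(1.0, fo, config))


class TestComputeRai:
    def test_positive_at_eight(self):
        r = make_record(baseline_scr_umol_l=30.0, d0_scr_umol_l=66.0)  # delta 2.2 -> injury 8
        result = compute_rai(r, rai_original())
        assert (result.risk_score, result.injury_score, result.rai) == (1, 8, 8)
        assert result.positive and not result.imputed_baseline

    def test_negative_below_eight(self):
        r = make_record(baseline_scr_umol_l=30.0, d0_scr_umol_l=48.0)  # delta 1.6 -> injury 4
        result = compute_rai(r, rai_original())
        assert result.rai == 4 and not result.positive

    def test_maximum_product(self):
        r = make_record(
            baseline_scr_umol_l=30.0,
            d0_scr_umol_l=66.0,
            mechanical_ventilation_8h=True,
            vasopressor_support_8h=True,
        )
        assert compute_rai(r, rai_original()).rai == 40

    def test_imputed_baseline_flagged(self):
        r = make_record(baseline_scr_umol_l=None)
        result = compute_rai(r, rai_original())
        assert result.imputed_baseline
        assert result.baseline_scr_umol_l == pytest.approx(36.5 * 95.0 / 120.0)

    def test_fo_unavailable_flagged(self):
        result = compute_rai(make_record(), rai_original())
        assert not result.fo_available and result.percent_fo is None
        with_fo = compute_rai(
            make_record(fluid_in_l_8h=1.0, fluid_out_l_8h=0.6), rai_original()
        )
        assert with_fo.fo_available and with_fo.percent_fo == pytest.approx(100 * 0.4 / 14.0)

    def test_missing_baseline_and_height_names_both_fields(self):
        with pytest.raises(ValueError, match="baseline_scr_umol_l.*height_cm"):
            make_record(baseline_scr_umol_l=None, height_cm=None)

    def test_mrai_multiplies_risk_sum_by_creatinine_score(self):
        r = make_record(
            diagnosis_category="sepsis",
            baseline_scr_umol_l=30.0,
            d0_scr_umol_l=39.0,  # delta 1.3 -> creatinine score 2
        )
        result = compute_mrai(r, mrai_local())
        assert (result.risk_score, result.injury_score, result.rai) == (11, 2, 22)

    def test_mrai_requires_mrai_mode(self):
        with pytest.raises(ConfigurationError):
            compute_mrai(make_record(), rai_original())


def brute_force_scores(risk_values, injuries):
    return sorted({r * i for r, i in itertools.product(risk_values, injuries)})


class TestAchievableScores:
    def test_original_config_matches_brute_force(self):
        # oracle: risk strata {1,3,5} (max semantics) x injury {1,2,4,8}
        expected = brute_force_scores([1, 3, 5], [1, 2, 4, 8])
        assert enumerate_achievable_scores(rai_original()) == expected

    def test_degenerate_single_weight(self):
        config = ScoreConfig(
            risk_weights={"icu_admission": 1},
            injury_dscr_tiers=(),
            injury_fo_tiers=(),
        )
        assert enumerate_achievable_scores(config) == [1]

    def test_mrai_preset_matches_subset_enumeration_oracle(self):
        config = mrai_local()
        togglable = {k: v for k, v in config.risk_weights.items() if k != "icu_admission"}
        sums = set()
        for k in range(len(togglable) + 1):
            for combo in itertools.combinations(togglable.values(), k):
                sums.add(1 + sum(combo))
        expected = brute_force_scores(sums, [1, 2, 4, 8])
        assert enumerate_achievable_scores(config) == expected
        assert max(expected) == 160  # 20 x 8, the top of the achievable range

    def test_every_original_rai_is_achievable_and_positivity_set_is_exact(self):
        config = rai_original()
        achievable = set(enumerate_achievable_scores(config))
        positives = set()
        for vent_vaso, transplant in itertools.product([False, True], repeat=2):
            for delta in (1.0, 1.2, 1.7, 2.2):
                r = make_record(
                    baseline_scr_umol_l=30.0,
                    d0_scr_umol_l=30.0 * delta,
                    mechanical_ventilation_8h=vent_vaso,
                    vasopressor_support_8h=vent_vaso,
                    transplant_history=transplant,
                )
                result = compute_rai(r, config)
                assert result.rai == result.risk_score * result.injury_score
                assert result.rai in achievable
                if result.positive:
                    positives.add(result.rai)
        assert positives == {s for s in achievable if s >= 8}
        assert positives == {8, 10, 12, 20, 24, 40}


class TestConfigLoading:
    def test_presets_load_by_name(self, tmp_path):
        assert not load_score_config("rai_original").mrai_mode
        assert load_score_config("mrai_local").mrai_mode

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        config = rai_original()
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(config.model_dump(mode="json")))
        assert load_score_config(path) == config

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            load_score_config("no_such_preset")

    def test_tier_ordering_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            ScoreConfig(
                risk_weights={"icu_admission": 1},
                injury_dscr_tiers=(
                    {"lower": 2.0, "score": 2},
                    {"lower": 1.5, "score": 4},
                ),
            )
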