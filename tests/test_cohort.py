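"""Patient/cohort model: LDL-C derivation, goal logic, eligibility waterfall."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lltsim import (
    Cohort,
    LipidPanel,
    Patient,
    Regimen,
    RiskLevel,
    StatinIntensity,
    WaterfallReport,
    apply_eligibility_filter,
    friedewald_ldl,
    goal_threshold,
    is_at_goal,
    mgdl_from_mmol,
    resolve_ldl,
    summarize_baseline,
)
from lltsim.errors import (
    DataInconsistencyError,
    EmptyCohortError,
    FriedewaldInvalidError,
    UnclassifiableRiskError,
    ValidationError,
)


def make_patient(pid="p1", risk=RiskLevel.VERY_HIGH, ldl=80.0,
                 intensity=StatinIntensity.HIGH, **flags):
    return Patient(
        patient_id=pid,
        risk=risk,
        regimen=Regimen(statin_intensity=intensity, **flags),
        ldl_baseline=ldl,
    )


class TestFriedewald:
    @pytest.mark.parametrize(
        "tc,hdl,tg,expected",
        [(200, 50, 150, 120.0), (100, 100, 0, 0.0), (180, 45, 100, 115.0)],
    )
    def test_formula(self, tc, hdl, tg, expected):
        panel = LipidPanel(total_cholesterol=tc, hdl_cholesterol=hdl, triglycerides=tg)
        assert friedewald_ldl(panel) == pytest.approx(expected)

    def test_high_triglycerides_invalid(self):
        panel = LipidPanel(total_cholesterol=180, hdl_cholesterol=40, triglycerides=450)
        with pytest.raises(FriedewaldInvalidError):
            friedewald_ldl(panel)

    def test_negative_estimate_is_inconsistent(self):
        panel = LipidPanel(total_cholesterol=100, hdl_cholesterol=120, triglycerides=100)
        with pytest.raises(DataInconsistencyError):
            friedewald_ldl(panel)

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError):
            friedewald_ldl(LipidPanel(total_cholesterol=180, hdl_cholesterol=50))

    @given(
        tc=st.floats(100, 300),
        hdl=st.floats(20, 80),
        tg=st.floats(0, 350),
        k=st.floats(0, 50),
    )
    def test_linear_in_total_cholesterol(self, tc, hdl, tg, k):
        base = LipidPanel(total_cholesterol=tc + 100, hdl_cholesterol=hdl, triglycerides=tg)
        shifted = LipidPanel(
            total_cholesterol=tc + 100 + k, hdl_cholesterol=hdl, triglycerides=tg
        )
        assert friedewald_ldl(shifted) - friedewald_ldl(base) == pytest.approx(k, abs=1e-9)

    def test_direct_measurement_wins_over_formula(self):
        p = Patient(
            patient_id="x",
            panel=LipidPanel(
                total_cholesterol=200, hdl_cholesterol=50, triglycerides=150,
                ldl_direct=99.0,
            ),
        )
        assert resolve_ldl(p) == 99.0


class TestUnitsAndGoals:
    def test_mmol_conversion(self):
        assert mgdl_from_mmol(1.0) == pytest.approx(38.67)
        assert mgdl_from_mmol(0.0) == 0.0

    def test_goal_thresholds(self):
        assert goal_threshold(RiskLevel.HIGH) == 70.0
        assert goal_threshold(RiskLevel.VERY_HIGH) == 55.0
        with pytest.raises(UnclassifiableRiskError):
            goal_threshold(RiskLevel.MISSING)

    def test_thresholds_coherent_with_mmol_goals(self):
        # guideline goals are stated both in mg/dL and mmol/L; the mg/dL
        # values are primary and agree with the converted ones within rounding
        assert abs(goal_threshold(RiskLevel.HIGH) - mgdl_from_mmol(1.8)) < 1.0
        assert abs(goal_threshold(RiskLevel.VERY_HIGH) - mgdl_from_mmol(1.4)) < 1.0

    @pytest.mark.parametrize(
        "ldl,risk,expected",
        [
            (54.9, RiskLevel.VERY_HIGH, True),
            (55.0, RiskLevel.VERY_HIGH, False),  # strict '<' at the boundary
            (69.0, RiskLevel.HIGH, True),
            (70.0, RiskLevel.HIGH, False),
        ],
    )
    def test_at_goal_strict(self, ldl, risk, expected):
        assert is_at_goal(ldl, risk) is expected

    @given(ldl=st.floats(0, 200), vh=st.booleans())
    def test_at_goal_matches_brute_force(self, ldl, vh):
        risk = RiskLevel.VERY_HIGH if vh else RiskLevel.HIGH
        brute = ldl < (55.0 if vh else 70.0)
        assert is_at_goal(ldl, risk) == brute


class TestEligibilityFilter:
    def test_clean_cohort_is_untouched(self):
        cohort = Cohort([make_patient(pid=f"p{i}") for i in range(5)])
        out, report = apply_eligibility_filter(cohort)
        assert [p.patient_id for p in out] == [p.patient_id for p in cohort]
        assert report.stage_counts == (5, 5, 5, 5, 5, 5)

    def test_pcsk9i_only_cohort_is_emptied(self):
        cohort = Cohort(
            [make_patient(pid=f"p{i}", on_pcsk9i=True) for i in range(3)]
        )
        out, report = apply_eligibility_filter(cohort)
        assert len(out) == 0
        assert report.stage_counts == (3, 3, 3, 3, 3, 0)

    def test_first_failing_stage_counts(self):
        patients = [
            make_patient("ok"),
            Patient(patient_id="no_ldl", risk=RiskLevel.HIGH,
                    regimen=Regimen(statin_intensity=StatinIntensity.HIGH)),
            make_patient("no_risk", risk=RiskLevel.MISSING),
            make_patient("unk", intensity=StatinIntensity.UNKNOWN),
            make_patient("no_llt", intensity=StatinIntensity.NONE),
            make_patient("pcsk9", on_pcsk9i=True),
        ]
        out, report = apply_eligibility_filter(Cohort(patients))
        assert report.stage_counts == (6, 5, 4, 3, 2, 1)
        assert [p.patient_id for p in out] == ["ok"]

    def test_ldl_is_resolved_by_filter(self):
        p = Patient(
            patient_id="panel_only",
            risk=RiskLevel.HIGH,
            regimen=Regimen(statin_intensity=StatinIntensity.MODERATE),
            panel=LipidPanel(total_cholesterol=200, hdl_cholesterol=50, triglycerides=150),
        )
        out, _ = apply_eligibility_filter(Cohort([p]))
        assert out.patients[0].ldl_baseline == pytest.approx(120.0)

    def test_other_llt_only_patients_are_retained(self):
        p = make_patient("other", intensity=StatinIntensity.NONE, on_other_llt=True)
        out, _ = apply_eligibility_filter(Cohort([p]))
        assert len(out) == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(EmptyCohortError):
            apply_eligibility_filter(Cohort([]))

    def test_waterfall_must_be_non_increasing(self):
        with pytest.raises(ValueError):
            WaterfallReport(stage_names=("a", "b"), stage_counts=(3, 5))


class TestBaselineSummary:
    def test_single_patient_degenerate(self):
        s = summarize_baseline(Cohort([make_patient(ldl=40.0)]))
        assert s.n == 1
        assert s.ldl_mean == 40.0
        assert s.ldl_sd == 0.0
        assert s.frac_at_goal == 1.0

    def test_two_patient_arithmetic(self):
        cohort = Cohort([make_patient("a", ldl=50.0), make_patient("b", ldl=90.0)])
        s = summarize_baseline(cohort)
        assert s.ldl_mean == pytest.approx(70.0)
        assert s.frac_below[55.0] == pytest.approx(0.5)

    def test_regimen_counts(self):
        cohort = Cohort(
            [
                make_patient("a", on_ezetimibe=True),
                make_patient("b", intensity=StatinIntensity.LOW),
                make_patient("c", intensity=StatinIntensity.NONE, on_other_llt=True),
            ]
        )
        s = summarize_baseline(cohort)
        assert s.n_on_statin == 2
        assert s.n_on_ezetimibe == 1
        assert s.n_statin_by_intensity == {"high": 1, "low": 1}

    def test_unadmitted_patient_rejected(self):
        with pytest.raises(ValueError):
            summarize_baseline(Cohort([make_patient(risk=RiskLevel.MISSING)]))


class TestCohortIO:
    def test_csv_round_trip(self, tmp_path, sim_cohort):
        path = tmp_path / "cohort.csv"
        sim_cohort.to_csv(path)
        back = Cohort.from_csv(path)
        assert len(back) == len(sim_cohort)
        for a, b in zip(sim_cohort, back):
            assert a.patient_id == b.patient_id
            assert a.risk == b.risk
            assert a.regimen == b.regimen
            assert resolve_ldl(b) == pytest.approx(a.ldl_baseline)

    def test_unknown_risk_label_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "patient_id,risk,statin_intensity,on_ezetimibe,on_pcsk9i,on_other_llt,"
            "ldl_mgdl,tc_mgdl,hdl_mgdl,tg_mgdl\n"
            "p1,hgih,high,0,0,0,80,,,\n"
        )
        with pytest.raises(ValidationError) as exc:
            Cohort.from_csv(path)
        assert any("row 2" in item and "risk" in item for item in exc.value.items)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            Cohort([make_patient("a"), make_patient("a")])
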