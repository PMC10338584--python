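"""Intensification pathway and Monte Carlo engine."""

import numpy as np
import pytest

from lltsim import (
    Cohort,
    EfficacyPoolRule,
    FixedRatio,
    FixedReduction,
    Patient,
    PathwayStep,
    Regimen,
    RiskLevel,
    SimulationConfig,
    StatinIntensity,
    ldl_cutoff_proportions,
    run_monte_carlo,
    run_replicate,
    simulate_patient,
)


def _patient(pid="p", ldl=80.0, risk=RiskLevel.VERY_HIGH,
             intensity=StatinIntensity.HIGH, on_ezetimibe=False):
    return Patient(
        patient_id=pid,
        risk=risk,
        regimen=Regimen(statin_intensity=intensity, on_ezetimibe=on_ezetimibe),
        ldl_baseline=ldl,
    )


def _forced_rule(reduction=0.25, ratio=0.9):
    """Deterministic efficacy draws for hand-traceable pathways."""
    return EfficacyPoolRule(
        ezetimibe=FixedReduction(reduction),
        pool_moderate_high=FixedRatio(ratio),
        pool_none_low=FixedRatio(ratio),
    )


class TestSimulatePatient:
    def test_at_goal_at_baseline_untouched(self):
        cfg = SimulationConfig(n_reps=1, master_seed=0)
        path = simulate_patient(_patient(ldl=50.0), cfg, np.random.default_rng(0))
        assert path.ldl == (50.0, 50.0, 50.0)
        assert path.at_goal == (True, True, True)
        assert not path.ezetimibe_added and not path.bempedoic_added

    def test_hand_traced_two_step_pathway(self):
        # 80 mg/dL very-high risk: forced 25% ezetimibe reduction gives 60
        # (still >= 55), forced 0.9 bempedoic ratio gives 54 -> at goal
        cfg = SimulationConfig(n_reps=1, master_seed=0, efficacy=_forced_rule())
        path = simulate_patient(_patient(ldl=80.0), cfg, np.random.default_rng(0))
        assert path.ldl == pytest.approx((80.0, 60.0, 54.0))
        assert path.at_goal == (False, False, True)
        assert path.ezetimibe_added and path.bempedoic_added

    def test_baseline_ezetimibe_user_skips_to_bempedoic(self):
        cfg = SimulationConfig(n_reps=1, master_seed=0, efficacy=_forced_rule())
        path = simulate_patient(
            _patient(ldl=80.0, on_ezetimibe=True), cfg, np.random.default_rng(0)
        )
        assert path.ldl == pytest.approx((80.0, 80.0, 72.0))
        assert not path.ezetimibe_added
        assert path.bempedoic_added

    def test_stops_once_goal_reached_after_ezetimibe(self):
        cfg = SimulationConfig(
            n_reps=1, master_seed=0, efficacy=_forced_rule(reduction=0.5)
        )
        path = simulate_patient(_patient(ldl=80.0), cfg, np.random.default_rng(0))
        assert path.ldl == pytest.approx((80.0, 40.0, 40.0))
        assert path.ezetimibe_added and not path.bempedoic_added

    def test_unadmitted_patient_rejected(self):
        cfg = SimulationConfig(n_reps=1)
        bad = Patient(patient_id="x", risk=RiskLevel.MISSING, ldl_baseline=80.0)
        with pytest.raises(ValueError):
            simulate_patient(bad, cfg, np.random.default_rng(0))


class TestRunReplicate:
    def test_all_at_goal_cohort_is_invariant_to_seed(self):
        cohort = Cohort([_patient(pid=f"p{i}", ldl=40.0) for i in range(4)])
        cfg = SimulationConfig(n_reps=1, master_seed=123)
        rep = run_replicate(cohort, cfg, 0)
        assert np.all(rep.ldl == 40.0)
        assert rep.at_goal.all()
        assert not rep.ezetimibe_added.any()
        assert not rep.bempedoic_added.any()

    def test_bit_identical_replay(self, sim_cohort):
        cfg = SimulationConfig(n_reps=1, master_seed=99)
        a = run_replicate(sim_cohort, cfg, 3)
        b = run_replicate(sim_cohort, cfg, 3)
        assert np.array_equal(a.ldl, b.ldl)
        assert np.array_equal(a.at_goal, b.at_goal)

    def test_matches_scalar_pathway_under_forced_draws(self):
        cohort = Cohort(
            [
                _patient("a", ldl=50.0),
                _patient("b", ldl=80.0),
                _patient("c", ldl=80.0, on_ezetimibe=True),
                _patient("d", ldl=90.0, intensity=StatinIntensity.NONE),
            ]
        )
        cfg = SimulationConfig(n_reps=1, master_seed=0, efficacy=_forced_rule())
        rep = run_replicate(cohort, cfg, 0)
        for j, p in enumerate(cohort):
            path = simulate_patient(p, cfg, np.random.default_rng(0))
            assert rep.ldl[:, j] == pytest.approx(path.ldl)
            assert tuple(rep.at_goal[:, j]) == path.at_goal
            assert rep.ezetimibe_added[j] == path.ezetimibe_added
            assert rep.bempedoic_added[j] == path.bempedoic_added

    def test_structural_ezetimibe_additions_are_deterministic(self, sim_cohort):
        # 92 not at goal, of whom 20 already on ezetimibe -> 72 additions
        cfg = SimulationConfig(n_reps=1, master_seed=0)
        for rep_index in range(5):
            rep = run_replicate(sim_cohort, cfg, rep_index)
            assert rep.ezetimibe_added.sum() == 72


@pytest.fixture(scope="module")
def reps(sim_cohort):
    cfg = SimulationConfig(n_reps=1, master_seed=5)
    return [run_replicate(sim_cohort, cfg, i) for i in range(100)]


class TestReplicateInvariants:

    def test_at_goal_count_non_decreasing_across_steps(self, reps):
        for rep in reps:
            counts = rep.at_goal.sum(axis=1)
            assert counts[0] <= counts[1] <= counts[2]

    def test_at_goal_patients_never_retreated(self, reps):
        for rep in reps:
            goal0 = rep.at_goal[0]
            assert np.all(rep.ldl[1, goal0] == rep.ldl[0, goal0])
            assert np.all(rep.ldl[2, goal0] == rep.ldl[0, goal0])
            assert not rep.ezetimibe_added[goal0].any()
            assert not rep.bempedoic_added[goal0].any()

    def test_ezetimibe_stage_never_raises_cohort_mean(self, reps):
        for rep in reps:
            assert rep.ldl[1].mean() <= rep.ldl[0].mean()

    def test_added_flags_imply_not_at_goal(self, reps):
        for rep in reps:
            assert not (rep.ezetimibe_added & rep.at_goal[0]).any()
            assert not (rep.bempedoic_added & rep.at_goal[1]).any()


class TestCutoffProportions:
    def test_arithmetic(self):
        cohort = Cohort([_patient("a", ldl=50.0), _patient("b", ldl=60.0)])
        rep = run_replicate(cohort, SimulationConfig(n_reps=1), 0)
        assert ldl_cutoff_proportions(rep, PathwayStep.BASELINE, [55, 70]) == [0.5, 1.0]

    def test_empty_cutoffs(self):
        cohort = Cohort([_patient("a", ldl=50.0)])
        rep = run_replicate(cohort, SimulationConfig(n_reps=1), 0)
        assert ldl_cutoff_proportions(rep, PathwayStep.BASELINE, []) == []


class TestMonteCarlo:
    def test_single_replicate_collapses_quantiles(self, sim_cohort):
        summ = run_monte_carlo(sim_cohort, SimulationConfig(n_reps=1, master_seed=2))
        for step in PathwayStep:
            q = summ.steps[step].mean_ldl
            assert q.median == q.q025 == q.q975

    def test_quantile_ordering_and_goal_monotonicity(self, sim_cohort, small_config):
        summ = run_monte_carlo(sim_cohort, small_config)
        medians = []
        for step in PathwayStep:
            s = summ.steps[step]
            for q in (s.mean_ldl, s.at_goal_count, *s.frac_below.values()):
                assert q.q025 <= q.median <= q.q975
            medians.append(s.at_goal_count.median)
        assert medians[0] <= medians[1] <= medians[2]

    def test_full_run_reproducibility(self, sim_cohort, small_config):
        a = run_monte_carlo(sim_cohort, small_config)
        b = run_monte_carlo(sim_cohort, small_config)
        assert a.to_dict() == b.to_dict()

    def test_end_of_pathway_utilization(self, sim_cohort, small_config):
        summ = run_monte_carlo(sim_cohort, small_config)
        # ezetimibe end count is structural: 35 baseline users + 72 additions
        assert summ.ezetimibe_end_count.median == 107
        assert summ.ezetimibe_end_count.q025 == summ.ezetimibe_end_count.q975 == 107
        # bempedoic count varies with ezetimibe response but is at least the
        # 20 baseline-ezetimibe patients not at goal
        assert summ.bempedoic_end_count.median >= 20

    def test_trace_export(self, sim_cohort, tmp_path):
        trace = tmp_path / "trace.csv"
        cfg = SimulationConfig(n_reps=3, master_seed=1)
        run_monte_carlo(sim_cohort, cfg, trace_file=trace)
        lines = trace.read_text().strip().splitlines()
        assert lines[0].startswith("rep,step,mean_ldl,at_goal_count")
        assert len(lines) == 1 + 3 * len(PathwayStep)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_reps=0)
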