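"""Sequential treatment-intensification pathway and Monte Carlo engine.

The pathway, applied independently to each patient in a cohort:

1. If the baseline LDL-C already meets the risk-based goal, nothing is done.
2. Otherwise, if the patient is not on ezetimibe, ezetimibe is added and a
   beta-distributed fractional reduction is drawn; if the new LDL-C meets
   the goal, the pathway stops.
3. If the patient is still not at goal (or was on ezetimibe at baseline),
   bempedoic acid is added and a lognormal post/pre ratio is drawn from the
   pool matching the patient's statin background.

LDL-C is carried forward unchanged through any step where no drug is added,
and the at-goal comparison is strict (<) at every step.

The Monte Carlo engine repeats the pathway ``n_reps`` times (default
10,000) with fresh efficacy draws each replicate, and summarises the
per-replicate cohort mean LDL-C, at-goal count, below-cutoff fractions and
treatment utilisation by their median and 2.5%/97.5% quantiles.

Reproducibility: replicate ``i`` of a run with master seed ``s`` uses
``numpy.random.default_rng(SeedSequence((s, i)))``.  Within a replicate,
draws are consumed as blocks in cohort order: one beta block for every
patient receiving simulated ezetimibe, then one lognormal block per
bempedoic pool (moderate/high-statin pool first).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

from .cohort import (
    GOAL_THRESHOLDS_MGDL,
    Cohort,
    Patient,
    RiskLevel,
    StatinIntensity,
    goal_threshold,
    is_at_goal,
)
from .efficacy import EfficacyPoolRule, Treatment, sample_post_ldl, select_efficacy


class PathwayStep(IntEnum):
    """Ordered stages of the intensification pathway."""

    BASELINE = 0
    AFTER_EZETIMIBE = 1
    AFTER_BEMPEDOIC = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters for the Monte Carlo engine."""

    n_reps: int = 10_000
    master_seed: int = 0
    efficacy: EfficacyPoolRule = field(default_factory=EfficacyPoolRule.default)
    goal_thresholds: dict[RiskLevel, float] = field(
        default_factory=lambda: dict(GOAL_THRESHOLDS_MGDL)
    )
    cutoffs: tuple[float, ...] = (55.0, 70.0)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if any(t <= 0 for t in self.goal_thresholds.values()):
            raise ValueError("goal thresholds must be positive")


@dataclass(frozen=True)
class PatientPathway:
    """Per-patient trace of the pathway: LDL-C and at-goal flag at each step."""

    ldl: tuple[float, float, float]
    at_goal: tuple[bool, bool, bool]
    ezetimibe_added: bool
    bempedoic_added: bool


def simulate_patient(
    patient: Patient, config: SimulationConfig, rng: np.random.Generator
) -> PatientPathway:
    """Walk one patient through the intensification pathway (scalar reference)."""
    if not patient.admitted or patient.regimen.on_pcsk9i:
        raise ValueError(
            f"patient {patient.patient_id} does not satisfy simulation "
            "preconditions (resolved LDL-C and risk, not on PCSK9i)"
        )
    thr = config.goal_thresholds
    ldl0 = float(patient.ldl_baseline)
    g0 = is_at_goal(ldl0, patient.risk, thr)

    ldl1, eze_added = ldl0, False
    if not g0 and not patient.regimen.on_ezetimibe:
        d = select_efficacy(Treatment.EZETIMIBE, patient, config.efficacy)
        ldl1 = sample_post_ldl(ldl0, d, rng)
        eze_added = True
    g1 = g0 or is_at_goal(ldl1, patient.risk, thr)

    ldl2, bemp_added = ldl1, False
    if not g1:
        d = select_efficacy(Treatment.BEMPEDOIC_ACID, patient, config.efficacy)
        ldl2 = sample_post_ldl(ldl1, d, rng)
        bemp_added = True
    g2 = g1 or is_at_goal(ldl2, patient.risk, thr)

    return PatientPathway(
        ldl=(ldl0, ldl1, ldl2),
        at_goal=(g0, g1, g2),
        ezetimibe_added=eze_added,
        bempedoic_added=bemp_added,
    )


@dataclass(frozen=True)
class RepResult:
    """One replicate's full per-patient state.

    Arrays are shaped (3, n_patients) for per-step quantities, indexed by
    :class:`PathwayStep`, and (n_patients,) for the added-treatment flags.
    """

    ldl: np.ndarray
    at_goal: np.ndarray
    ezetimibe_added: np.ndarray
    bempedoic_added: np.ndarray
    rep_index: int
    seed: tuple[int, int]

    @property
    def n_patients(self) -> int:
        return self.ldl.shape[1]


@dataclass(frozen=True)
class _CohortArrays:
    """Precomputed per-patient arrays shared by all replicates of a run."""

    ldl0: np.ndarray
    threshold: np.ndarray
    on_ezetimibe: np.ndarray
    pool_moderate_high: np.ndarray  # True -> moderate/high statin pool


def _prepare_arrays(cohort: Cohort, config: SimulationConfig) -> _CohortArrays:
    bad = [
        p.patient_id for p in cohort if not p.admitted or p.regimen.on_pcsk9i
    ]
    if bad:
        raise ValueError(
            f"cohort contains patients not admitted to simulation: {bad[:5]}"
        )
    unknown = [
        p.patient_id
        for p in cohort
        if p.regimen.statin_intensity is StatinIntensity.UNKNOWN
    ]
    if unknown:
        raise ValueError(f"unknown statin intensity in cohort: {unknown[:5]}")
    ldl0 = np.array([p.ldl_baseline for p in cohort], dtype=float)
    threshold = np.array(
        [goal_threshold(p.risk, config.goal_thresholds) for p in cohort], dtype=float
    )
    on_eze = np.array([p.regimen.on_ezetimibe for p in cohort], dtype=bool)
    pool1 = np.array(
        [
            p.regimen.statin_intensity
            in (StatinIntensity.MODERATE, StatinIntensity.HIGH)
            for p in cohort
        ],
        dtype=bool,
    )
    return _CohortArrays(ldl0, threshold, on_eze, pool1)


def run_replicate(
    cohort: Cohort,
    config: SimulationConfig,
    rep_index: int,
    _arrays: _CohortArrays | None = None,
) -> RepResult:
    """Run one replicate of the pathway over the whole cohort.

    Deterministic given (cohort, config.master_seed, rep_index).
    """
    arr = _arrays if _arrays is not None else _prepare_arrays(cohort, config)
    rng = np.random.default_rng(
        np.random.SeedSequence((config.master_seed, rep_index))
    )
    rule = config.efficacy
    n = arr.ldl0.size

    at_goal0 = arr.ldl0 < arr.threshold

    # Ezetimibe stage: the treated set is fixed by the baseline state.
    eze_added = (~at_goal0) & (~arr.on_ezetimibe)
    ldl1 = arr.ldl0.copy()
    idx_eze = np.flatnonzero(eze_added)
    if idx_eze.size:
        ldl1[idx_eze] = arr.ldl0[idx_eze] * rule.ezetimibe.post_factor(
            rng, size=idx_eze.size
        )
    at_goal1 = at_goal0 | (ldl1 < arr.threshold)

    # Bempedoic stage: everyone still not at goal, pool by statin background.
    bemp_added = ~at_goal1
    ldl2 = ldl1.copy()
    for pool_mask, dist in (
        (arr.pool_moderate_high, rule.pool_moderate_high),
        (~arr.pool_moderate_high, rule.pool_none_low),
    ):
        idx = np.flatnonzero(bemp_added & pool_mask)
        if idx.size:
            ldl2[idx] = ldl1[idx] * np.asarray(dist.post_factor(rng, size=idx.size))
    at_goal2 = at_goal1 | (ldl2 < arr.threshold)

    return RepResult(
        ldl=np.stack([arr.ldl0, ldl1, ldl2]),
        at_goal=np.stack([at_goal0, at_goal1, at_goal2]),
        ezetimibe_added=eze_added,
        bempedoic_added=bemp_added,
        rep_index=rep_index,
        seed=(config.master_seed, rep_index),
    )


def ldl_cutoff_proportions(
    rep: RepResult, step: PathwayStep, cutoffs: Sequence[float]
) -> list[float]:
    """Fraction of patients with LDL-C strictly below each cutoff at a step."""
    ldl = rep.ldl[int(step)]
    return [float((ldl < c).mean()) for c in cutoffs]


@dataclass(frozen=True)
class Quantiles:
    """Median and central 95% band of a per-replicate scalar series."""

    median: float
    q025: float
    q975: float

    @classmethod
    def from_samples(cls, x: np.ndarray) -> "Quantiles":
        q = np.quantile(np.asarray(x, dtype=float), [0.5, 0.025, 0.975])
        return cls(median=float(q[0]), q025=float(q[1]), q975=float(q[2]))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class StepSummary:
    """Monte Carlo summary of one pathway step."""

    mean_ldl: Quantiles
    at_goal_count: Quantiles
    at_goal_count_median_rounded: int
    frac_below: dict[float, Quantiles]

    def to_dict(self) -> dict:
        return {
            "mean_ldl": self.mean_ldl.to_dict(),
            "at_goal_count": self.at_goal_count.to_dict(),
            "at_goal_count_median_rounded": self.at_goal_count_median_rounded,
            "frac_below": {str(c): q.to_dict() for c, q in self.frac_below.items()},
        }


@dataclass(frozen=True)
class MonteCarloSummary:
    """Quantile summaries across replicates, plus utilisation and provenance."""

    steps: dict[PathwayStep, StepSummary]
    ezetimibe_end_count: Quantiles
    bempedoic_end_count: Quantiles
    n_patients: int
    n_reps: int
    master_seed: int

    def to_dict(self) -> dict:
        return {
            "steps": {s.name.lower(): summ.to_dict() for s, summ in self.steps.items()},
            "utilization_end_of_pathway": {
                "ezetimibe_count": self.ezetimibe_end_count.to_dict(),
                "bempedoic_acid_count": self.bempedoic_end_count.to_dict(),
            },
            "n_patients": self.n_patients,
            "n_reps": self.n_reps,
            "master_seed": self.master_seed,
        }


def run_monte_carlo(
    cohort: Cohort,
    config: SimulationConfig,
    trace_file=None,
) -> MonteCarloSummary:
    """Run the full Monte Carlo study and summarise across replicates.

    ``trace_file``: optional open text handle or path; when given, one CSV
    row of per-replicate scalars is written per replicate for audit.
    """
    arr = _prepare_arrays(cohort, config)
    n = arr.ldl0.size
    n_reps = config.n_reps
    cutoffs = [float(c) for c in config.cutoffs]

    mean_ldl = np.empty((3, n_reps))
    at_goal = np.empty((3, n_reps))
    frac_below = np.empty((3, len(cutoffs), n_reps))
    eze_end = np.empty(n_reps)
    bemp_end = np.empty(n_reps)

    close_trace = False
    if isinstance(trace_file, (str, bytes)) or hasattr(trace_file, "__fspath__"):
        trace_file = open(trace_file, "w")
        close_trace = True
    if trace_file is not None:
        header = ["rep", "step", "mean_ldl", "at_goal_count"] + [
            f"frac_below_{c:g}" for c in cutoffs
        ]
        trace_file.write(",".join(header) + "\n")

    try:
        for i in range(n_reps):
            rep = run_replicate(cohort, config, i, _arrays=arr)
            mean_ldl[:, i] = rep.ldl.mean(axis=1)
            at_goal[:, i] = rep.at_goal.sum(axis=1)
            for j, c in enumerate(cutoffs):
                frac_below[:, j, i] = (rep.ldl < c).mean(axis=1)
            eze_end[i] = arr.on_ezetimibe.sum() + rep.ezetimibe_added.sum()
            bemp_end[i] = rep.bempedoic_added.sum()
            if trace_file is not None:
                for s in PathwayStep:
                    row = [str(i), s.name.lower(), f"{mean_ldl[s, i]:.6f}",
                           f"{int(at_goal[s, i])}"] + [
                        f"{frac_below[s, j, i]:.6f}" for j in range(len(cutoffs))
                    ]
                    trace_file.write(",".join(row) + "\n")
    finally:
        if close_trace:
            trace_file.close()

    steps = {}
    for s in PathwayStep:
        agq = Quantiles.from_samples(at_goal[s])
        steps[s] = StepSummary(
            mean_ldl=Quantiles.from_samples(mean_ldl[s]),
            at_goal_count=agq,
            at_goal_count_median_rounded=int(round(agq.median)),
            frac_below={
                c: Quantiles.from_samples(frac_below[s, j]) for j, c in enumerate(cutoffs)
            },
        )
    return MonteCarloSummary(
        steps=steps,
        ezetimibe_end_count=Quantiles.from_samples(eze_end),
        bempedoic_end_count=Quantiles.from_samples(bemp_end),
        n_patients=n,
        n_reps=n_reps,
        master_seed=config.master_seed,
    )
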