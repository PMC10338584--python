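"""Synthetic cohorts calibrated to published aggregate statistics.

Patient-level data for the Austrian high/very-high-risk registry cohort are
not public; only aggregates are (N=144; LDL-C mean 76.38, SD 43.59 mg/dL;
52 patients at goal; 35 on ezetimibe of whom 20 not at goal; 134 on
moderate/high-intensity statin; 9 high-risk vs 135 very-high-risk; 35% of
patients below 55 mg/dL and 55% below 70 mg/dL).  This module builds a
synthetic stand-in cohort with the *structural* counts exact by
construction and the baseline LDL-C values drawn from a per-risk-stratum
lognormal model calibrated to the pooled mean, SD, cutoff fractions and
expected at-goal count.

A lognormal family is used because baseline LDL-C is positive and
right-skewed (pooled CV here is 0.57); two parameters per stratum against
five pooled constraints.  LDL-C values are conditioned on each patient's
assigned at-goal status by truncating the stratum distribution at the
risk-based goal.

The module also generates a larger raw-registry fixture (N=310) whose
data defects are placed so the eligibility waterfall reproduces the
published attrition 310, 297, 280, 275, 199, 144, and synthetic trial
response ratios for distribution-fit recovery checks.
"""

from __future__ import annotations

import dataclasses
import functools
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .cohort import (
    GOAL_THRESHOLDS_MGDL,
    Cohort,
    LipidPanel,
    Patient,
    Regimen,
    RiskLevel,
    StatinIntensity,
)
from .efficacy import LognormalRatio
from .errors import CalibrationError, GenerationError

#: Rejection-sampling budget per patient before falling back to
#: inverse-transform sampling of the truncated distribution.
REJECTION_CAP = 100_000


@dataclass(frozen=True)
class AggregateConstraints:
    """Published baseline aggregates a synthetic cohort must reproduce."""

    n_total: int
    n_high: int
    n_very_high: int
    n_at_goal: int
    n_on_ezetimibe: int
    n_on_ezetimibe_not_at_goal: int
    n_statin_mod_high: int
    n_statin_low: int
    n_no_statin: int
    ldl_mean: float
    ldl_sd: float
    frac_below_55: float
    frac_below_70: float

    def validate(self) -> None:
        c = self
        if c.n_high + c.n_very_high != c.n_total:
            raise ValueError("risk strata must partition the cohort")
        if c.n_statin_mod_high + c.n_statin_low + c.n_no_statin != c.n_total:
            raise ValueError("statin categories must partition the cohort")
        if not (0 <= c.n_at_goal <= c.n_total):
            raise ValueError("n_at_goal out of range")
        if c.n_on_ezetimibe_not_at_goal > c.n_on_ezetimibe:
            raise ValueError("ezetimibe-not-at-goal exceeds ezetimibe users")
        if c.n_on_ezetimibe_not_at_goal > c.n_total - c.n_at_goal:
            raise ValueError("more ezetimibe users not at goal than patients not at goal")
        if c.ldl_sd <= 0 or c.ldl_mean <= 0:
            raise ValueError("LDL-C mean and SD must be positive")
        if not (0.0 <= c.frac_below_55 <= c.frac_below_70 <= 1.0):
            raise ValueError("cutoff fractions must satisfy 0 <= P(<55) <= P(<70) <= 1")


def default_constraints() -> AggregateConstraints:
    """The published aggregates of the Austrian simulation cohort (N=144)."""
    return AggregateConstraints(
        n_total=144,
        n_high=9,
        n_very_high=135,
        n_at_goal=52,
        n_on_ezetimibe=35,
        n_on_ezetimibe_not_at_goal=20,
        n_statin_mod_high=134,
        n_statin_low=1,
        n_no_statin=9,
        ldl_mean=76.38,
        ldl_sd=43.59,
        frac_below_55=0.35,
        frac_below_70=0.55,
    )


@dataclass(frozen=True)
class CalibratedLdlModel:
    """Per-risk-stratum lognormal baseline LDL-C model plus calibration fit.

    ``params`` maps risk level to (mu, sigma) of log LDL-C.  ``residuals``
    are the relative deviations of each implied pooled statistic from its
    target; ``implied`` are the statistics themselves.
    """

    params: dict[RiskLevel, tuple[float, float]]
    residuals: dict[str, float]
    implied: dict[str, float]
    loss: float

    def cdf(self, risk: RiskLevel, x: float) -> float:
        mu, sigma = self.params[risk]
        return float(stats.norm.cdf((np.log(x) - mu) / sigma))

    def goal_probability(self, risk: RiskLevel) -> float:
        return self.cdf(risk, GOAL_THRESHOLDS_MGDL[risk])


def _pooled_stats(x: np.ndarray, c: AggregateConstraints) -> dict[str, float]:
    """Implied pooled statistics of the two-stratum lognormal mixture."""
    mu_vh, s_vh, mu_h, s_h = x
    w_vh = c.n_very_high / c.n_total
    w_h = c.n_high / c.n_total

    def _moments(mu, s):
        m1 = np.exp(mu + s**2 / 2)
        m2 = np.exp(2 * mu + 2 * s**2)
        return m1, m2

    m1_vh, m2_vh = _moments(mu_vh, s_vh)
    m1_h, m2_h = _moments(mu_h, s_h)
    mean = w_vh * m1_vh + w_h * m1_h
    second = w_vh * m2_vh + w_h * m2_h
    sd = np.sqrt(max(second - mean**2, 1e-12))

    def _p_below(cut):
        return w_vh * stats.norm.cdf((np.log(cut) - mu_vh) / s_vh) + w_h * stats.norm.cdf(
            (np.log(cut) - mu_h) / s_h
        )

    p55 = _p_below(55.0)
    p70 = _p_below(70.0)
    at_goal = c.n_very_high * stats.norm.cdf(
        (np.log(55.0) - mu_vh) / s_vh
    ) + c.n_high * stats.norm.cdf((np.log(70.0) - mu_h) / s_h)
    return {
        "ldl_mean": float(mean),
        "ldl_sd": float(sd),
        "frac_below_55": float(p55),
        "frac_below_70": float(p70),
        "expected_at_goal": float(at_goal),
    }


def calibrate_ldl_model(
    constraints: AggregateConstraints,
    tol: float = 0.05,
) -> CalibratedLdlModel:
    """Fit per-stratum lognormal LDL-C parameters to the pooled aggregates.

    Minimises the sum of squared relative deviations of (pooled mean, pooled
    SD, P(<55), P(<70), expected at-goal count) from their targets.  The
    high-risk stratum is small, so a mild ridge term (1e-3) shrinks its
    parameters toward the very-high stratum's.  Raises
    :class:`CalibrationError` when any relative residual exceeds ``tol``.
    """
    c = constraints
    c.validate()

    targets = {
        "ldl_mean": c.ldl_mean,
        "ldl_sd": c.ldl_sd,
        "frac_below_55": c.frac_below_55,
        "frac_below_70": c.frac_below_70,
        "expected_at_goal": float(c.n_at_goal),
    }

    # Moment-matched pooled lognormal as the common starting point.
    cv2 = (c.ldl_sd / c.ldl_mean) ** 2
    sigma0 = np.sqrt(np.log1p(cv2))
    mu0 = np.log(c.ldl_mean) - sigma0**2 / 2

    def unpack(z):
        return np.array([z[0], np.exp(z[1]), z[2], np.exp(z[3])])

    def objective(z):
        x = unpack(z)
        implied = _pooled_stats(x, c)
        loss = sum(
            ((implied[k] - targets[k]) / targets[k]) ** 2 for k in targets if targets[k]
        )
        ridge = 1e-3 * ((x[2] - x[0]) ** 2 + (z[3] - z[1]) ** 2)
        return loss + ridge

    z0 = np.array([mu0, np.log(sigma0), mu0, np.log(sigma0)])
    res = optimize.minimize(objective, z0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    x = unpack(res.x)
    implied = _pooled_stats(x, c)
    residuals = {
        k: (implied[k] - targets[k]) / targets[k] if targets[k] else implied[k]
        for k in targets
    }
    model = CalibratedLdlModel(
        params={
            RiskLevel.VERY_HIGH: (float(x[0]), float(x[1])),
            RiskLevel.HIGH: (float(x[2]), float(x[3])),
        },
        residuals=residuals,
        implied=implied,
        loss=float(res.fun),
    )
    worst = max(abs(v) for v in residuals.values())
    if worst > tol:
        raise CalibrationError(
            f"calibration failed: max relative residual {worst:.3f} > {tol}",
            residuals=residuals,
        )
    return model


def _sample_truncated_lognormal(
    mu: float,
    sigma: float,
    lo: float,
    hi: float,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw from a lognormal(mu, sigma) restricted to [lo, hi).

    Rejection sampling in batches, with an inverse-transform fallback when
    the budget is exhausted (thin truncation regions).
    """
    out = np.empty(size)
    filled = 0
    spent = 0
    while filled < size and spent < REJECTION_CAP:
        batch = max(256, 4 * (size - filled))
        draws = rng.lognormal(mu, sigma, size=batch)
        spent += batch
        keep = draws[(draws >= lo) & (draws < hi)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    if filled < size:
        a = stats.norm.cdf((np.log(lo) - mu) / sigma) if lo > 0 else 0.0
        b = stats.norm.cdf((np.log(hi) - mu) / sigma) if np.isfinite(hi) else 1.0
        if b - a <= 0:
            raise GenerationError(
                f"truncation region [{lo}, {hi}) has zero mass under "
                f"lognormal({mu:.3f}, {sigma:.3f})"
            )
        u = rng.uniform(a, b, size=size - filled)
        out[filled:] = np.exp(mu + sigma * stats.norm.ppf(u))
    return out


@dataclass(frozen=True)
class _Slot:
    """Structural assignment of one synthetic patient (everything but LDL-C)."""

    risk: RiskLevel
    at_goal: bool
    on_ezetimibe: bool
    statin: StatinIntensity
    on_other_llt: bool


def _allocate(total: int, weights: list[float], caps: list[int]) -> list[int]:
    """Largest-remainder apportionment of ``total`` across groups with caps."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    raw = total * w / w.sum()
    base = np.minimum(np.floor(raw).astype(int), caps)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    for i in order:
        if rem == 0:
            break
        if base[i] < caps[i]:
            base[i] += 1
            rem -= 1
    if rem != 0:
        # caps were binding everywhere in preference order; distribute anywhere.
        for i in range(len(base)):
            room = caps[i] - base[i]
            take = min(room, rem)
            base[i] += take
            rem -= take
    if rem != 0:
        raise GenerationError("structural allocation infeasible under caps")
    return base.tolist()


def _build_slots(
    c: AggregateConstraints, model: CalibratedLdlModel
) -> list[_Slot]:
    """Deterministic structural layout honouring every count constraint.

    At-goal counts are split across risk strata proportionally to the
    calibrated model's stratum goal probabilities; ezetimibe users (at goal
    and not) are spread across strata proportionally to stratum size.  Of
    the no-statin patients, two thirds (6 of 9 under the default
    constraints) are ezetimibe-alone and the rest other-LLT-only — one
    consistent completion of the published overlapping regimen categories.
    """
    strata = [(RiskLevel.VERY_HIGH, c.n_very_high), (RiskLevel.HIGH, c.n_high)]
    weights = [n * model.goal_probability(r) for r, n in strata]
    goal_counts = _allocate(c.n_at_goal, weights, [n for _, n in strata])

    size_weights = [n for _, n in strata]
    eze_goal = _allocate(
        c.n_on_ezetimibe - c.n_on_ezetimibe_not_at_goal, size_weights, goal_counts
    )
    eze_notgoal = _allocate(
        c.n_on_ezetimibe_not_at_goal,
        size_weights,
        [n - g for (_, n), g in zip(strata, goal_counts)],
    )

    slots: list[_Slot] = []
    for (risk, n_stratum), n_goal, n_eg, n_eng in zip(
        strata, goal_counts, eze_goal, eze_notgoal
    ):
        for i in range(n_stratum):
            at_goal = i < n_goal
            if at_goal:
                on_eze = i < n_eg
            else:
                on_eze = (i - n_goal) < n_eng
            slots.append(
                _Slot(
                    risk=risk,
                    at_goal=at_goal,
                    on_ezetimibe=on_eze,
                    statin=StatinIntensity.MODERATE,  # provisional; fixed below
                    on_other_llt=False,
                )
            )

    # Statin layout: n_no_statin patients off statin (ezetimibe-alone first,
    # then other-LLT-only), one low-intensity user, remainder moderate/high
    # alternating.  Applied deterministically over the slot order.
    n_eze_alone = min(round(c.n_no_statin * 2 / 3), c.n_on_ezetimibe)
    n_other_only = c.n_no_statin - n_eze_alone

    eze_idx = [i for i, s in enumerate(slots) if s.on_ezetimibe]
    non_eze_idx = [i for i, s in enumerate(slots) if not s.on_ezetimibe]
    if len(eze_idx) < n_eze_alone or len(non_eze_idx) < n_other_only + c.n_statin_low:
        raise GenerationError("cannot place no-statin patients consistently")

    no_statin_eze = set(eze_idx[-n_eze_alone:]) if n_eze_alone else set()
    no_statin_other = set(non_eze_idx[-n_other_only:]) if n_other_only else set()
    low_idx = set(non_eze_idx[: c.n_statin_low])

    toggle = True
    for i, s in enumerate(slots):
        if i in no_statin_eze:
            slots[i] = dataclasses.replace(s, statin=StatinIntensity.NONE)
        elif i in no_statin_other:
            slots[i] = dataclasses.replace(
                s, statin=StatinIntensity.NONE, on_other_llt=True
            )
        elif i in low_idx:
            slots[i] = dataclasses.replace(s, statin=StatinIntensity.LOW)
        else:
            slots[i] = dataclasses.replace(
                s,
                statin=StatinIntensity.HIGH if toggle else StatinIntensity.MODERATE,
            )
            toggle = not toggle
    return slots


def generate_cohort(
    constraints: AggregateConstraints,
    model: CalibratedLdlModel,
    seed: int,
    id_prefix: str = "P",
    label: str = "synthetic simulation cohort (calibrated)",
) -> Cohort:
    """Emit a synthetic cohort: exact structural counts, stochastic LDL-C.

    Risk class, regimen and at-goal membership are assigned deterministically
    from the constraints; each patient's baseline LDL-C is then drawn from
    the calibrated stratum lognormal truncated to the at-goal side of the
    patient's risk-based threshold.  Same seed, same cohort.
    """
    constraints.validate()
    slots = _build_slots(constraints, model)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0)))
    width = len(str(len(slots)))
    patients = []
    for i, s in enumerate(slots):
        mu, sigma = model.params[s.risk]
        thr = GOAL_THRESHOLDS_MGDL[s.risk]
        lo, hi = (0.0, thr) if s.at_goal else (thr, np.inf)
        ldl = float(_sample_truncated_lognormal(mu, sigma, lo, hi, 1, rng)[0])
        patients.append(
            Patient(
                patient_id=f"{id_prefix}{i + 1:0{width}d}",
                risk=s.risk,
                regimen=Regimen(
                    statin_intensity=s.statin,
                    on_ezetimibe=s.on_ezetimibe,
                    on_other_llt=s.on_other_llt,
                ),
                ldl_baseline=ldl,
            )
        )
    return Cohort(patients=patients, label=label)


#: Sequential defect counts of the published attrition waterfall
#: 310 -> 297 -> 280 -> 275 -> 199 -> 144.
_WATERFALL_DEFECTS = {
    "missing_ldl": 13,
    "missing_risk": 17,
    "unknown_intensity": 5,
    "no_llt": 76,
    "pcsk9i": 55,
}


@functools.lru_cache(maxsize=1)
def _default_model() -> CalibratedLdlModel:
    return calibrate_ldl_model(default_constraints())


def generate_full_cohort_fixture(
    seed: int,
    constraints: AggregateConstraints | None = None,
    model: CalibratedLdlModel | None = None,
) -> Cohort:
    """A synthetic 310-patient raw-registry cohort for the eligibility filter.

    The 144 eligible patients come from :func:`generate_cohort`; 166 extra
    patients carry exactly one data defect each, sized to the published
    sequential attrition (13 unresolvable LDL-C, 17 missing risk, 5 unknown
    statin intensity, 76 on no therapy, 55 on a PCSK9 inhibitor), so the
    waterfall is 310, 297, 280, 275, 199, 144 for every seed.  Every fifth
    eligible patient is stored as a consistent lipid panel instead of a
    direct LDL-C, exercising the Friedewald path.
    """
    c = constraints or default_constraints()
    m = model or (_default_model() if constraints is None else calibrate_ldl_model(c))
    core = generate_cohort(c, m, seed=seed, id_prefix="S", label="")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF1)))

    patients: list[Patient] = []
    for i, p in enumerate(core):
        if i % 5 == 4:
            # store as panel only; TC is constructed so Friedewald recovers
            # the sampled LDL-C exactly (TG/5 = 32 is float-exact)
            ldl = p.ldl_baseline
            panel = LipidPanel(
                total_cholesterol=ldl + 52.0 + 32.0,
                hdl_cholesterol=52.0,
                triglycerides=160.0,
            )
            patients.append(
                dataclasses.replace(p, panel=panel, ldl_baseline=None)
            )
        else:
            patients.append(p)

    mu_vh, s_vh = m.params[RiskLevel.VERY_HIGH]

    def _ldl():
        return float(rng.lognormal(mu_vh, s_vh))

    k = len(patients)

    def _pid():
        nonlocal k
        k += 1
        return f"S{k:03d}"

    # Stage-1 defects: LDL-C unresolvable.
    n = _WATERFALL_DEFECTS["missing_ldl"]
    for j in range(n):
        if j % 3 == 0:
            panel = LipidPanel(total_cholesterol=220.0, hdl_cholesterol=45.0,
                               triglycerides=450.0)  # TG out of Friedewald domain
        elif j % 3 == 1:
            panel = None  # nothing recorded
        else:
            panel = LipidPanel(total_cholesterol=180.0, hdl_cholesterol=50.0)  # TG missing
        patients.append(
            Patient(
                patient_id=_pid(),
                risk=RiskLevel.VERY_HIGH,
                regimen=Regimen(statin_intensity=StatinIntensity.MODERATE),
                panel=panel,
            )
        )

    # Stage-2 defects: risk not classified (LDL-C resolvable).
    for _ in range(_WATERFALL_DEFECTS["missing_risk"]):
        patients.append(
            Patient(
                patient_id=_pid(),
                risk=RiskLevel.MISSING,
                regimen=Regimen(statin_intensity=StatinIntensity.MODERATE),
                ldl_baseline=_ldl(),
            )
        )

    # Stage-3 defects: statin user, intensity undocumented.
    for _ in range(_WATERFALL_DEFECTS["unknown_intensity"]):
        patients.append(
            Patient(
                patient_id=_pid(),
                risk=RiskLevel.VERY_HIGH,
                regimen=Regimen(statin_intensity=StatinIntensity.UNKNOWN),
                ldl_baseline=_ldl(),
            )
        )

    # Stage-4 defects: no lipid-lowering therapy documented.
    for _ in range(_WATERFALL_DEFECTS["no_llt"]):
        patients.append(
            Patient(
                patient_id=_pid(),
                risk=RiskLevel.VERY_HIGH,
                regimen=Regimen(),
                ldl_baseline=_ldl(),
            )
        )

    # Stage-5 defects: PCSK9-inhibitor users.
    for j in range(_WATERFALL_DEFECTS["pcsk9i"]):
        patients.append(
            Patient(
                patient_id=_pid(),
                risk=RiskLevel.VERY_HIGH,
                regimen=Regimen(
                    statin_intensity=StatinIntensity.HIGH if j % 2 else StatinIntensity.MODERATE,
                    on_pcsk9i=True,
                ),
                ldl_baseline=_ldl(),
            )
        )

    return Cohort(patients=patients, label="synthetic raw registry cohort (N=310)")


def generate_trial_ratios(
    d: LognormalRatio, n: int, seed: int
) -> np.ndarray:
    """n independent synthetic week-12/baseline ratios from a lognormal pool."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return np.asarray(d.sample(rng, size=n), dtype=float)
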