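"""Patient and cohort data model for LDL-C goal-attainment analyses.

A *cohort* is an ordered collection of patients at high or very-high
cardiovascular risk, each carrying a lipid-lowering regimen and a baseline
LDL-C concentration (mg/dL) that is either directly measured or estimated
from a full lipid panel with the Friedewald formula.  The 2019 ESC/EAS
risk-based goals (< 70 mg/dL for high risk, < 55 mg/dL for very-high risk)
drive all at-goal logic.

The eligibility filter reproduces the standard attrition waterfall used to
select a simulation cohort from an observational registry: resolve LDL-C,
require a risk classification, require a known statin intensity for statin
users, drop untreated patients, drop PCSK9-inhibitor users.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import (
    DataInconsistencyError,
    EmptyCohortError,
    FriedewaldInvalidError,
    UnclassifiableRiskError,
    ValidationError,
)

#: mg/dL of LDL-C per mmol/L.
MGDL_PER_MMOL = 38.67

#: Friedewald estimation is unreliable above this triglyceride level (mg/dL).
FRIEDEWALD_TG_LIMIT = 400.0


class RiskLevel(str, Enum):
    """ESC/EAS cardiovascular risk class used for goal assignment."""

    HIGH = "high"
    VERY_HIGH = "very_high"
    MISSING = "missing"


class StatinIntensity(str, Enum):
    """Categorical statin dose intensity.

    ``UNKNOWN`` encodes "statin user, intensity not documented" and is only
    meaningful for patients flagged as statin users; such patients are
    excluded by the eligibility filter.
    """

    NONE = "none"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    UNKNOWN = "unknown"


#: Default risk-based LDL-C goals, mg/dL (2019 ESC/EAS).
GOAL_THRESHOLDS_MGDL: dict[RiskLevel, float] = {
    RiskLevel.HIGH: 70.0,
    RiskLevel.VERY_HIGH: 55.0,
}


@dataclass(frozen=True)
class Regimen:
    """Baseline lipid-lowering regimen flags for one patient."""

    statin_intensity: StatinIntensity = StatinIntensity.NONE
    on_ezetimibe: bool = False
    on_pcsk9i: bool = False
    on_other_llt: bool = False

    @property
    def on_statin(self) -> bool:
        return self.statin_intensity is not StatinIntensity.NONE

    @property
    def no_llt(self) -> bool:
        """True iff the patient is on no lipid-lowering therapy at all."""
        return not (
            self.on_statin or self.on_ezetimibe or self.on_pcsk9i or self.on_other_llt
        )


@dataclass(frozen=True)
class LipidPanel:
    """A lipid panel in mg/dL; any component may be missing (``None``)."""

    total_cholesterol: float | None = None
    hdl_cholesterol: float | None = None
    triglycerides: float | None = None
    ldl_direct: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "total_cholesterol",
            "hdl_cholesterol",
            "triglycerides",
            "ldl_direct",
        ):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")


@dataclass(frozen=True)
class Patient:
    """One individual: risk class, regimen, and baseline LDL-C.

    ``ldl_baseline`` is the resolved baseline LDL-C in mg/dL.  Patients read
    from raw files may carry only a panel; the eligibility filter resolves
    LDL-C (direct measurement wins over Friedewald recalculation) and stamps
    it here.
    """

    patient_id: str
    risk: RiskLevel = RiskLevel.MISSING
    regimen: Regimen = field(default_factory=Regimen)
    panel: LipidPanel | None = None
    ldl_baseline: float | None = None

    @property
    def admitted(self) -> bool:
        """Whether the patient satisfies the simulation preconditions."""
        return (
            self.ldl_baseline is not None
            and self.ldl_baseline > 0
            and self.risk is not RiskLevel.MISSING
        )


@dataclass
class Cohort:
    """An ordered, uniquely identified collection of patients."""

    patients: list[Patient]
    label: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id values in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[Patient]:
        return iter(self.patients)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            panel = p.panel or LipidPanel()
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "risk": "" if p.risk is RiskLevel.MISSING else p.risk.value,
                    "statin_intensity": p.regimen.statin_intensity.value,
                    "on_ezetimibe": int(p.regimen.on_ezetimibe),
                    "on_pcsk9i": int(p.regimen.on_pcsk9i),
                    "on_other_llt": int(p.regimen.on_other_llt),
                    "ldl_mgdl": _fmt(p.ldl_baseline if p.ldl_baseline is not None
                                     else panel.ldl_direct),
                    "tc_mgdl": _fmt(panel.total_cholesterol),
                    "hdl_mgdl": _fmt(panel.hdl_cholesterol),
                    "tg_mgdl": _fmt(panel.triglycerides),
                }
            )
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "Cohort":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls.from_dataframe(df, label=label)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "Cohort":
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError([f"missing required column(s): {', '.join(missing)}"])
        problems: list[str] = []
        patients: list[Patient] = []
        for idx, row in df.iterrows():
            rowno = int(idx) + 2  # 1-based, after header
            pid = str(row["patient_id"]).strip()
            if not pid:
                problems.append(f"row {rowno}, column patient_id: empty identifier")
                continue
            risk_raw = str(row["risk"]).strip()
            if risk_raw == "":
                risk = RiskLevel.MISSING
            else:
                try:
                    risk = RiskLevel(risk_raw)
                except ValueError:
                    problems.append(
                        f"row {rowno}, column risk: unknown label {risk_raw!r}"
                    )
                    continue
            try:
                intensity = StatinIntensity(str(row["statin_intensity"]).strip() or "none")
            except ValueError:
                problems.append(
                    f"row {rowno}, column statin_intensity: unknown label "
                    f"{row['statin_intensity']!r}"
                )
                continue
            flags = {}
            bad_flag = False
            for col in ("on_ezetimibe", "on_pcsk9i", "on_other_llt"):
                raw = str(row[col]).strip()
                if raw not in {"0", "1", ""}:
                    problems.append(f"row {rowno}, column {col}: expected 0 or 1, got {raw!r}")
                    bad_flag = True
                else:
                    flags[col] = raw == "1"
            if bad_flag:
                continue
            nums = {}
            bad_num = False
            for col in ("ldl_mgdl", "tc_mgdl", "hdl_mgdl", "tg_mgdl"):
                raw = str(row[col]).strip()
                if raw == "":
                    nums[col] = None
                else:
                    try:
                        nums[col] = float(raw)
                    except ValueError:
                        problems.append(
                            f"row {rowno}, column {col}: not a number: {raw!r}"
                        )
                        bad_num = True
            if bad_num:
                continue
            panel = LipidPanel(
                total_cholesterol=nums["tc_mgdl"],
                hdl_cholesterol=nums["hdl_mgdl"],
                triglycerides=nums["tg_mgdl"],
                ldl_direct=nums["ldl_mgdl"],
            )
            patients.append(
                Patient(
                    patient_id=pid,
                    risk=risk,
                    regimen=Regimen(
                        statin_intensity=intensity,
                        on_ezetimibe=flags["on_ezetimibe"],
                        on_pcsk9i=flags["on_pcsk9i"],
                        on_other_llt=flags["on_other_llt"],
                    ),
                    panel=panel,
                )
            )
        if problems:
            raise ValidationError(problems)
        return cls(patients=patients, label=label)


COHORT_COLUMNS = [
    "patient_id",
    "risk",
    "statin_intensity",
    "on_ezetimibe",
    "on_pcsk9i",
    "on_other_llt",
    "ldl_mgdl",
    "tc_mgdl",
    "hdl_mgdl",
    "tg_mgdl",
]


def _fmt(v: float | None):
    return "" if v is None else v


@dataclass(frozen=True)
class WaterfallReport:
    """Per-stage patient counts of the eligibility filter (non-increasing)."""

    stage_names: tuple[str, ...]
    stage_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.stage_names) != len(self.stage_counts):
            raise ValueError("stage_names and stage_counts must align")
        counts = self.stage_counts
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"waterfall counts must be non-increasing: {counts}")
        if any(c < 0 for c in counts):
            raise ValueError("stage counts must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"stage": self.stage_names, "n": self.stage_counts})


def mgdl_from_mmol(x: float) -> float:
    """Convert an LDL-C concentration from mmol/L to mg/dL (x 38.67)."""
    if not math.isfinite(x) or x < 0:
        raise ValueError(f"concentration must be finite and non-negative, got {x!r}")
    return x * MGDL_PER_MMOL


def friedewald_ldl(panel: LipidPanel) -> float:
    """Estimate LDL-C (mg/dL) as TC - HDL - TG/5.

    Valid only for triglycerides below 400 mg/dL; above that the TG/5 VLDL
    approximation breaks down and :class:`FriedewaldInvalidError` is raised.
    A negative estimate signals an inconsistent panel.  A directly measured
    LDL-C, when available, should be preferred over this estimate.
    """
    tc, hdl, tg = panel.total_cholesterol, panel.hdl_cholesterol, panel.triglycerides
    if tc is None or hdl is None or tg is None:
        raise ValueError("Friedewald estimation needs TC, HDL and TG all present")
    if tg >= FRIEDEWALD_TG_LIMIT:
        raise FriedewaldInvalidError(
            f"triglycerides {tg} mg/dL >= {FRIEDEWALD_TG_LIMIT:g} mg/dL: "
            "Friedewald formula not applicable"
        )
    ldl = tc - hdl - tg / 5.0
    if ldl < 0:
        raise DataInconsistencyError(
            f"Friedewald LDL-C estimate is negative ({ldl:.1f} mg/dL) for panel {panel}"
        )
    return ldl


def resolve_ldl(patient: Patient) -> float | None:
    """Baseline LDL-C for a patient: stamped value, else direct, else Friedewald.

    Returns ``None`` when LDL-C cannot be resolved (missing inputs, TG out of
    the Friedewald domain, or an inconsistent panel).
    """
    if patient.ldl_baseline is not None:
        return patient.ldl_baseline
    if patient.panel is None:
        return None
    if patient.panel.ldl_direct is not None:
        return patient.panel.ldl_direct
    try:
        return friedewald_ldl(patient.panel)
    except (ValueError, FriedewaldInvalidError, DataInconsistencyError):
        return None


def goal_threshold(
    risk: RiskLevel, thresholds: dict[RiskLevel, float] | None = None
) -> float:
    """Risk-based LDL-C goal in mg/dL: < 70 for high, < 55 for very-high risk."""
    if risk is RiskLevel.MISSING:
        raise UnclassifiableRiskError("cannot assign a goal to a patient with missing risk")
    return (thresholds or GOAL_THRESHOLDS_MGDL)[risk]


def is_at_goal(
    ldl: float, risk: RiskLevel, thresholds: dict[RiskLevel, float] | None = None
) -> bool:
    """Strict comparison: at goal iff ldl < threshold; a tie is NOT at goal."""
    if ldl < 0:
        raise ValueError(f"LDL-C must be non-negative, got {ldl!r}")
    return ldl < goal_threshold(risk, thresholds)


#: Waterfall stage labels, in filter order.
WATERFALL_STAGES = (
    "all patients",
    "baseline LDL-C available (direct or Friedewald)",
    "CV risk classification available",
    "statin intensity known for statin users",
    "on lipid-lowering therapy",
    "not on PCSK9 inhibitor",
)


def apply_eligibility_filter(cohort: Cohort) -> tuple[Cohort, WaterfallReport]:
    """Select simulation-eligible patients, reporting per-stage attrition.

    Stages, applied in order (a patient is counted out at the first failing
    stage): (1) resolve baseline LDL-C and drop the unresolvable; (2) drop
    missing risk; (3) drop statin users with unknown intensity; (4) drop
    patients on no lipid-lowering therapy; (5) drop PCSK9-inhibitor users.
    Survivors are returned with ``ldl_baseline`` stamped.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("eligibility filter received an empty cohort")

    counts = [len(cohort)]
    stage1: list[Patient] = []
    for p in cohort:
        ldl = resolve_ldl(p)
        if ldl is not None:
            stage1.append(dataclasses.replace(p, ldl_baseline=ldl))
    counts.append(len(stage1))

    stage2 = [p for p in stage1 if p.risk is not RiskLevel.MISSING]
    counts.append(len(stage2))

    stage3 = [
        p for p in stage2 if p.regimen.statin_intensity is not StatinIntensity.UNKNOWN
    ]
    counts.append(len(stage3))

    stage4 = [p for p in stage3 if not p.regimen.no_llt]
    counts.append(len(stage4))

    stage5 = [p for p in stage4 if not p.regimen.on_pcsk9i]
    counts.append(len(stage5))

    report = WaterfallReport(stage_names=WATERFALL_STAGES, stage_counts=tuple(counts))
    label = f"{cohort.label} (eligible)" if cohort.label else "eligible"
    return Cohort(patients=stage5, label=label), report


@dataclass(frozen=True)
class BaselineSummary:
    """Aggregate description of an admitted cohort at baseline."""

    n: int
    ldl_mean: float
    ldl_sd: float
    n_at_goal: int
    frac_at_goal: float
    n_at_goal_by_risk: dict[str, int]
    n_by_risk: dict[str, int]
    n_statin_by_intensity: dict[str, int]
    n_on_statin: int
    n_on_ezetimibe: int
    n_on_other_llt: int
    frac_below: dict[float, float]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frac_below"] = {str(k): v for k, v in self.frac_below.items()}
        return d


def summarize_baseline(
    cohort: Cohort,
    cutoffs: Sequence[float] = (55.0, 70.0),
    thresholds: dict[RiskLevel, float] | None = None,
) -> BaselineSummary:
    """Baseline aggregates: LDL-C moments, goal attainment, regimen counts.

    Requires every patient to be admitted (resolved LDL-C and risk).
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot summarize an empty cohort")
    not_admitted = [p.patient_id for p in cohort if not p.admitted]
    if not_admitted:
        raise ValueError(
            f"summarize_baseline requires admitted patients; offending ids: "
            f"{not_admitted[:5]}"
        )
    ldl = np.array([p.ldl_baseline for p in cohort], dtype=float)
    at_goal = np.array(
        [is_at_goal(p.ldl_baseline, p.risk, thresholds) for p in cohort], dtype=bool
    )
    n = len(cohort)
    by_risk: dict[str, int] = {}
    goal_by_risk: dict[str, int] = {}
    for p, g in zip(cohort, at_goal):
        by_risk[p.risk.value] = by_risk.get(p.risk.value, 0) + 1
        if g:
            goal_by_risk[p.risk.value] = goal_by_risk.get(p.risk.value, 0) + 1
    statin_by_intensity: dict[str, int] = {}
    for p in cohort:
        if p.regimen.on_statin:
            key = p.regimen.statin_intensity.value
            statin_by_intensity[key] = statin_by_intensity.get(key, 0) + 1
    return BaselineSummary(
        n=n,
        ldl_mean=float(ldl.mean()),
        ldl_sd=float(ldl.std(ddof=1)) if n > 1 else 0.0,
        n_at_goal=int(at_goal.sum()),
        frac_at_goal=float(at_goal.mean()),
        n_at_goal_by_risk=goal_by_risk,
        n_by_risk=by_risk,
        n_statin_by_intensity=statin_by_intensity,
        n_on_statin=sum(1 for p in cohort if p.regimen.on_statin),
        n_on_ezetimibe=sum(1 for p in cohort if p.regimen.on_ezetimibe),
        n_on_other_llt=sum(1 for p in cohort if p.regimen.on_other_llt),
        frac_below={float(c): float((ldl < c).mean()) for c in cutoffs},
    )
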