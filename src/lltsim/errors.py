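"""Exception hierarchy for lltsim.

Every anticipated failure mode raises a subclass of :class:`LltsimError`,
so callers can distinguish domain errors (bad lipid panel, infeasible
constraints) from programming errors.
"""

from __future__ import annotations


class LltsimError(Exception):
    """Base class for all lltsim domain errors."""


class FriedewaldInvalidError(LltsimError):
    """Friedewald estimation is outside its validity domain (TG >= 400 mg/dL)."""


class DataInconsistencyError(LltsimError):
    """A lipid panel is internally inconsistent (e.g. negative estimated LDL-C)."""


class UnclassifiableRiskError(LltsimError):
    """A goal threshold was requested for a patient with missing CV risk."""


class EmptyCohortError(LltsimError):
    """An operation that needs at least one patient received an empty cohort."""


class InfeasibleMomentsError(LltsimError):
    """Requested (mean, sd) cannot be realised by a beta distribution."""


class InsufficientDataError(LltsimError):
    """Too few observations to fit a distribution."""


class CalibrationError(LltsimError):
    """The synthetic-cohort LDL-C model failed to meet its calibration tolerance."""

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


class GenerationError(LltsimError):
    """Synthetic cohort generation failed (e.g. rejection-sampling cap exceeded)."""


class ValidationError(LltsimError):
    """A cohort file violated its schema; ``items`` lists row/column problems."""

    def __init__(self, items: list[str]):
        self.items = list(items)
        super().__init__(
            "cohort file failed validation:\n" + "\n".join(f"  - {i}" for i in items)
        )
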