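"""Exception hierarchy and structured validation issues."""

from __future__ import annotations

from dataclasses import dataclass


class YawnscopeError(Exception):
    """Base class for all package errors."""


class SchemaError(YawnscopeError):
    """A table is missing, has missing columns, or a wrong schema version."""


class DaytimeWindowError(YawnscopeError):
    """Event clock time falls outside the observation window."""


class UnknownAUCodeError(YawnscopeError):
    """An action-unit code is not in the declared vocabulary."""


class DegenerateInputError(YawnscopeError):
    """Input matrix is constant or too small for projection."""


class InsufficientDistinctPointsError(YawnscopeError):
    """k exceeds the number of distinct rows available for clustering."""


class StateGapError(YawnscopeError):
    """State intervals do not cover the queried window."""


class NonNestedModelsError(YawnscopeError):
    """Likelihood-ratio comparison requested for non-nested fits."""


class ConvergenceError(YawnscopeError):
    """A model fit did not converge."""


class GeneratorConfigError(YawnscopeError):
    """Synthetic-data configuration is infeasible or invalid."""


@dataclass(frozen=True)
class ValidationIssue:
    """One named validation failure located in an input table."""

    code: str
    table: str
    record_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.table}/{self.record_id}: {self.message}"


@dataclass(frozen=True)
class Rejection:
    """A record excluded from an analysis step, with an explicit reason."""

    record_id: str
    reason: str
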