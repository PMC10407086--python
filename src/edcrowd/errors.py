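"""Exception hierarchy shared across the package."""

from __future__ import annotations


class EdCrowdError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EdCrowdError):
    """A required configuration item is missing or inconsistent (e.g. an
    unknown ED id, a bed count <= 0, a column that cannot be resolved)."""


class DomainError(EdCrowdError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class EstimationError(EdCrowdError):
    """A statistical fit is degenerate or failed (no events, no contrast,
    non-convergence)."""


class SearchError(EdCrowdError):
    """A bounded numerical search exhausted its iteration budget."""


class PipelineError(EdCrowdError):
    """Wraps a stage failure in the end-to-end pipeline with stage context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage={stage}] {message}")
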