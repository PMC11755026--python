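"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: configuration problems exit 2, data
problems exit 3, model non-convergence exits 4.
"""


class NeighbordepError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(NeighbordepError):
    """Invalid configuration (bad parameter values, missing outcome models)."""

    exit_code = 2


class DataError(NeighbordepError):
    """Invalid or insufficient input data."""

    exit_code = 3


class InsufficientPopulationError(DataError):
    """Total population smaller than a requested neighborhood k-level."""

    def __init__(self, k_level: int, total: int):
        self.k_level = k_level
        self.total = total
        super().__init__(
            f"total population {total} is smaller than k-level {k_level}"
        )


class UndefinedIndexError(DataError):
    """Gini/Deaton undefined (empty reference group or zero mean income)."""


class DesignError(NeighbordepError):
    """Rank-deficient or otherwise unusable model design matrix."""

    exit_code = 3


class NonConvergenceError(NeighbordepError):
    """Logistic fit failed to converge; carries fit diagnostics."""

    exit_code = 4

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PipelineError(NeighbordepError):
    """A pipeline stage failed or its inputs were missing."""

    exit_code = 3
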