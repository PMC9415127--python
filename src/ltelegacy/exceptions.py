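"""Exception hierarchy shared by all ltelegacy modules."""


class LTELegacyError(Exception):
    """Base class for all package errors."""


class DatasetValidationError(LTELegacyError, ValueError):
    """One or more records violate a dataset invariant.

    Carries the full list of violations so callers see every problem,
    not only the first one encountered.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} validation problem(s):\n  "
            + "\n  ".join(self.problems)
        )


class PairingError(DatasetValidationError):
    """A plot observation is missing its required partner plot."""


class DomainError(LTELegacyError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigError(LTELegacyError, ValueError):
    """A synthetic-generator or pipeline configuration violates an invariant."""


class RankDeficientError(LTELegacyError, ValueError):
    """The fixed-effect design matrix is singular for the requested model."""
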