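"""Exception hierarchy for renangia."""


class RenangiaError(Exception):
    """Base class for all renangia errors."""


class InvalidInputError(RenangiaError, ValueError):
    """A value violates a precondition (wrong sign, missing field, length mismatch)."""


class ConfigurationError(RenangiaError, ValueError):
    """A score or cohort configuration is unusable (empty weights, bad simplex)."""


class ValidationFailure(RenangiaError):
    """A cohort CSV failed schema validation; carries the per-row report."""

    def __init__(self, report):
        self.report = report
        super().__init__(f"cohort validation failed with {len(report.errors)} error(s)")
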