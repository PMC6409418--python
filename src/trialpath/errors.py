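"""Exception hierarchy for trialpath.

Every error raised by the library derives from :class:`TrialPathError` so
callers (and the CLI) can distinguish library failures from programming
errors.
"""

from __future__ import annotations


class TrialPathError(Exception):
    """Base class for all trialpath errors."""


class SchemaError(TrialPathError):
    """A registry table is missing a mandatory column or has a malformed header."""


class DuplicateKeyError(TrialPathError):
    """Duplicate (trial, drug, indication, sponsor) quartets in a registry table."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        super().__init__(
            f"{len(self.offenders)} duplicate (trial_id, drug_id, indication_id, "
            f"sponsor_id) quartet(s); first offenders: {self.offenders[:5]}"
        )


class ConfigurationError(TrialPathError):
    """Invalid analysis configuration (bad dates, thresholds, missing snapshot...)."""


class ImputationError(TrialPathError):
    """End-date imputation is impossible: no donor record has an observed duration."""


class ConsistencyError(TrialPathError):
    """Internal invariant violated (development-path conservation law).

    Raised by the transition tabulator when the flow-balance identity fails;
    this is asserted to be unreachable on valid inputs.
    """


class UndefinedEstimateError(TrialPathError):
    """A POS estimate has an empty denominator.

    Carries the offending counts so callers can inspect what was tallied.
    """

    def __init__(self, message, counts=None):
        self.counts = counts
        super().__init__(message)
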