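"""Exception hierarchy shared across the pipeline stages."""


class HepalncError(Exception):
    """Base class for all package-specific errors."""


class GtfParseError(HepalncError, ValueError):
    """A GTF row could not be parsed; the message names the line number."""


class ValidationError(HepalncError, ValueError):
    """A domain object violates one of its invariants."""


class ConsistencyError(HepalncError, ValueError):
    """Records that should agree (e.g. one gene on one chromosome) do not."""


class ConfigurationError(HepalncError, ValueError):
    """A run was configured with missing or inconsistent inputs."""


class InsufficientReplicationError(HepalncError, ValueError):
    """A statistical test was requested with too few replicates per group."""
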