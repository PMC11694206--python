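"""Exception hierarchy shared across the pipeline."""


class SprintWindowError(Exception):
    """Base class for all package-specific errors."""


class TraceFormatError(SprintWindowError):
    """A trace/metadata file does not have the expected columns or dialect."""


class TraceIntegrityError(SprintWindowError):
    """File parses but violates a data invariant (e.g. non-monotone time)."""


class MetadataError(SprintWindowError):
    """Session metadata is inconsistent (e.g. unknown position code)."""


class ConfigError(SprintWindowError):
    """A configuration object violates its invariants."""


class InsufficientDataError(SprintWindowError):
    """Too few complete observations to compute the requested statistic."""


class MissingPositionError(SprintWindowError):
    """A position-level aggregate was requested with a position absent."""
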