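"""Exception types shared across the pipeline."""


class SgaScoreError(Exception):
    """Base class for all package errors."""


class FormatError(SgaScoreError, ValueError):
    """An on-disk table violates the expected dialect or an invariant."""


class ConfigurationError(SgaScoreError, ValueError):
    """A configuration object or CLI option set is internally inconsistent."""


class LayoutError(ConfigurationError):
    """Requested spots do not fit the plate geometry."""


class InsufficientDataError(SgaScoreError, ValueError):
    """Too few observations to compute the requested statistic."""
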