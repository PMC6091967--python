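"""Exception types shared across the pipeline."""


class CoidietError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CoidietError, ValueError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(CoidietError, ValueError):
    """Parsed data violates a structural invariant (e.g. tree/alignment mismatch)."""
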