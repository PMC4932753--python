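"""Exception hierarchy shared across the package."""


class PupilpathError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PupilpathError, ValueError):
    """An input file does not have the expected layout (e.g. missing column)."""


class ValidationError(PupilpathError, ValueError):
    """Parsed content violates a domain invariant (range, ordering, shape)."""


class UnrecoverableTrialError(PupilpathError):
    """A trial cannot be salvaged (e.g. zero valid pupil samples)."""


class InsufficientWindowError(PupilpathError):
    """An event sits too close to a recording edge to extract the full
    pre/post window; the trial is skipped, not repaired."""
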