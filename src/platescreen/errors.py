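"""Exception hierarchy for the toolkit."""


class PlatescreenError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(PlatescreenError, ValueError):
    """A tolerance, count, or other parameter is out of range."""


class FormatError(PlatescreenError, ValueError):
    """A file could not be parsed, or violates the expected schema."""


class InvariantError(PlatescreenError, ValueError):
    """A domain object violates one of its structural invariants."""


class UnsupportedModeError(FormatError):
    """The mzML run contains profile-mode spectra; only centroid data is supported."""


class InputError(PlatescreenError, ValueError):
    """Inconsistent user input (e.g. duplicate plate/well coordinates)."""
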