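"""Exception types shared across the package."""


class PtmHotspotsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PtmHotspotsError):
    """A required column, path, or parameter is missing or malformed."""


class ValidationError(PtmHotspotsError):
    """Input data violates an invariant (conflicting records, ragged alignment...)."""


class AlignerNotFoundError(PtmHotspotsError):
    """The external multiple-sequence aligner could not be executed."""


class PairingError(PtmHotspotsError):
    """A structure chain could not be matched to the claimed alignment member."""
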