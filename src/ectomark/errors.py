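"""Exception hierarchy shared by all ectomark stages."""


class EctomarkError(Exception):
    """Base class for all errors raised by ectomark."""


class ConfigurationError(EctomarkError, ValueError):
    """A simulation or analysis configuration is invalid; message names the field."""


class FormatError(EctomarkError, ValueError):
    """A file does not conform to its documented on-disk format."""


class InputError(EctomarkError, ValueError):
    """Inputs violate an operation's preconditions (misaligned IDs, missing columns...)."""


class GeneLookupError(EctomarkError, KeyError):
    """A requested gene is absent from the matrix or panel."""


class DegenerateDataError(EctomarkError, ValueError):
    """Data are statistically degenerate for the requested test (no events, empty group)."""


class DerivationError(EctomarkError, ValueError):
    """A threshold-derivation strategy cannot be applied to the supplied context."""
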