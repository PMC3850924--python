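"""Exception hierarchy.

All errors derive from :class:`NWRError` so callers can catch package
failures with a single ``except``; they also derive from the builtin the
condition corresponds to (``ValueError``, ``KeyError``-free design).
"""


class NWRError(Exception):
    """Base class for all package errors."""


class ParseError(NWRError, ValueError):
    """A text input could not be parsed; the message names the line."""


class IntegrityError(NWRError, ValueError):
    """Input violates a structural invariant (duplicates, missing metadata)."""


class BoundsError(NWRError, IndexError):
    """A requested segment falls outside a recorded trace."""


class ConfigurationError(NWRError, ValueError):
    """A configuration value is inconsistent with the data (e.g. a split
    ratio that cannot be realised within a stratum)."""


class CapacityError(NWRError, ValueError):
    """A stratum does not hold enough subjects for the requested draw."""


class ProtocolError(NWRError, ValueError):
    """The validation protocol was violated (e.g. training and evaluation
    subjects overlap, or the test set is touched during model selection)."""


class SchemaVersionError(NWRError, ValueError):
    """A serialized model bundle has an incompatible schema version."""
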