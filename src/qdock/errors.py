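"""Exception hierarchy.

Everything raised on purpose derives from :class:`QDockError` so callers can
catch the package's own failures without swallowing programming errors.
"""


class QDockError(Exception):
    """Base class for all qdock errors."""


class RangeViolationError(QDockError, ValueError):
    """A continuous property value lies outside its declared range."""


class EmptyChainError(QDockError, ValueError):
    """A molecule chain with zero interaction sites was supplied."""


class SizeError(QDockError, ValueError):
    """Incompatible sizes (ligand longer than protein, label mismatch, ...)."""


class CapacityError(QDockError, RuntimeError):
    """A requested register exceeds the configured qubit budget."""


class DegenerateInputError(QDockError, ValueError):
    """Input is degenerate for the requested operation (e.g. two zero-norm vectors)."""


class FixtureError(QDockError, RuntimeError):
    """The synthetic-data generator could not satisfy a plant specification."""


class ChainFormatError(QDockError, ValueError):
    """A chain CSV file is malformed."""


class ConfigError(QDockError, ValueError):
    """A run configuration is malformed or inconsistent."""
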