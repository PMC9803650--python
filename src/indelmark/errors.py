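"""Exception hierarchy.

``ConfigurationError`` maps to CLI exit code 2, ``DataError`` (and
subclasses) to exit code 3.
"""


class IndelmarkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IndelmarkError):
    """Invalid configuration: bad parameter values, unknown methods, samples
    missing from the group table."""


class DataError(IndelmarkError):
    """Invalid or inconsistent input data."""


class SizingError(DataError):
    """A simulated sequence is too small to host the requested features."""


class LocusMismatchError(DataError):
    """Two genotype sets do not share the same locus list."""
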