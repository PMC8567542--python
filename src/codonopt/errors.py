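"""Exception hierarchy for codonopt.

All package errors derive from :class:`CodonOptError` so callers (and the
CLI) can distinguish data errors from programming errors.
"""


class CodonOptError(Exception):
    """Base class for all codonopt errors."""


class AlphabetError(CodonOptError):
    """A sequence contains a character outside the expected alphabet."""


class FrameError(CodonOptError):
    """A nucleotide sequence length is not a multiple of three."""


class PrematureStopError(CodonOptError):
    """A stop codon occurs before the final position of a coding sequence."""


class InputError(CodonOptError):
    """An input is empty or structurally invalid."""


class ParameterError(CodonOptError):
    """A parameter value is outside its valid range."""


class TableError(CodonOptError):
    """A score or usage table failed to load or is incomplete."""


class SizeError(CodonOptError):
    """A brute-force enumeration would exceed the configured cap."""
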