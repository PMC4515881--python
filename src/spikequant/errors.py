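"""Exception hierarchy shared across the package.

``TableError`` marks malformed or inconsistent input (CLI exit code 2);
``InsufficientDataError`` marks inputs that parse but cannot support the
requested computation, e.g. fewer than two usable regression points
(CLI exit code 3).
"""


class SpikeQuantError(Exception):
    """Base class for all spikequant errors."""


class TableError(SpikeQuantError):
    """Structural or parse problem in an input table."""


class InsufficientDataError(SpikeQuantError):
    """Valid input that cannot support the requested computation."""
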