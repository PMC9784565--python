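"""Exception hierarchy shared across the package.

``InputError`` covers malformed or missing user inputs (exit code 2 in the
CLI); ``ComputationError`` covers degenerate numerical situations detected
while running the model (exit code 3).
"""


class FodmError(Exception):
    """Base class for all package errors."""


class InputError(FodmError):
    """Invalid, missing or unreadable input (file, table, accession)."""


class ComputationError(FodmError):
    """Degenerate or inconsistent state detected during computation."""
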