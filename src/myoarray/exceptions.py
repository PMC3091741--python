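"""Exception hierarchy shared across the pipeline.

``ValidationError`` covers malformed or inconsistent inputs (CLI exit code 2);
``ComputationError`` covers failures inside a statistical stage (exit code 3).
"""


class MyoarrayError(Exception):
    """Base class for all package errors."""


class ValidationError(MyoarrayError, ValueError):
    """Input data or parameters violate a documented invariant."""


class ComputationError(MyoarrayError, RuntimeError):
    """A statistical or numerical stage could not produce a result."""
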