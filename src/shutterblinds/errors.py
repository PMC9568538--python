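"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (validation 2, I/O 3, contract 4).
"""


class ShutterBlindsError(Exception):
    """Base class for all package errors."""


class ValidationError(ShutterBlindsError, ValueError):
    """Invalid user input: out-of-range value, wrong shape, bad config."""


class ContractViolationError(ShutterBlindsError, RuntimeError):
    """A pluggable component (e.g. a backbone) broke its declared contract."""


class InputOutputError(ShutterBlindsError, OSError):
    """Unreadable or unwritable file/image."""
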