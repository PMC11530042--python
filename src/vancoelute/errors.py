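"""Exception types shared across the package."""


class VancoeluteError(Exception):
    """Base class for all package errors."""


class ValidationError(VancoeluteError):
    """An input violated a documented precondition; message names the field."""


class StabilityError(VancoeluteError):
    """Time step exceeds the explicit-scheme bound dt <= dx^2 / (6 D)."""


class SolverFault(VancoeluteError):
    """The solver produced a non-physical state (negative / non-finite)."""
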