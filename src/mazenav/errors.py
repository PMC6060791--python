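"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class NumericalDegeneracyError(ArithmeticError):
    """A belief update produced a non-normalizable distribution."""


class DegeneratePreferenceError(ValueError):
    """The diffusion kernel assigns (numerically) zero mass everywhere."""


class TooShortSignalError(ValueError):
    """A trace is shorter than the filter warm-up it is being pushed through."""


class PrecisionFloorWarning(RuntimeWarning):
    """The precision update drove beta to (or below) zero; it was floored."""
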