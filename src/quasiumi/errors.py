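"""Exception hierarchy for quasiumi."""


class QuasiUMIError(Exception):
    """Base class for all quasiumi errors."""


class ParameterError(QuasiUMIError, ValueError):
    """A distribution parameter is outside its domain."""


class InputError(QuasiUMIError, ValueError):
    """Invalid user input (shapes, values, labels)."""


class DegenerateInputError(InputError):
    """Input is structurally degenerate (e.g. an all-zero cell)."""


class NoZerosError(InputError):
    """A cell has no zero entries, so its scale cannot be estimated
    from the zero fraction."""


class AllZeroError(InputError):
    """A cell is entirely zero."""


class CalibrationError(QuasiUMIError):
    """Too few cells converged to calibrate a shape parameter."""


class FormatError(InputError):
    """A matrix file could not be parsed."""
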