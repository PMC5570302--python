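"""Exception types shared across the package."""


class VecvError(Exception):
    """Base class for all package errors."""


class InputError(VecvError, ValueError):
    """Malformed or inconsistent input (length mismatch, missing values, bad names)."""


class UndefinedMeasureError(VecvError, ValueError):
    """A measure is mathematically undefined for the given data.

    Examples: Pearson r of a constant prediction vector, variance-normalised
    measures on a constant observed vector, relative errors when the observed
    mean is zero.
    """

    def __init__(self, measure: str, reason: str):
        self.measure = measure
        self.reason = reason
        super().__init__(f"{measure} is undefined: {reason}")
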