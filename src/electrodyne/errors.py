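"""Exception hierarchy."""


class ElectrodyneError(Exception):
    """Base class for all package errors."""


class ValidationError(ElectrodyneError, ValueError):
    """A field failed validation.

    Carries the name of the offending field so callers (and CLI error
    messages) can point at it directly.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class UnitsMismatchError(ElectrodyneError, ValueError):
    """Declared unit conventions of two objects disagree.

    Raised instead of silently converting, because the empirical
    excursion-model coefficient `b` is unit-convention dependent.
    """


class ConvergenceError(ElectrodyneError, RuntimeError):
    """A numerical routine failed to converge within its budget."""


class SampleCountError(ElectrodyneError, ValueError):
    """A transient simulation would exceed the sample-count ceiling."""
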