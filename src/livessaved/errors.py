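"""Exception types shared across the package."""


class LivesSavedError(Exception):
    """Base class for package errors."""


class ProfileValidationError(LivesSavedError):
    """A country profile violated an invariant.

    Carries the offending field (and, where applicable, the row key) so
    callers can point users at the exact cell of the input tables.
    """

    def __init__(self, field: str, message: str, row=None):
        self.field = field
        self.row = row
        loc = f"{field}[{row}]" if row is not None else field
        super().__init__(f"{loc}: {message}")


class DegenerateInputError(LivesSavedError):
    """A cause is fully averted at baseline, so the counterfactual ratio
    is undefined (division by a zero residual)."""


class ConsistencyError(LivesSavedError):
    """Internal accounting invariant violated (should not occur)."""
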