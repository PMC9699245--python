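"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: schema/input problems -> 2,
fit non-convergence -> 3. Domain errors (invalid parameter values)
are ordinary ``ValueError`` subclasses so library users can catch
them without importing anything special.
"""


class FibrilkinError(Exception):
    """Base class for all toolkit errors."""


class DomainError(FibrilkinError, ValueError):
    """A parameter value outside its mathematical domain (e.g. k <= 0)."""


class InputError(FibrilkinError, ValueError):
    """Structurally invalid input data (too few points, bad window...)."""


class SchemaError(FibrilkinError, ValueError):
    """A CSV file that does not match the expected schema.

    Carries the offending row number (1-based, counting the header as
    row 1) when the problem is localised to a row.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class FitError(FibrilkinError, RuntimeError):
    """A fit that cannot be carried out at all (as opposed to a fit
    that runs but fails to converge, which is reported in-band via a
    ``converged=False`` flag)."""
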