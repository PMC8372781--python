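"""Exception hierarchy for litterbmd."""


class LitterBmdError(Exception):
    """Base class for all litterbmd errors."""


class SchemaError(LitterBmdError):
    """Input table is missing required columns or is otherwise malformed."""


class ValidationError(LitterBmdError):
    """A row or record violates a domain invariant (e.g. affected > size)."""


class InsufficientDataError(LitterBmdError):
    """Not enough litters/groups/points for the requested computation."""


class DegenerateGroupError(LitterBmdError):
    """A dose group has proportion affected of exactly 0 or 1, so the
    design effect is undefined (callers conventionally substitute D = 1)."""


class MissingCoefficientsError(LitterBmdError):
    """No historical regression coefficients available for the species."""


class FitError(LitterBmdError):
    """Model fitting failed or the fit does not support the request."""
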