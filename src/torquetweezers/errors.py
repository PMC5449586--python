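"""Exception hierarchy for torquetweezers."""


class TorqueTweezersError(Exception):
    """Base class for package errors."""


class InvalidInputError(TorqueTweezersError, ValueError):
    """Input violates a documented precondition."""


class RegimeError(TorqueTweezersError, ValueError):
    """Model evaluated outside its regime of validity (names the violated inequality)."""


class CircleFitError(TorqueTweezersError, RuntimeError):
    """Circle fit failed (degenerate / collinear points)."""


class FitError(TorqueTweezersError, RuntimeError):
    """A least-squares fit failed to converge or lacks data."""


class SchemaError(TorqueTweezersError, ValueError):
    """A table is missing required columns or has an unknown format version."""


class DataError(TorqueTweezersError, ValueError):
    """A table's contents violate an invariant (e.g. non-monotonic time)."""
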