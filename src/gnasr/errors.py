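"""Exception hierarchy.

Every error raised by the package derives from :class:`GnasrError` so callers
(and the CLI) can catch one base class and report the failing stage.
"""


class GnasrError(Exception):
    """Base class for all gnasr errors."""


class InvalidMotionError(GnasrError):
    """Internal-motion parameters are inconsistent (e.g. S2 < 1 with tau <= 0)."""


class InfeasibleModelError(GnasrError):
    """Tumbling/exchange model has a non-decaying orientational component.

    A bound, non-tumbling state with zero exchange (or a model in which both
    states stop tumbling) makes J(0) infinite and R2 undefined.
    """


class InsufficientDataError(GnasrError):
    """Too few residues/observables for the requested estimate."""


class EstimationError(GnasrError):
    """Global tumbling-time estimation failed (no root in the search bracket)."""


class PairingError(GnasrError):
    """Free and gel tables share no residues."""


class CalibrationError(GnasrError):
    """Calibration-mask mean of the delta profile is not positive."""


class ComparisonError(GnasrError):
    """Profiles share too few residues to compare."""


class FormatError(GnasrError):
    """Malformed input table (duplicate residue, bad number, wrong header)."""


class OracleFailure(GnasrError):
    """Numerical quadrature oracle did not converge."""
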