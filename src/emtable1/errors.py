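"""Exception types shared across the toolkit.

Curation deliberately does NOT raise: admission failures are verdict codes.
These exceptions cover genuinely unusable inputs (unparsable files,
degenerate math) and contract violations.
"""


class EmTable1Error(Exception):
    """Base class for all toolkit errors."""


class ParseFailureError(EmTable1Error):
    """A model or map file could not be parsed (feeds the PROCESS_FAILURE filter)."""


class NonsensicalBoxError(EmTable1Error):
    """Map header declares non-positive cell or grid dimensions."""


class InvalidOperatorError(EmTable1Error):
    """An assembly operator matrix is singular."""


class MissingResolutionError(EmTable1Error):
    """Neither model nor map metadata carries a resolution value."""


class UndefinedCorrelationError(EmTable1Error):
    """Correlation requested on constant (zero-variance) input."""


class EmptyEnvelopeError(EmTable1Error):
    """An atom mask selects no voxels."""


class UnknownElementError(EmTable1Error):
    """Element missing from the scattering table (no fallback requested)."""


class UndefinedStatisticError(EmTable1Error):
    """A geometry statistic is undefined for the given model (too few items)."""


class CalibrationError(EmTable1Error):
    """Monte Carlo null calibration failed (degenerate reference)."""


class InvalidSpecError(EmTable1Error):
    """A fixture specification violates its own constraints (e.g. Nyquist)."""


class IncompleteReportError(EmTable1Error):
    """Table 1 assembly is missing an upstream stage result."""
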