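"""Exception hierarchy for lyoscat.

All package errors derive from :class:`LyoscatError` so callers can catch
one base class at CLI boundaries.
"""


class LyoscatError(Exception):
    """Base class for all lyoscat errors."""


class MalformedInputError(LyoscatError):
    """Input file or table does not meet the minimal structural contract."""


class DuplicateAbscissaError(MalformedInputError):
    """q grid contains duplicate values after sorting."""


class UnitError(LyoscatError):
    """Unknown or inconsistent unit tag."""


class ParameterError(LyoscatError, ValueError):
    """Model parameters violate an invariant."""


class ConfigurationError(LyoscatError):
    """Inconsistent component configuration (e.g. all model terms disabled)."""


class GeometryError(LyoscatError):
    """A derived structural quantity has no real solution."""


class FitError(LyoscatError):
    """Optimization failed to converge; carries the best attempt."""

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class NoAggregationError(LyoscatError):
    """Concentration series shows no scattering increase (no CAC)."""


class MassBalanceError(LyoscatError):
    """Cumulative released mass exceeds the loaded amount beyond tolerance."""


class NoPeriodicityError(LyoscatError):
    """No spectral peak above the prominence threshold."""


class InsufficientProfileError(LyoscatError):
    """Gray-value profile contains fewer than two complete periods."""


class SamplingError(LyoscatError):
    """Requested spatial period violates the Nyquist limit."""


class PhaseStateError(LyoscatError):
    """Operation requires an assigned phase."""
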