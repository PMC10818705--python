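"""Exception and warning hierarchy for hopmap.

The CLI maps these onto distinct exit codes: configuration problems (2),
data/format problems (3), fit-convergence problems (4).
"""


class HopmapError(Exception):
    """Base class for all hopmap errors."""


class ConfigError(HopmapError):
    """Invalid configuration or physical-parameter values."""


class DataError(HopmapError):
    """Malformed, inconsistent, or missing input data."""


class UnitsError(DataError):
    """Input table declared in the wrong units (potentials must be V, not mV)."""


class TraceFormatError(DataError):
    """Kinetic-trace file violates the two-column format contract."""


class ConvergenceError(HopmapError):
    """A nonlinear fit failed to converge."""


class IdentifiabilityWarning(UserWarning):
    """The two fitted rates are too close to be reliably distinguished."""


class PhaseAmbiguityWarning(UserWarning):
    """Fast/slow phase assignment is ambiguous (rates within a factor of 2)."""
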