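"""Exception hierarchy shared across the pipeline."""


class Breath2PlasmaError(Exception):
    """Base class for all package errors."""


class DataError(Breath2PlasmaError):
    """Input series unusable (empty, too few points, bad values)."""


class DegenerateModelError(Breath2PlasmaError):
    """Compartment model exponents coincide (non-distinct roots)."""


class InconsistentMacroError(Breath2PlasmaError):
    """Macro constants do not correspond to a valid micro parameterization."""


class FitFailureError(Breath2PlasmaError):
    """Least-squares fit did not converge; carries the best iterate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class MetricsUnavailableError(Breath2PlasmaError):
    """Cmax/Tmax undefined because every point is censored."""


class CalibrationError(Breath2PlasmaError):
    """Calibration curve cannot be fitted or is non-monotone."""


class OutOfRangeError(CalibrationError):
    """Signal inverts to a concentration outside the trusted range."""


class UnitError(Breath2PlasmaError):
    """Unknown or incompatible unit conversion requested."""


class PairingError(Breath2PlasmaError):
    """No breath/plasma pairs could be formed."""


class RegressionError(Breath2PlasmaError):
    """Log-log regression inputs are degenerate."""


class UndefinedStatisticError(Breath2PlasmaError):
    """Statistic undefined for this input (zero variance, constant data)."""


class RefusedComparisonError(Breath2PlasmaError):
    """Cross-matrix comparison refused for unit-incommensurable parameters."""


class SchemaError(Breath2PlasmaError):
    """CSV input violates the series schema; message names offending rows."""
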