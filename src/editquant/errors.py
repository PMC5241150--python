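"""Exception hierarchy shared across the package."""


class EditQuantError(Exception):
    """Base class for all package errors."""


class WindowRangeError(EditQuantError):
    """Analysis window lies (partly) outside the melt curve's temperature range."""


class DegenerateCurveError(EditQuantError):
    """Melt curve has no dynamic range inside the analysis window."""


class GridMismatchError(EditQuantError):
    """Two melt curves are not defined on compatible temperature grids."""


class InsufficientDataError(EditQuantError):
    """Too few calibration points (or dilution levels) for the requested fit."""


class FitError(EditQuantError):
    """Least-squares design is degenerate (e.g. collinear calibration points)."""


class OutOfCalibrationError(EditQuantError):
    """Quadratic inversion has no real root: the DCA is outside the calibrated range."""


class InvalidSeriesError(EditQuantError):
    """Dilution series with non-negative slope: no meaningful amplification efficiency."""


class IncompleteInputError(EditQuantError):
    """A required Cq measurement (e.g. the reference target) is missing."""


class UndefinedRatioError(EditQuantError):
    """Denominator of a requested ratio is zero (e.g. %HDR_t with HN = 0)."""
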