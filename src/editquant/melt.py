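"""Quantitative high-resolution melting analysis (HRMA).

A post-PCR melt exposes sequence variants as shifts in the melting profile:
amplicons carrying indels melt at a lower (or occasionally higher) temperature
than wild type, so a mixed population produces a melt curve intermediate
between the pure wild-type and pure mutant curves.  This module implements the
quantitative workflow built on that observation:

1. restrict each raw fluorescence curve to an analysis window and normalize it
   to [0, 1] (``normalize_melt_curve``);
2. subtract the normalized control profile from each test profile and
   integrate the absolute difference over temperature — the *difference curve
   area* (DCA, in normalized-RFU·°C) (``difference_curve``);
3. calibrate DCA against known mutant percentages with a second-order
   polynomial standard curve (``fit_standard_curve``);
4. invert the calibration to estimate the mutant fraction of an unknown
   sample from its DCA (``estimate_mutant_fraction``).

The DCA is defined as the trapezoidal integral of the *absolute* difference,
so it is non-negative regardless of the direction of the Tm shift and is zero
only when test and control profiles coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCurveError,
    FitError,
    GridMismatchError,
    InsufficientDataError,
    OutOfCalibrationError,
    WindowRangeError,
)

__all__ = [
    "MeltCurve",
    "AnalysisWindow",
    "NormalizedMeltCurve",
    "DifferenceCurve",
    "StandardCurve",
    "MutantFractionEstimate",
    "normalize_melt_curve",
    "difference_curve",
    "fit_standard_curve",
    "estimate_mutant_fraction",
    "mean_curve",
    "replicate_dca",
    "suggest_window",
    "read_melt_csv",
]

_GRID_TOL = 1e-6  # max deviation (°C) tolerated in the uniform-step check

Orientation = Literal["dca-from-pct", "pct-from-dca"]


def _as_uniform_grid(temperatures: Sequence[float]) -> np.ndarray:
    t = np.asarray(temperatures, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("temperature grid needs at least two points")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise ValueError("temperatures must be strictly increasing")
    if np.ptp(steps) > _GRID_TOL:
        raise ValueError("temperature step must be uniform within 1e-6 °C")
    return t


@dataclass(frozen=True)
class MeltCurve:
    """Raw melt profile for one well/sample: fluorescence vs temperature."""

    label: str
    temperatures: np.ndarray
    rfu: np.ndarray

    def __post_init__(self):
        t = _as_uniform_grid(self.temperatures)
        f = np.asarray(self.rfu, dtype=float)
        if f.shape != t.shape:
            raise ValueError("temperatures and rfu must have equal length")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "rfu", f)

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])


@dataclass(frozen=True)
class AnalysisWindow:
    """Temperature window: 100 % fluorescence at ``t_low``, 0 % at ``t_high``."""

    t_low: float
    t_high: float

    def __post_init__(self):
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be below t_high")


@dataclass(frozen=True)
class NormalizedMeltCurve:
    """Melt profile restricted to the window, scaled so max = 1 and F(t_high) = 0."""

    label: str
    temperatures: np.ndarray
    norm_rfu: np.ndarray


@dataclass(frozen=True)
class DifferenceCurve:
    """Pointwise (test − control) normalized fluorescence and its area (DCA)."""

    temperatures: np.ndarray
    delta: np.ndarray
    dca: float


@dataclass(frozen=True)
class MutantFractionEstimate:
    """Mutant percentage estimated from a standard curve.

    ``out_of_range`` flags estimates outside [0, 100]; the value is never
    clamped (estimates slightly above 100 % are physically meaningful noise).
    """

    percent: float
    out_of_range: bool

    def __float__(self) -> float:
        return self.percent


def normalize_melt_curve(curve: MeltCurve, window: AnalysisWindow) -> NormalizedMeltCurve:
    """Restrict ``curve`` to ``window`` and rescale fluorescence to [0, 1].

    The fluorescence at the high cut-off temperature defines 0 %, and the
    maximum of the baseline-subtracted profile defines 100 %.  The result is
    invariant under positive affine transforms of the raw fluorescence.
    """
    t, f = curve.temperatures, curve.rfu
    eps = _GRID_TOL
    if window.t_low < t[0] - eps or window.t_high > t[-1] + eps:
        raise WindowRangeError(
            f"window [{window.t_low}, {window.t_high}] outside curve range "
            f"[{t[0]}, {t[-1]}] for {curve.label!r}"
        )
    mask = (t >= window.t_low - eps) & (t <= window.t_high + eps)
    t_w, f_w = t[mask], f[mask]
    baseline = float(np.interp(window.t_high, t, f))
    shifted = f_w - baseline
    peak = float(shifted.max())
    if peak <= 0.0:
        raise DegenerateCurveError(
            f"curve {curve.label!r} has no dynamic range inside the window"
        )
    return NormalizedMeltCurve(curve.label, t_w, shifted / peak)


def difference_curve(test: NormalizedMeltCurve, control: NormalizedMeltCurve) -> DifferenceCurve:
    """Subtract ``control`` from ``test`` pointwise and integrate |Δ| over T.

    The two curves must share a temperature grid.  Grids with equal step but
    a sub-half-step offset are linearly interpolated onto the control grid;
    anything else raises :class:`GridMismatchError` (silently comparing curves
    from different runs is the failure mode this guards against).
    """
    t_c, t_t = control.temperatures, test.temperatures
    y_t = test.norm_rfu
    if t_c.shape == t_t.shape and np.allclose(t_c, t_t, atol=_GRID_TOL):
        t, delta = t_c, y_t - control.norm_rfu
    else:
        step_c = t_c[1] - t_c[0]
        step_t = t_t[1] - t_t[0]
        offset = abs(t_t[0] - t_c[0])
        if abs(step_c - step_t) > _GRID_TOL or offset >= step_c / 2:
            raise GridMismatchError(
                f"incompatible grids for {test.label!r} vs {control.label!r}"
            )
        interp = np.interp(t_c, t_t, y_t)
        t, delta = t_c, interp - control.norm_rfu
    dca = float(np.trapezoid(np.abs(delta), t))
    return DifferenceCurve(t, delta, dca)


@dataclass(frozen=True)
class StandardCurve:
    """Degree-2 polynomial calibration between mutant percentage and DCA.

    ``coefficients`` are in descending degree for the fitted orientation:
    with ``orientation="dca-from-pct"`` (default) the polynomial maps percent
    to DCA, matching how a calibration plot of DCA vs percentage is drawn,
    and estimation inverts it analytically; ``"pct-from-dca"`` maps DCA to
    percent and estimation is a direct evaluation.
    """

    coefficients: np.ndarray
    orientation: Orientation
    r_squared: float
    points: tuple = field(default_factory=tuple)  # (percent, dca) pairs retained

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (3,):
            raise ValueError("expected three polynomial coefficients (degree 2)")
        object.__setattr__(self, "coefficients", c)

    def residuals(self) -> np.ndarray:
        """Observed − predicted at the calibration points, in the fit orientation."""
        pct = np.array([p for p, _ in self.points])
        dca = np.array([d for _, d in self.points])
        if self.orientation == "dca-from-pct":
            return dca - np.polyval(self.coefficients, pct)
        return pct - np.polyval(self.coefficients, dca)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficients": self.coefficients.tolist(),
            "orientation": self.orientation,
            "r_squared": self.r_squared,
            "points": [list(p) for p in self.points],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["coefficients"], dtype=float),
            d["orientation"],
            float(d["r_squared"]),
            tuple(tuple(p) for p in d["points"]),
        )


def fit_standard_curve(
    points: Iterable[tuple[float, float]],
    orientation: Orientation = "dca-from-pct",
) -> StandardCurve:
    """Least-squares degree-2 polynomial through (nominal percent, DCA) pairs.

    ``r_squared`` is the coefficient of determination of the fit in the
    requested orientation.  At least four points are required so the quadratic
    is overdetermined.
    """
    pts = tuple((float(p), float(d)) for p, d in points)
    if len(pts) < 4:
        raise InsufficientDataError("standard curve needs at least 4 calibration points")
    pct = np.array([p for p, _ in pts])
    dca = np.array([d for _, d in pts])
    if np.any(pct < 0) or np.any(pct > 100):
        raise ValueError("nominal percentages must lie in [0, 100]")
    x, y = (pct, dca) if orientation == "dca-from-pct" else (dca, pct)
    if np.ptp(x) == 0:
        raise FitError("calibration points are degenerate (no spread in the predictor)")
    try:
        coeffs = np.polyfit(x, y, 2)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numpy rarely fails here
        raise FitError(str(exc)) from exc
    resid = y - np.polyval(coeffs, x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise FitError("response values are constant; cannot define r_squared")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return StandardCurve(coeffs, orientation, r2, pts)


def _invert_quadratic(coeffs: np.ndarray, y: float) -> float:
    """Real root of a·x² + b·x + c = y closest to [0, 100] (ties → smaller root)."""
    a, b, c = coeffs
    if abs(a) < 1e-14:
        if abs(b) < 1e-14:
            raise OutOfCalibrationError("degenerate polynomial: cannot invert")
        return (y - c) / b
    disc = b * b - 4.0 * a * (c - y)
    if disc < 0:
        raise OutOfCalibrationError(f"no real root for DCA={y}: outside calibrated range")
    sq = float(np.sqrt(disc))
    roots = sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a)))

    def dist(x: float) -> float:
        return 0.0 if 0.0 <= x <= 100.0 else min(abs(x), abs(x - 100.0))

    # sorted() puts the smaller root first, so min() resolves exact ties to it
    return min(roots, key=dist)


def estimate_mutant_fraction(curve: StandardCurve, dca: float) -> MutantFractionEstimate:
    """Estimate the mutant percentage corresponding to an observed DCA.

    For the default ``dca-from-pct`` orientation the quadratic is inverted
    analytically, choosing the real root closest to the physical range
    [0, 100]; for ``pct-from-dca`` the polynomial is evaluated directly.
    Out-of-range estimates are returned unclamped with ``out_of_range=True``.
    """
    if dca < 0:
        raise ValueError("DCA must be non-negative")
    if curve.orientation == "dca-from-pct":
        pct = _invert_quadratic(curve.coefficients, float(dca))
    else:
        pct = float(np.polyval(curve.coefficients, float(dca)))
    return MutantFractionEstimate(pct, not 0.0 <= pct <= 100.0)


def mean_curve(curves: Sequence[NormalizedMeltCurve], label: str = "mean") -> NormalizedMeltCurve:
    """Pointwise mean of replicate normalized curves (shared grid required)."""
    if not curves:
        raise InsufficientDataError("no curves to average")
    t0 = curves[0].temperatures
    for c in curves[1:]:
        if c.temperatures.shape != t0.shape or not np.allclose(c.temperatures, t0, atol=_GRID_TOL):
            raise GridMismatchError("replicate curves are on different grids")
    stack = np.vstack([c.norm_rfu for c in curves])
    return NormalizedMeltCurve(label, t0, stack.mean(axis=0))


def replicate_dca(
    tests: Sequence[NormalizedMeltCurve],
    controls: Sequence[NormalizedMeltCurve],
) -> tuple[float, float, list[DifferenceCurve]]:
    """Per-replicate difference curves against the mean control profile.

    Returns ``(mean_dca, sd_dca, per_replicate_curves)``.  The replicate mean
    DCA is what feeds :func:`estimate_mutant_fraction`; the SD quantifies
    run-to-run spread (ddof=1, zero for a single replicate).
    """
    ctrl = mean_curve(controls, label="mean-control")
    diffs = [difference_curve(t, ctrl) for t in tests]
    dcas = np.array([d.dca for d in diffs])
    sd = float(dcas.std(ddof=1)) if len(dcas) > 1 else 0.0
    return float(dcas.mean()), sd, diffs


def suggest_window(curves: Sequence[MeltCurve], slope_frac: float = 0.01) -> AnalysisWindow:
    """Heuristic analysis window from the pooled melt transition.

    Picks the outermost temperatures at which the pooled mean |dF/dT| falls
    below ``slope_frac`` of its maximum, i.e. the flat pre- and post-melt
    plateaus flanking the transition.  Intended as a starting point; windows
    are normally chosen per assay.
    """
    if not curves:
        raise InsufficientDataError("no curves supplied")
    t = curves[0].temperatures
    pooled = np.vstack([c.rfu for c in curves]).mean(axis=0)
    slope = np.abs(np.gradient(pooled, t))
    thresh = slope_frac * slope.max()
    quiet = np.flatnonzero(slope <= thresh)
    peak = int(np.argmax(slope))
    low = quiet[quiet < peak]
    high = quiet[quiet > peak]
    t_low = t[low[-1]] if low.size else t[0]
    t_high = t[high[0]] if high.size else t[-1]
    return AnalysisWindow(float(t_low), float(t_high))


def read_melt_csv(path: str | Path, fmt: Literal["wide", "long"] = "wide") -> list[MeltCurve]:
    """Read melt curves from CSV.

    ``wide``: first column ``Temperature`` (°C), one column of raw RFU per
    well/sample.  ``long``: columns ``sample, temperature, rfu``.
    """
    df = pd.read_csv(path, comment="#")
    if fmt == "wide":
        tcol = df.columns[0]
        t = df[tcol].to_numpy(dtype=float)
        return [MeltCurve(str(col), t, df[col].to_numpy(dtype=float)) for col in df.columns[1:]]
    curves = []
    for sample, grp in df.groupby("sample", sort=False):
        grp = grp.sort_values("temperature")
        curves.append(
            MeltCurve(str(sample), grp["temperature"].to_numpy(float), grp["rfu"].to_numpy(float))
        )
    return curves
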