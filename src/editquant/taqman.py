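"""Efficiency-corrected relative quantification of qPCR (TaqMan) data.

A hydrolysis-probe qPCR reports the quantification cycle Cq at which target
amplification crosses threshold.  Relative template amounts between samples
are computed with the efficiency-corrected ratio (the Pfaffl formula)

    ratio = E_target ** dCq_target / E_reference ** dCq_reference,

where E is the fold-amplification per cycle estimated from a dilution series
and dCq = Cq(control) − Cq(sample).  With that sign convention a ratio of 1
means "same template as the control" and, when the assay probe spans a
genome-editing cut site, the ratio read directly as the remnant wild-type
fraction of an edited sample.

The uncertainty attached to a ratio is a first-order (delta-method)
propagation of the replicate Cq standard deviations:

    sd(ratio) ≈ ratio * sqrt( ln(E_t)² (sd_t,s² + sd_t,c²)
                            + ln(E_r)² (sd_r,s² + sd_r,c²) )

treating the four mean Cq values as independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IncompleteInputError, InsufficientDataError, InvalidSeriesError

__all__ = [
    "CqStats",
    "DilutionSeries",
    "EfficiencyFit",
    "RelativeQuantity",
    "cq_stats",
    "fit_efficiency",
    "relative_quantity",
    "normalize_panel",
    "efficiency_to_percent",
    "read_cq_csv",
    "read_dilution_csv",
]


@dataclass(frozen=True)
class CqStats:
    """Replicate-aggregated Cq for one sample × target: mean, SD (ddof=1), n."""

    mean: float
    sd: float
    n: int


def cq_stats(cqs: Sequence[float]) -> CqStats:
    """Aggregate replicate Cq values; non-finite entries (failed wells) are dropped."""
    arr = np.asarray(list(cqs), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise IncompleteInputError("no finite Cq replicates")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return CqStats(float(arr.mean()), sd, int(arr.size))


@dataclass(frozen=True)
class DilutionSeries:
    """Serial-dilution Cq data: (log10 relative input, Cq replicates) per level."""

    levels: tuple[tuple[float, tuple[float, ...]], ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, Sequence[float]]]) -> "DilutionSeries":
        return cls(tuple((float(x), tuple(float(c) for c in cq)) for x, cq in pairs))


@dataclass(frozen=True)
class EfficiencyFit:
    """Regression of mean Cq on log10 input: slope, intercept, E = 10^(−1/slope)."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float


@dataclass(frozen=True)
class RelativeQuantity:
    """Efficiency-corrected relative quantity for one sample, with delta-method SD."""

    label: str
    ratio: float
    sd: float
    e_target: float
    e_reference: float
    dcq_target: float
    dcq_reference: float


def fit_efficiency(series: DilutionSeries) -> EfficiencyFit:
    """Fit the dose-response line mean Cq ~ log10(input) and derive E.

    A perfect doubling assay gives slope −3.3219 cycles/decade and E = 2.
    Series with fewer than three distinct dilution levels are rejected, as
    are non-negative slopes (more template must amplify earlier).
    """
    if len({x for x, _ in series.levels}) < 3:
        raise InsufficientDataError("dilution series needs >= 3 distinct levels")
    x = np.array([lvl for lvl, _ in series.levels], dtype=float)
    y = np.array([cq_stats(reps).mean for _, reps in series.levels])
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise InvalidSeriesError(f"non-negative slope ({slope:.3f}): invalid dilution series")
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return EfficiencyFit(float(slope), float(intercept), float(10.0 ** (-1.0 / slope)), r2)


def efficiency_to_percent(efficiency: float) -> float:
    """Convert fold-per-cycle E (1–2) to percent efficiency (0–100)."""
    return 100.0 * (efficiency - 1.0)


def _as_stats(value) -> CqStats:
    if isinstance(value, CqStats):
        return value
    if isinstance(value, (int, float)):
        return CqStats(float(value), 0.0, 1)
    return cq_stats(value)


def relative_quantity(
    label: str,
    sample_cq: Mapping[str, object],
    control_cq: Mapping[str, object],
    e_target: float,
    e_reference: float,
) -> RelativeQuantity:
    """Efficiency-corrected ratio of ``sample`` to ``control``.

    ``sample_cq`` / ``control_cq`` map ``"target"`` and ``"reference"`` to a
    Cq value, a replicate sequence, or a :class:`CqStats`.  dCq is control
    minus sample, so more template in the sample gives ratio > 1 and an
    unedited control anchors at 1.
    """
    for name, d in (("sample", sample_cq), ("control", control_cq)):
        for key in ("target", "reference"):
            if key not in d:
                raise IncompleteInputError(f"{name}_cq is missing the {key!r} Cq")
    if not (1.0 < e_target <= 2.2 and 1.0 < e_reference <= 2.2):
        raise ValueError("efficiencies must lie in (1, 2.2]")
    st, sr = _as_stats(sample_cq["target"]), _as_stats(sample_cq["reference"])
    ct, cr = _as_stats(control_cq["target"]), _as_stats(control_cq["reference"])
    if min(st.mean, sr.mean, ct.mean, cr.mean) <= 0:
        raise ValueError("Cq values must be positive")
    dcq_t = ct.mean - st.mean
    dcq_r = cr.mean - sr.mean
    ratio = e_target**dcq_t / e_reference**dcq_r
    var = (math.log(e_target) ** 2) * (st.sd**2 + ct.sd**2) + (
        math.log(e_reference) ** 2
    ) * (sr.sd**2 + cr.sd**2)
    return RelativeQuantity(label, float(ratio), float(ratio * math.sqrt(var)),
                            e_target, e_reference, float(dcq_t), float(dcq_r))


def normalize_panel(samples: Sequence[RelativeQuantity], anchor: str) -> list[RelativeQuantity]:
    """Divide every ratio by the anchor sample's ratio (anchor becomes 1.0).

    SDs scale with the ratios (the anchor is treated as the fixed unit).
    Idempotent and order-preserving.
    """
    by_label = {s.label: s for s in samples}
    if anchor not in by_label:
        raise KeyError(f"anchor sample {anchor!r} not in panel")
    a = by_label[anchor].ratio
    if a <= 0:
        raise ValueError("anchor ratio must be positive")
    return [
        RelativeQuantity(s.label, s.ratio / a, s.sd / a, s.e_target, s.e_reference,
                         s.dcq_target, s.dcq_reference)
        for s in samples
    ]


def read_cq_csv(path: str | Path) -> pd.DataFrame:
    """Long-format Cq table: columns ``sample, target, replicate, cq``."""
    df = pd.read_csv(path, comment="#")
    missing = {"sample", "target", "cq"} - set(df.columns)
    if missing:
        raise IncompleteInputError(f"Cq CSV is missing columns: {sorted(missing)}")
    return df


def read_dilution_csv(path: str | Path, target: str) -> DilutionSeries:
    """Dilution-series CSV (``target, log10_input, replicate, cq``) for one target."""
    df = pd.read_csv(path, comment="#")
    df = df[df["target"] == target]
    if df.empty:
        raise IncompleteInputError(f"no dilution rows for target {target!r}")
    pairs = [
        (float(lvl), grp["cq"].tolist())
        for lvl, grp in df.groupby("log10_input", sort=True)
    ]
    return DilutionSeries.from_pairs(pairs)
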