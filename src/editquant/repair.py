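"""Partition of double-strand-break repair into NHEJ and HDR frequencies.

Four probe-panel relative quantities (all anchored so the unedited control
Ec = 1) measure how much amplifiable, probe-binding wild-type target remains
under different co-transfections:

- ``Eb``      edited + empty backbone plasmid, cut-site (homologous) probe —
              only NHEJ indels remove signal;
- ``Ed_hom``  edited + donor template, homologous probe — NHEJ and HDR both
              remove signal (HDR replaces the locus and deletes the primer
              and probe sites);
- ``Ed_het``  edited + donor, *heterologous* probe at an adjacent site —
              unaffected by cut-site indels, lost only on donor integration,
              hence a direct readout of true HDR.

The derived frequencies::

    N      = (Ec − Eb) / Ec          NHEJ
    HN     = (Ec − Ed_hom) / Ec      NHEJ + HDR combined
    HDR_a  = (HN − N) / Ec           apparent HDR (difference of the above)
    HDR_t  = (Ec − Ed_het) / Ec      true HDR
    %HDR_t = 100 · HDR_t / HN        share of combined repair that is true HDR

``HDR_a`` divides the already-normalized difference by Ec a second time; with
the conventional anchoring Ec = 1 this is indistinguishable from HN − N, and
the formula is kept in that published form.  ``strict=True`` computes HN − N
instead.  Noise can push frequencies slightly negative or make HN < N; such
values are flagged, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import UndefinedRatioError

__all__ = ["ProbePanel", "RepairEstimate", "estimate_repair", "account_totals",
           "TotalAccounting", "read_panel_csv", "estimates_to_frame"]


@dataclass(frozen=True)
class ProbePanel:
    """Relative quantities for one editing condition (see module docstring)."""

    label: str
    ec: float
    eb: float
    ed_hom: float
    ed_het: float | None = None

    def __post_init__(self):
        if self.ec <= 0:
            raise ValueError("Ec must be positive")
        vals = [self.eb, self.ed_hom] + ([self.ed_het] if self.ed_het is not None else [])
        if any(v < 0 for v in vals):
            raise ValueError("relative quantities must be non-negative")


@dataclass(frozen=True)
class RepairEstimate:
    """Repair-pathway frequencies (fractions) for one editing condition."""

    label: str
    n: float
    hn: float
    hdr_a: float
    hdr_t: float | None
    pct_hdr_t: float | None
    flags: tuple[str, ...] = field(default_factory=tuple)


def estimate_repair(panel: ProbePanel, strict: bool = False,
                    pct_required: bool = False) -> RepairEstimate:
    """Apply the partition formulas to a probe panel.

    ``strict=True`` computes apparent HDR as HN − N without the second
    division by Ec (numerically identical when Ec = 1).  ``pct_hdr_t`` is
    only defined when a heterologous-probe quantity is present and HN ≠ 0;
    an undefined share is reported as ``None`` with a flag, or raised as
    :class:`UndefinedRatioError` when ``pct_required=True``.
    """
    ec = panel.ec
    n = (ec - panel.eb) / ec
    hn = (ec - panel.ed_hom) / ec
    hdr_a = (hn - n) if strict else (hn - n) / ec
    flags = []
    if n < 0:
        flags.append("negative_nhej")
    if hn < 0:
        flags.append("negative_hn")
    if hn < n:
        flags.append("hn_below_n")
    hdr_t = pct = None
    if panel.ed_het is not None:
        hdr_t = (ec - panel.ed_het) / ec
        if hdr_t < 0:
            flags.append("negative_hdr_t")
        if hn == 0:
            if pct_required:
                raise UndefinedRatioError(
                    f"{panel.label!r}: %HDR_t undefined because HN = 0"
                )
            flags.append("pct_hdr_t_undefined")
        else:
            pct = 100.0 * hdr_t / hn
    return RepairEstimate(panel.label, n, hn, hdr_a, hdr_t, pct, tuple(flags))


@dataclass(frozen=True)
class TotalAccounting:
    """Sum of an HRMA mutant percentage and a TaqMan wild-type percentage."""

    total_percent: float
    exceeds_100: bool

    def __float__(self) -> float:
        return self.total_percent


def account_totals(mutant_pct_hrma: float, wildtype_pct_taqman: float) -> TotalAccounting:
    """Reconcile the two complementary assays for the same sample.

    HRMA measures the mutant fraction, the cut-site TaqMan probe measures the
    remnant wild-type fraction; for a fully accounted population the sum is
    100.  Sums above 100 are possible (both assays carry error) and are
    flagged rather than rejected; negative inputs are a usage error.
    """
    if mutant_pct_hrma < 0 or wildtype_pct_taqman < 0:
        raise ValueError("percentages must be non-negative")
    total = mutant_pct_hrma + wildtype_pct_taqman
    return TotalAccounting(float(total), total > 100.0)


def read_panel_csv(path: str | Path) -> list[ProbePanel]:
    """Panel CSV with columns ``condition, Ec, Eb, Ed_hom[, Ed_het]``.

    An empty/NA ``Ed_het`` cell means the heterologous probe was not run for
    that condition.
    """
    df = pd.read_csv(path, comment="#")
    panels = []
    for _, row in df.iterrows():
        het = row.get("Ed_het")
        het = None if het is None or pd.isna(het) else float(het)
        panels.append(
            ProbePanel(str(row["condition"]), float(row["Ec"]), float(row["Eb"]),
                       float(row["Ed_hom"]), het)
        )
    return panels


def estimates_to_frame(estimates: Sequence[RepairEstimate]) -> pd.DataFrame:
    """Tidy DataFrame of repair estimates (one row per condition)."""
    return pd.DataFrame(
        {
            "condition": [e.label for e in estimates],
            "N": [e.n for e in estimates],
            "HN": [e.hn for e in estimates],
            "HDR_a": [e.hdr_a for e in estimates],
            "HDR_t": [e.hdr_t for e in estimates],
            "pct_HDR_t": [e.pct_hdr_t for e in estimates],
            "flags": [";".join(e.flags) for e in estimates],
        }
    )
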