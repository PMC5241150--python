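"""Synthetic inputs with known ground truth for every stage of the pipeline.

Three generators emulate the raw data the analysis modules consume:

- **Melt curves** — a two-state melting transition modelled as a falling
  logistic, F(T) = f_low + (f_high − f_low) / (1 + exp((T − tm)/width)),
  with optional additive Gaussian noise.  Mixed wild-type/mutant populations
  are pointwise convex combinations of the two pure-species curves
  (heteroduplex melting is deliberately not modelled; see docs/methods.md).
- **Amplicon reads** — reads drawn allele-multinomially from a wild-type
  sequence plus user-specified indel alleles, flanked by the locus primers,
  with uniform substitution-only sequencing error and random strand
  orientation.  Ground-truth per-read labels are returned alongside.
- **Cq tables** — quantification cycles from the exponential-amplification
  law Cq = baseline − log(template) / log(E), plus replicate noise, for
  dilution series and multi-sample panels.

Every generator takes a seed and is reproducible draw-for-draw: one
``numpy.random.Generator`` is created per call and consumed in the documented
order (melt: one noise vector; reads: allele index, then error positions,
then substituted bases, then orientation, per read; Cq: one noise value per
replicate well in sample-then-target-then-replicate order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .melt import MeltCurve
from .ngs import LocusConfig, reverse_complement

__all__ = [
    "MeltModelParams",
    "IndelAllele",
    "ReadSimSpec",
    "CqSimSpec",
    "simulate_melt_curve",
    "simulate_mixture",
    "simulate_reads",
    "simulate_cq",
    "simulate_dilution_series",
    "default_temperature_grid",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_temperature_grid(t_min: float = 70.0, t_max: float = 95.0,
                             step: float = 0.2) -> np.ndarray:
    """The standard melt acquisition grid: 70–95 °C in 0.2 °C increments."""
    n = int(round((t_max - t_min) / step)) + 1
    return t_min + step * np.arange(n)


@dataclass(frozen=True)
class MeltModelParams:
    """Two-state melt model: midpoint ``tm`` (°C), transition ``width`` (°C),
    pre-/post-melt plateaus ``f_high``/``f_low`` (RFU), additive noise SD."""

    tm: float
    width: float = 0.5
    f_high: float = 1000.0
    f_low: float = 50.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")
        if not self.f_high > self.f_low >= 0:
            raise ValueError("need f_high > f_low >= 0")

    def closed_form(self, t: np.ndarray) -> np.ndarray:
        """Noise-free fluorescence at temperatures ``t``."""
        return self.f_low + (self.f_high - self.f_low) / (1.0 + np.exp((t - self.tm) / self.width))


def simulate_melt_curve(
    params: MeltModelParams,
    grid: np.ndarray | None = None,
    seed: int | None = 0,
    label: str | None = None,
) -> MeltCurve:
    """One melt curve from the logistic model; ``noise_sd=0`` is exact."""
    t = default_temperature_grid() if grid is None else np.asarray(grid, dtype=float)
    f = params.closed_form(t)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, params.noise_sd, size=t.shape)
    return MeltCurve(label or f"sim_tm{params.tm:g}", t, f)


def simulate_mixture(
    fraction_mutant: float,
    wt: MeltModelParams,
    mut: MeltModelParams,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    label: str | None = None,
) -> MeltCurve:
    """Melt curve of a wild-type/mutant mix: convex combination plus noise.

    Models PCR products mixed in known proportions, the way dose-response
    standards are made; ``fraction_mutant`` is the mutant share in [0, 1].
    """
    if not 0.0 <= fraction_mutant <= 1.0:
        raise ValueError("fraction_mutant must lie in [0, 1]")
    t = default_temperature_grid() if grid is None else np.asarray(grid, dtype=float)
    f = (1.0 - fraction_mutant) * wt.closed_form(t) + fraction_mutant * mut.closed_form(t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=t.shape)
    return MeltCurve(label or f"mix_{100 * fraction_mutant:g}pct", t, f)


@dataclass(frozen=True)
class IndelAllele:
    """One mutant allele: a deletion of ``size`` bp at ``position`` (0-based,
    within the wild-type segment) or an insertion of ``insert`` before
    ``position``.  ``frequency`` is the allele's share of the population."""

    position: int
    frequency: float
    size: int = 0  # deletion length in bp; 0 for pure insertions
    insert: str = ""  # inserted sequence; empty for pure deletions

    def apply(self, wild_type: str) -> str:
        if self.position < 0 or self.position + self.size > len(wild_type):
            raise ValueError("indel lies outside the wild-type segment")
        return wild_type[: self.position] + self.insert + wild_type[self.position + self.size :]


@dataclass(frozen=True)
class ReadSimSpec:
    """Amplicon read-set specification (see module docstring for draw order)."""

    locus: LocusConfig
    mutant_alleles: tuple[IndelAllele, ...] = ()
    per_base_error: float = 0.006
    n_reads: int = 1000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "mutant_alleles", tuple(self.mutant_alleles))
        total = sum(a.frequency for a in self.mutant_alleles)
        if any(a.frequency < 0 for a in self.mutant_alleles) or total > 1.0 + 1e-9:
            raise ValueError("allele frequencies must be >= 0 and sum to <= 1")
        if not 0.0 <= self.per_base_error <= 0.05:
            raise ValueError("per_base_error must lie in [0, 0.05]")


def _mutate(seq: str, rng: np.random.Generator, p: float) -> str:
    """Uniform substitution errors: each base flips to one of the other three."""
    if p <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < p)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(spec: ReadSimSpec) -> tuple[list[tuple[str, str]], list[str]]:
    """Generate amplicon reads with known truth.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence)`` and ``truth[i]`` is ``"wildtype"`` or the 0-based
    index (as ``"allele_k"``) of the mutant allele read ``i`` was drawn from.
    Each read is sense primer + allele segment + antisense-primer binding
    site, substitution errors applied over the whole read, then presented on
    a random strand.
    """
    rng = np.random.default_rng(spec.seed)
    locus = spec.locus
    alleles = [locus.wild_type] + [a.apply(locus.wild_type) for a in spec.mutant_alleles]
    probs = np.array([1.0 - sum(a.frequency for a in spec.mutant_alleles)]
                     + [a.frequency for a in spec.mutant_alleles])
    anti_site = reverse_complement(locus.antisense_primer)
    reads: list[tuple[str, str]] = []
    truth: list[str] = []
    for i in range(spec.n_reads):
        k = int(rng.choice(len(alleles), p=probs))
        amplicon = locus.sense_primer + alleles[k] + anti_site
        seq = _mutate(amplicon, rng, spec.per_base_error)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append((f"read_{i}", seq))
        truth.append("wildtype" if k == 0 else f"allele_{k - 1}")
    return reads, truth


@dataclass(frozen=True)
class CqSimSpec:
    """Cq panel specification.

    ``true_template_fractions`` maps sample label to its template amount for
    the *target* assay relative to the control (1.0 = unedited); the
    reference assay sees equal template in every sample.  A fraction of 0
    emits no Cq for the target (failed well).
    """

    true_template_fractions: dict = field(default_factory=dict)
    efficiencies: dict = field(default_factory=lambda: {"target": 2.0, "reference": 2.0})
    baseline_cq: float = 24.0
    noise_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        for s, f in self.true_template_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {s!r} outside [0, 1]")
        for t, e in self.efficiencies.items():
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency for {t!r} outside (1, 2]")


def simulate_cq(spec: CqSimSpec) -> pd.DataFrame:
    """Long-format Cq table (sample, target, replicate, cq) from the log law.

    Cq = baseline − log(template) / log(E) + noise.  Halving the template at
    E = 2 raises Cq by exactly one cycle.  Zero-template wells are omitted
    (the instrument reports no Cq).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for sample, frac in spec.true_template_fractions.items():
        for target, eff in spec.efficiencies.items():
            template = frac if target == "target" else 1.0
            if template == 0.0:
                continue
            base = spec.baseline_cq - np.log(template) / np.log(eff)
            for rep in range(1, spec.n_replicates + 1):
                noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                rows.append((sample, target, rep, base + noise))
    return pd.DataFrame(rows, columns=["sample", "target", "replicate", "cq"])


def simulate_dilution_series(
    efficiency: float = 2.0,
    levels: Sequence[float] = (0.0, -1.0, -2.0, -3.0),
    baseline_cq: float = 20.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[tuple[float, list[float]]]:
    """(log10 input, Cq replicates) pairs from the same amplification law.

    At E = 2 a ten-fold dilution series has slope −3.3219 cycles/decade.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must lie in (1, 2]")
    rng = np.random.default_rng(seed)
    out = []
    for lvl in levels:
        base = baseline_cq - lvl * np.log(10.0) / np.log(efficiency)
        reps = [float(base + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
                for _ in range(n_replicates)]
        out.append((float(lvl), reps))
    return out
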