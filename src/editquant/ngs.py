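"""Amplicon deep-sequencing indel analysis by primer anchoring and edit distance.

Each read is searched (on both strands) for an exact match of the sense
primer followed by the antisense-primer binding site; the intervening segment
is the amplified target.  That segment is scored against the wild-type target
by Levenshtein edit distance — the minimum number of single-base
substitutions, insertions and deletions converting one string into the other,
computed by dynamic programming — and classified with two quantities:

- ``size_delta`` = len(extracted) − len(wild type), the net indel size;
- ``edit_distance`` against a *stringency factor*: reads closer than the
  stringency to wild type are called wild type, absorbing background
  substitutions from sequencing error.

Calls: ``deletion`` (size_delta < 0), ``insertion`` (size_delta > 0) or
``complex`` (distance ≥ stringency but no net length change; counted among
mutations but excluded from both indel size spectra).  ``summarize_mutations``
aggregates calls into per-locus mutation percentages, deduplicated indel
sequence sets and 1-bp size histograms.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import yaml

from .errors import EditQuantError

__all__ = [
    "LocusConfig",
    "ReadClassification",
    "MutationSummary",
    "edit_distance",
    "reverse_complement",
    "extract_target",
    "classify_read",
    "summarize_mutations",
    "background_subtract",
    "BackgroundCorrected",
    "read_sequences",
    "write_summary",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

Status = Literal["no_target", "wildtype", "deletion", "insertion", "complex"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocusConfig:
    """Target locus description for amplicon classification.

    ``wild_type`` is the reference segment *between* the primers (uppercase
    ACGT).  Both primers are given as their own 5'→3' sequences, as they
    would appear in an oligo order sheet; the antisense primer's reverse
    complement is what is located on the sense strand.  ``stringency`` is
    the minimum edit distance for a mutant call (default 3: up to two
    changes are tolerated as sequencing background).
    """

    name: str
    wild_type: str
    sense_primer: str
    antisense_primer: str
    stringency: int = 3

    def __post_init__(self):
        for label, seq in (("wild_type", self.wild_type),
                           ("sense_primer", self.sense_primer),
                           ("antisense_primer", self.antisense_primer)):
            s = seq.upper()
            if not s or set(s) - set("ACGTN"):
                raise ValueError(f"{label} must be a non-empty ACGT(N) string")
            object.__setattr__(self, label, s)
        if len(self.sense_primer) < 15 or len(self.antisense_primer) < 15:
            raise ValueError("primers must be at least 15 nt")
        if self.stringency < 0:
            raise ValueError("stringency must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "LocusConfig":
        """Load from a YAML (or JSON — valid YAML) mapping with LocusConfig fields."""
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            name=data["name"],
            wild_type=data["wild_type"],
            sense_primer=data["sense_primer"],
            antisense_primer=data["antisense_primer"],
            stringency=int(data.get("stringency", 3)),
        )


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    status: Status
    edit_distance: int | None
    size_delta: int | None
    extracted: str


@dataclass(frozen=True)
class MutationSummary:
    """Per-locus aggregate of read classifications."""

    locus: str
    counts: dict
    with_target: int
    percent_mutant: float
    unique_deletions: dict = field(default_factory=dict)  # sequence -> deletion size (bp)
    unique_insertions: dict = field(default_factory=dict)  # sequence -> insertion size (bp)
    deletion_size_hist: Counter = field(default_factory=Counter)
    insertion_size_hist: Counter = field(default_factory=Counter)


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance between two DNA strings.

    Unit-cost substitutions, insertions and deletions; ``N`` matches only
    ``N``.  Classic dynamic program, iterated over the shorter string's rows
    with the inner recurrence vectorized.  Empty strings are allowed:
    d(s, "") = len(s).
    """
    a, b = a.upper(), b.upper()
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    idx = np.arange(len(b) + 1, dtype=np.int64)
    prev = idx.copy()
    curr = np.empty_like(prev)
    for i, ca in enumerate(arr_a, start=1):
        curr[0] = i
        np.minimum(prev[:-1] + (arr_b != ca), prev[1:] + 1, out=curr[1:])
        # unit-cost insertions propagate left-to-right:
        # curr[j] = min_{k<=j} curr[k] + (j-k), a prefix-min in (curr - j) space
        curr = np.minimum.accumulate(curr - idx) + idx
        prev, curr = curr, prev
    return int(prev[-1])


def _find_exact(hay: str, needle: str, start: int = 0) -> int:
    return hay.find(needle, start)


def _find_fuzzy(hay: str, needle: str, max_mismatch: int, start: int = 0) -> int:
    """First position >= start where ``needle`` matches with <= max_mismatch substitutions."""
    n, m = len(hay), len(needle)
    nd = np.frombuffer(needle.encode(), dtype=np.uint8)
    for i in range(start, n - m + 1):
        window = np.frombuffer(hay[i : i + m].encode(), dtype=np.uint8)
        if int((window != nd).sum()) <= max_mismatch:
            return i
    return -1


def _anchor(read: str, sense: str, anti_site: str, max_mismatch: int) -> str | None:
    find = _find_exact if max_mismatch == 0 else (
        lambda h, p, s=0: _find_fuzzy(h, p, max_mismatch, s)
    )
    i = find(read, sense)
    if i < 0:
        return None
    j = find(read, anti_site, i + len(sense))
    if j < 0:
        return None
    if find(read, sense, i + 1) >= 0 or find(read, anti_site, j + 1) >= 0:
        logger.warning("multiple primer anchors in read; using first sense/antisense pair")
    return read[i + len(sense) : j]


def extract_target(read: str, locus: LocusConfig, max_mismatch: int = 0) -> str | None:
    """Extract the inter-primer segment from a read, or ``None``.

    The read and its reverse complement are both searched; the first
    orientation yielding a sense anchor followed downstream by the
    antisense-primer binding site wins.  Primers are excluded from the
    returned segment.  ``max_mismatch`` optionally allows that many
    substitutions inside each primer (default: exact matching).
    """
    read = read.upper()
    anti_site = reverse_complement(locus.antisense_primer)
    for oriented in (read, reverse_complement(read)):
        seg = _anchor(oriented, locus.sense_primer, anti_site, max_mismatch)
        if seg is not None:
            return seg
    return None


def classify_read(
    read: str, locus: LocusConfig, read_id: str = "", max_mismatch: int = 0
) -> ReadClassification:
    """Classify one read against the locus (see module docstring for the rules)."""
    seg = extract_target(read, locus, max_mismatch)
    if seg is None:
        return ReadClassification(read_id, "no_target", None, None, "")
    dist = edit_distance(seg, locus.wild_type)
    delta = len(seg) - len(locus.wild_type)
    if dist < locus.stringency:
        status: Status = "wildtype"
    elif delta < 0:
        status = "deletion"
    elif delta > 0:
        status = "insertion"
    else:
        status = "complex"
    return ReadClassification(read_id, status, dist, delta, seg)


def summarize_mutations(
    reads: Iterable[str | tuple[str, str]],
    locus: LocusConfig,
    max_mismatch: int = 0,
) -> MutationSummary:
    """Classify a read set and aggregate mutation statistics.

    ``reads`` may be plain sequences or ``(read_id, sequence)`` pairs.
    ``percent_mutant`` is 100·(deletions + insertions + complex) over reads
    with a recovered target.  The unique indel sets deduplicate on the
    extracted sequence (multiple reads carrying the same mutation count
    once); the size histograms use 1-bp bins of |size_delta|.
    """
    counts: Counter = Counter()
    uniq_del: dict[str, int] = {}
    uniq_ins: dict[str, int] = {}
    n_total = 0
    for item in reads:
        rid, seq = item if isinstance(item, tuple) else ("", item)
        n_total += 1
        rc = classify_read(seq, locus, rid, max_mismatch)
        counts[rc.status] += 1
        if rc.status == "deletion":
            uniq_del.setdefault(rc.extracted, -rc.size_delta)
        elif rc.status == "insertion":
            uniq_ins.setdefault(rc.extracted, rc.size_delta)
    with_target = n_total - counts["no_target"]
    if with_target == 0:
        raise EditQuantError(f"no reads with a recoverable {locus.name} target")
    mutant = counts["deletion"] + counts["insertion"] + counts["complex"]
    return MutationSummary(
        locus=locus.name,
        counts=dict(counts),
        with_target=with_target,
        percent_mutant=100.0 * mutant / with_target,
        unique_deletions=uniq_del,
        unique_insertions=uniq_ins,
        deletion_size_hist=Counter(uniq_del.values()),
        insertion_size_hist=Counter(uniq_ins.values()),
    )


@dataclass(frozen=True)
class BackgroundCorrected:
    """Mutation percentage after subtracting the background rate."""

    percent: float
    negative: bool

    def __float__(self) -> float:
        return self.percent


def background_subtract(test_pct: float, background_pct: float) -> BackgroundCorrected:
    """Subtract the locus background mutation percentage from a test percentage.

    A plain difference: control samples at the same locus define the
    background called at the chosen stringency.  Results below zero are
    flagged, not floored.
    """
    for v in (test_pct, background_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError("percentages must lie in [0, 100]")
    diff = test_pct - background_pct
    return BackgroundCorrected(float(diff), diff < 0)


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTA or FASTQ, plain or gzip-compressed."""
    from Bio import SeqIO

    path = Path(path)
    name = path.name.lower()
    stem = name[:-3] if name.endswith(".gz") else name
    if stem.endswith((".fq", ".fastq")):
        fmt = "fastq"
    elif stem.endswith((".fa", ".fasta", ".fna")):
        fmt = "fasta"
    else:
        raise ValueError(f"cannot infer sequence format from {path.name!r}")
    opener = gzip.open if name.endswith(".gz") else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield rec.id, str(rec.seq)


def write_summary(summary: MutationSummary, out_dir: str | Path) -> dict[str, Path]:
    """Write a summary CSV, unique-indel FASTAs and size-histogram CSVs.

    Returns a mapping of artifact name to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary_path = out / f"{summary.locus}_summary.csv"
    with summary_path.open("w") as fh:
        fh.write("metric,value\n")
        for status in ("no_target", "wildtype", "deletion", "insertion", "complex"):
            fh.write(f"count_{status},{summary.counts.get(status, 0)}\n")
        fh.write(f"reads_with_target,{summary.with_target}\n")
        fh.write(f"percent_mutant,{summary.percent_mutant:.4f}\n")
    paths["summary"] = summary_path

    for kind, uniq in (("deletions", summary.unique_deletions),
                       ("insertions", summary.unique_insertions)):
        fasta = out / f"{summary.locus}_unique_{kind}.fasta"
        with fasta.open("w") as fh:
            for i, (seq, size) in enumerate(sorted(uniq.items()), start=1):
                fh.write(f">{summary.locus}_{kind[:-1]}_{i} size={size}\n{seq}\n")
        paths[f"unique_{kind}"] = fasta

    for kind, hist in (("deletion", summary.deletion_size_hist),
                       ("insertion", summary.insertion_size_hist)):
        hist_path = out / f"{summary.locus}_{kind}_sizes.csv"
        with hist_path.open("w") as fh:
            fh.write("size_bp,count\n")
            for size in sorted(hist):
                fh.write(f"{size},{hist[size]}\n")
        paths[f"{kind}_sizes"] = hist_path
    return paths
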