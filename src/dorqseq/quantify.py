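"""Read-to-probe quantification: trim, assign, count.

The reference set is a handful of 40-nt recognition sequences at mutual
Levenshtein distance >= 6, so full k-mer/EM quantification machinery is
unnecessary: a read trimmed to its first 40 nt either equals a recognition
(hash lookup) or sits within a small edit radius of exactly one. With the
default radius ``max_dist = 2 = floor((6-1)/2)``, the triangle inequality
guarantees the nearest probe is unique — a read within 2 of probe f is at
distance >= 6 - 2 = 4 > 2 from every other probe.

Fractions are computed over mapped reads (mapping rates are typically >98%,
so the distinction from total reads is sub-percent); RPM uses total reads.
Both are reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import edlib
import pandas as pd

from .probe_design import ProbeSet
from .sequence_core import Read, open_text, read_fastq

__all__ = [
    "EmptyInputError",
    "RadiusError",
    "TooShort",
    "Unassigned",
    "TRIM_LENGTH",
    "MAX_DIST_DEFAULT",
    "AbundanceTable",
    "trim_read",
    "assign_read",
    "quantify_sample",
    "write_abundance_csv",
    "read_abundance_csv",
]

TRIM_LENGTH = 40
MAX_DIST_DEFAULT = 2  # floor((6 - 1) / 2): unique-assignment radius at floor 6


class EmptyInputError(ValueError):
    """Zero reads in the input."""


class RadiusError(ValueError):
    """Strict mode: max_dist exceeds the uniqueness bound for this probe set."""


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name


TooShort = _Sentinel("TooShort")
Unassigned = _Sentinel("Unassigned")


@dataclass
class AbundanceTable:
    """Per-probe counts with fractions and RPM, plus mapping statistics."""

    counts: dict[str, int]
    total_reads: int
    too_short: int
    unassigned: int

    def __post_init__(self) -> None:
        if self.total_reads != self.mapped_reads + self.too_short + self.unassigned:
            raise ValueError("read accounting does not balance")

    @property
    def mapped_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def mapping_rate(self) -> float:
        return self.mapped_reads / self.total_reads if self.total_reads else 0.0

    @property
    def fractions(self) -> dict[str, float]:
        """Share of mapped reads per probe (sums to 1 when any read mapped)."""
        mapped = self.mapped_reads
        if mapped == 0:
            return {name: 0.0 for name in self.counts}
        return {name: c / mapped for name, c in self.counts.items()}

    @property
    def rpm(self) -> dict[str, float]:
        """Reads per million, on the total-read denominator."""
        if self.total_reads == 0:
            return {name: 0.0 for name in self.counts}
        return {
            name: 1e6 * c / self.total_reads for name, c in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        fractions = self.fractions
        rpm = self.rpm
        return pd.DataFrame(
            {
                "name": list(self.counts),
                "count": list(self.counts.values()),
                "fraction": [fractions[n] for n in self.counts],
                "rpm": [rpm[n] for n in self.counts],
            }
        )

    def stats(self) -> dict[str, float | int]:
        return {
            "total_reads": self.total_reads,
            "mapped_reads": self.mapped_reads,
            "too_short": self.too_short,
            "unassigned": self.unassigned,
            "mapping_rate": self.mapping_rate,
        }


# ---------------------------------------------------------------------------
# Per-read operations
# ---------------------------------------------------------------------------

def trim_read(read: Read, length: int = TRIM_LENGTH):
    """First ``length`` bases of the read, or ``TooShort``.

    Trimming to the recognition region discards the adapter tail; ``TooShort``
    is a counted outcome, not an error.
    """
    if len(read.sequence) < length:
        return TooShort
    return read.sequence[:length]


def uniqueness_radius(probe_set: ProbeSet) -> int:
    """Largest radius guaranteeing a unique nearest probe: floor((d_min-1)/2)."""
    d = probe_set.min_pairwise_distance
    if d is None:
        return MAX_DIST_DEFAULT
    return (d - 1) // 2


def assign_read(
    trimmed: str,
    probe_set: ProbeSet,
    max_dist: int = MAX_DIST_DEFAULT,
    *,
    strict: bool = False,
    _exact: dict[str, str] | None = None,
):
    """Assign a trimmed read to a probe name, or ``Unassigned``.

    Exact hash lookup first; otherwise the unique probe within Levenshtein
    ``max_dist``. Ties at the minimum distance are ``Unassigned`` — with a
    validated probe set and ``max_dist`` within the uniqueness radius they
    cannot occur. Strict mode raises :class:`RadiusError` when ``max_dist``
    exceeds that radius.
    """
    if strict and max_dist > uniqueness_radius(probe_set):
        raise RadiusError(
            f"max_dist={max_dist} exceeds uniqueness radius "
            f"{uniqueness_radius(probe_set)} for this probe set"
        )
    exact = _exact if _exact is not None else {
        p.recognition: p.name for p in probe_set
    }
    hit = exact.get(trimmed)
    if hit is not None:
        return hit
    best_name = None
    best_dist = max_dist + 1
    tie = False
    for probe in probe_set:
        d = edlib.align(
            trimmed, probe.recognition, mode="NW", task="distance", k=max_dist
        )["editDistance"]
        if d < 0:  # edlib reports -1 beyond k
            continue
        if d < best_dist:
            best_name, best_dist, tie = probe.name, d, False
        elif d == best_dist:
            tie = True
    if best_name is None or tie:
        return Unassigned
    return best_name


# ---------------------------------------------------------------------------
# Sample-level quantification
# ---------------------------------------------------------------------------

def quantify_sample(
    reads: Iterable[Read] | str | Path,
    probe_set: ProbeSet,
    max_dist: int = MAX_DIST_DEFAULT,
    *,
    strict: bool = False,
) -> AbundanceTable:
    """Trim and assign every read; return the abundance table.

    ``reads`` may be an iterable of :class:`Read` or a FASTQ path (gz ok).
    Every probe appears in the table, at count 0 if unseen. Deterministic and
    invariant to read order.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    if strict and max_dist > uniqueness_radius(probe_set):
        raise RadiusError(
            f"max_dist={max_dist} exceeds uniqueness radius "
            f"{uniqueness_radius(probe_set)}"
        )
    exact = {p.recognition: p.name for p in probe_set}
    counts = {p.name: 0 for p in probe_set}
    total = too_short = unassigned = 0
    for read in reads:
        total += 1
        trimmed = trim_read(read)
        if trimmed is TooShort:
            too_short += 1
            continue
        result = assign_read(trimmed, probe_set, max_dist, _exact=exact)
        if result is Unassigned:
            unassigned += 1
        else:
            counts[result] += 1
    if total == 0:
        raise EmptyInputError("no reads in input")
    return AbundanceTable(
        counts=counts, total_reads=total, too_short=too_short,
        unassigned=unassigned,
    )


# ---------------------------------------------------------------------------
# Interchange
# ---------------------------------------------------------------------------

def write_abundance_csv(
    table: AbundanceTable, path: str | Path, stats_path: str | Path | None = None
) -> None:
    table.to_frame().to_csv(path, index=False, float_format="%.10g")
    if stats_path is not None:
        with open_text(stats_path, "wt") as fh:
            json.dump(table.stats(), fh, indent=2)
            fh.write("\n")


def read_abundance_csv(path: str | Path, stats_path: str | Path | None = None) -> AbundanceTable:
    """Rebuild a table from CSV; totals come from the stats JSON when given,
    otherwise unmapped categories are assumed empty."""
    frame = pd.read_csv(path)
    counts = dict(zip(frame["name"], (int(c) for c in frame["count"])))
    if stats_path is not None:
        with open_text(stats_path) as fh:
            stats = json.load(fh)
        return AbundanceTable(
            counts=counts,
            total_reads=int(stats["total_reads"]),
            too_short=int(stats["too_short"]),
            unassigned=int(stats["unassigned"]),
        )
    total = sum(counts.values())
    return AbundanceTable(
        counts=counts, total_reads=total, too_short=0, unassigned=0
    )
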