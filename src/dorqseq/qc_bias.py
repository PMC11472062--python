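"""Quality summaries, PCR-cycle bias profiling, and pool comparisons.

Low-cycle index PCR can amplify probe constructs unevenly despite identical
primer binding sites; profiling abundance tables across a cycle series
quantifies that bias as per-family fold changes against the lowest cycle.
The GC correlation asks whether those fold changes track recognition GC
content (for real libraries they do only weakly), and pool-vs-pool R²
measures concordance between two samples' composition estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .probe_design import ProbeSet
from .quantify import AbundanceTable
from .sequence_core import Read, read_fastq

__all__ = [
    "EmptyInputError",
    "BaselineMissingError",
    "InsufficientOverlapError",
    "DegenerateError",
    "BiasProfile",
    "qscore_summary",
    "pcr_bias_profile",
    "gc_bias_correlation",
    "compare_pools",
]

LOG2_FC_FLAG_DEFAULT = 0.5


class EmptyInputError(ValueError):
    """No reads in the FASTQ."""


class BaselineMissingError(KeyError):
    """Requested baseline cycle not among the supplied tables."""


class InsufficientOverlapError(ValueError):
    """Fewer than 3 families shared between two tables."""


class DegenerateError(ValueError):
    """No variance in one of the correlated variables."""


@dataclass
class BiasProfile:
    """Per-family amplification bias of one cycle relative to a baseline."""

    baseline_cycle: int
    cycle: int
    fold_change: dict[str, float]
    log2_fc: dict[str, float]
    absent_at_baseline: tuple[str, ...]

    @property
    def max_enrichment(self) -> float:
        return max(self.fold_change.values())

    @property
    def max_depletion(self) -> float:
        return min(self.fold_change.values())

    def flagged(self, threshold: float = LOG2_FC_FLAG_DEFAULT) -> dict[str, float]:
        """Families whose |log2 fold change| exceeds ``threshold``."""
        return {
            name: fc
            for name, fc in self.log2_fc.items()
            if abs(fc) > threshold
        }


def qscore_summary(reads: Iterable[Read] | str | Path) -> dict:
    """Mean Phred score over all bases, per-position means, and sub-Q30 share."""
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    total = 0
    n_bases = 0
    below_q30 = 0
    position_sums: list[int] = []
    position_counts: list[int] = []
    for read in reads:
        for i, q in enumerate(read.qualities):
            if i >= len(position_sums):
                position_sums.append(0)
                position_counts.append(0)
            position_sums[i] += q
            position_counts[i] += 1
            total += q
            n_bases += 1
            if q < 30:
                below_q30 += 1
    if n_bases == 0:
        raise EmptyInputError("no reads")
    return {
        "mean_q": total / n_bases,
        "per_position_mean": [
            s / c for s, c in zip(position_sums, position_counts)
        ],
        "fraction_bases_below_q30": below_q30 / n_bases,
        "n_bases": n_bases,
    }


def pcr_bias_profile(
    tables: Mapping[int, AbundanceTable], baseline: int | None = None
) -> dict[int, BiasProfile]:
    """Fold change of every family's fraction at each cycle vs the baseline.

    ``baseline`` defaults to the smallest cycle present. Families with zero
    fraction at baseline are flagged (``absent_at_baseline``), not divided.
    Returns one profile per non-baseline cycle.
    """
    if len(tables) < 2:
        raise ValueError("need tables for >= 2 cycles")
    if baseline is None:
        baseline = min(tables)
    if baseline not in tables:
        raise BaselineMissingError(f"baseline cycle {baseline} not supplied")
    base_fracs = tables[baseline].fractions
    profiles: dict[int, BiasProfile] = {}
    for cycle, table in tables.items():
        if cycle == baseline:
            continue
        fracs = table.fractions
        shared = set(base_fracs) & set(fracs)
        absent = tuple(sorted(n for n in shared if base_fracs[n] == 0))
        fc = {
            n: fracs[n] / base_fracs[n]
            for n in sorted(shared)
            if base_fracs[n] > 0
        }
        profiles[cycle] = BiasProfile(
            baseline_cycle=baseline,
            cycle=cycle,
            fold_change=fc,
            log2_fc={
                n: math.log2(v) if v > 0 else float("-inf")
                for n, v in fc.items()
            },
            absent_at_baseline=absent,
        )
    return profiles


def gc_bias_correlation(
    profile: BiasProfile, probe_set: ProbeSet
) -> dict[str, float]:
    """Pearson correlation of log2 fold change against recognition GC fraction.

    Returns r and r²; a constant fold-change (or constant GC) vector has no
    defined correlation and is reported as r = 0 with ``degenerate`` set.
    Raises :class:`DegenerateError` when GC variance is zero.
    """
    gc = {p.name: p.gc_fraction for p in probe_set}
    names = sorted(set(profile.log2_fc) & set(gc))
    if len(names) < 3:
        raise ValueError("need >= 3 families for a correlation")
    x = np.array([gc[n] for n in names])
    y = np.array([profile.log2_fc[n] for n in names])
    if np.ptp(x) == 0:
        raise DegenerateError("GC content has zero variance")
    if np.ptp(y) == 0:
        return {"pearson_r": 0.0, "r_squared": 0.0, "n": len(names),
                "degenerate": True}
    r, _ = stats.pearsonr(x, y)
    return {
        "pearson_r": float(r),
        "r_squared": float(r**2),
        "n": len(names),
        "degenerate": False,
    }


def compare_pools(a: AbundanceTable, b: AbundanceTable) -> dict[str, float]:
    """Concordance of two composition estimates over their shared families.

    Simple linear regression of b's fractions on a's; adjusted R² uses one
    predictor: ``1 - (1 - R²)(n - 1)/(n - 2)``. R² is the squared Pearson
    correlation, hence symmetric in the two tables.
    """
    shared = sorted(set(a.fractions) & set(b.fractions))
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared families; need >= 3"
        )
    fa = a.fractions
    fb = b.fractions
    x = np.array([fa[n] for n in shared])
    y = np.array([fb[n] for n in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateError("fractions have zero variance")
    r, _ = stats.pearsonr(x, y)
    n = len(shared)
    r2 = float(r**2)
    return {
        "r_squared": r2,
        "adjusted_r_squared": 1.0 - (1.0 - r2) * (n - 1) / (n - 2),
        "n": n,
    }
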