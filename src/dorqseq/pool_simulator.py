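"""Forward model of the DORQ-seq workflow on synthetic pools.

Generates synthetic tRNA references, applies a deterministic per-family PCR
amplification bias, and emits FASTQ reads with a constant-rate substitution
error model, so the quantification and calibration machinery is testable
without any sequencing data.

Model summary
-------------
* **Capture** is quantitative (efficiency 1) by default: a family's chance of
  yielding a read equals its pool fraction, optionally reweighted by PCR bias.
* **PCR bias** is deterministic exponential amplification: after ``c`` cycles
  a family with per-cycle efficiency ``e`` carries weight
  ``fraction * (1 + e)**c``, renormalized. This reproduces reproducible,
  sequence-specific enrichment/depletion without a stochastic duplication
  tree.
* **Base errors** are independent substitutions to a uniformly random
  different base at rate ``p = 10**(-q/10)`` per base; indels are negligible
  for short Illumina reads at this scale. Reported qualities equal the
  configured q.
* Reads are drawn as one multinomial over families per simulation and emitted
  grouped by family; read order carries no information downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .probe_design import P3_DEFAULT, ProbeSet
from .sequence_core import Read, TRNAReference, levenshtein, write_fastq

__all__ = [
    "GenerationError",
    "PoolComposition",
    "SimConfig",
    "generate_reference_set",
    "pcr_weights",
    "spiked_composition",
    "simulate_reads",
    "simulate_fastq",
    "sample_family_counts",
    "expected_error_stats",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(RuntimeError):
    """Rejection sampling of well-separated references exceeded its budget."""


@dataclass(frozen=True)
class PoolComposition:
    """Relative abundances of probe families in an input pool (sum to 1)."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        values = np.array(list(self.fractions.values()), dtype=float)
        if (values < 0).any():
            raise ValueError("fractions must be non-negative")
        total = values.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"fractions must sum to 1, got {total}")

    @classmethod
    def from_weights(cls, weights: Mapping[str, float]) -> "PoolComposition":
        """Normalize arbitrary non-negative weights into a composition."""
        total = sum(weights.values())
        if total <= 0:
            raise ValueError("weights must have a positive sum")
        return cls({k: v / total for k, v in weights.items()})

    def __getitem__(self, name: str) -> float:
        return self.fractions[name]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of one simulated sequencing run.

    ``q_score`` sets both the per-base substitution rate ``10**(-q/10)`` and
    the reported quality of every base. ``read_length`` defaults to 66 =
    40-nt recognition + 26-nt P3 adapter, the full informative template.
    """

    n_reads: int
    q_score: float = 33.6
    pcr_cycles: int = 0
    efficiencies: dict[str, float] = field(default_factory=dict)
    read_length: int = 66
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.read_length < 40:
            raise ValueError("read_length must be >= 40")
        p = self.per_base_error
        if not 0.0 < p < 1.0:
            raise ValueError(f"per-base error rate {p} outside (0, 1)")
        for name, e in self.efficiencies.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"efficiency for {name!r} outside [0, 1]")

    @property
    def per_base_error(self) -> float:
        return 10.0 ** (-self.q_score / 10.0)


# ---------------------------------------------------------------------------
# Synthetic reference generation
# ---------------------------------------------------------------------------

def generate_reference_set(
    n_families: int,
    seed: int,
    tail_length: int = 40,
    total_length: int = 76,
    min_distance: int = 6,
    max_attempts_per_family: int = 1000,
) -> list[TRNAReference]:
    """Draw synthetic 76-nt mature tRNA references ending in CCA.

    The 3' ``tail_length``-mers are rejection-sampled until mutually at
    Levenshtein distance >= ``min_distance``, so a probe set designed from
    them validates cleanly. Compartments alternate cytosolic/mitochondrial
    round-robin; amino acids cycle the standard alphabet and anticodons are
    random, purely as plausible annotation.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    aa_cycle = "ARNDCQEGHILKMFPSTWYV"

    tails: list[str] = []
    attempts = 0
    budget = max_attempts_per_family * n_families
    while len(tails) < n_families:
        attempts += 1
        if attempts > budget:
            raise GenerationError(
                f"could not place {n_families} tails at distance >= "
                f"{min_distance} within {budget} attempts"
            )
        candidate = "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=tail_length - 3)
        ) + "CCA"
        if all(levenshtein(candidate, t) >= min_distance for t in tails):
            tails.append(candidate)

    refs = []
    head_length = total_length - tail_length
    for i, tail in enumerate(tails):
        head = "".join("ACGT"[j] for j in rng.integers(0, 4, size=head_length))
        anticodon = "".join("ACGT"[j] for j in rng.integers(0, 4, size=3))
        refs.append(
            TRNAReference(
                id=f"synth-tRNA-{i:03d}",
                organism="synthetic",
                compartment="cytosolic" if i % 2 == 0 else "mitochondrial",
                amino_acid=aa_cycle[i % len(aa_cycle)],
                anticodon=anticodon,
                sequence=head + tail,
            )
        )
    return refs


# ---------------------------------------------------------------------------
# PCR bias and pool arithmetic
# ---------------------------------------------------------------------------

def pcr_weights(
    composition: PoolComposition,
    efficiencies: Mapping[str, float],
    cycles: int,
) -> PoolComposition:
    """Pool composition after ``cycles`` rounds of biased amplification.

    Each family's weight scales by ``(1 + e_f)**cycles``; weights are then
    renormalized. Equal efficiencies (or zero cycles) leave the composition
    unchanged, and applying c1 then c2 cycles equals c1 + c2 at once.
    """
    missing = set(composition.fractions) - set(efficiencies)
    if missing:
        raise ValueError(f"efficiencies missing for families: {sorted(missing)}")
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    weights = {
        name: frac * (1.0 + efficiencies[name]) ** cycles
        for name, frac in composition.fractions.items()
    }
    return PoolComposition.from_weights(weights)


def spiked_composition(
    composition: PoolComposition,
    anchor: str,
    spike_ng: float,
    total_ng: float,
) -> PoolComposition:
    """Composition after adding ``spike_ng`` of the anchor family's analyte.

    Standard-addition premise: the spiked in vitro transcript hybridizes to
    the same probe as the native family, so its mass simply adds to the
    anchor's share of the (now larger) pool.
    """
    if anchor not in composition.fractions:
        raise KeyError(f"anchor family {anchor!r} not in composition")
    if spike_ng < 0 or total_ng <= 0:
        raise ValueError("spike_ng must be >= 0 and total_ng > 0")
    masses = {f: frac * total_ng for f, frac in composition.fractions.items()}
    masses[anchor] += spike_ng
    return PoolComposition.from_weights(masses)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def sample_family_counts(
    composition: PoolComposition, n_reads: int, rng: np.random.Generator
) -> dict[str, int]:
    """One multinomial draw of read counts per family (names in sorted order)."""
    names = sorted(composition.fractions)
    probs = np.array([composition.fractions[n] for n in names], dtype=float)
    counts = rng.multinomial(n_reads, probs / probs.sum())
    return dict(zip(names, (int(c) for c in counts)))


def _template(recognition: str, p3: str, read_length: int) -> str:
    tpl = recognition + p3
    if len(tpl) >= read_length:
        return tpl[:read_length]
    return tpl + "A" * (read_length - len(tpl))  # pad past the adapter


def _mutate(seqs: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Apply iid substitutions at rate p; each error picks a different base."""
    if p <= 0:
        return seqs
    hit = rng.random(seqs.shape) < p
    if not hit.any():
        return seqs
    # offset 1..3 from the current base index, uniform over the 3 alternatives
    idx = np.searchsorted(_BASES, seqs[hit])
    offsets = rng.integers(1, 4, size=idx.shape)
    seqs[hit] = _BASES[(idx + offsets) % 4]
    return seqs


def simulate_reads(
    probes: ProbeSet,
    composition: PoolComposition,
    config: SimConfig,
) -> Iterator[Read]:
    """Yield simulated reads for a pool (deterministic given ``config.seed``).

    Per read: family drawn from ``pcr_weights(composition, efficiencies,
    pcr_cycles)``; sequence = the probe's recognition followed by P3 adapter
    bases up to ``read_length``; substitutions at rate ``10**(-q/10)``;
    qualities all equal to the configured q (rounded to integer Phred).
    """
    unknown = set(composition.fractions) - set(probes.names)
    if unknown:
        raise ValueError(f"composition names not in probe set: {sorted(unknown)}")
    if config.efficiencies:
        composition = pcr_weights(
            composition, config.efficiencies, config.pcr_cycles
        )
    rng = np.random.default_rng(config.seed)
    counts = sample_family_counts(composition, config.n_reads, rng)
    recognitions = {p.name: p.recognition for p in probes}
    q = int(round(config.q_score))
    qualities = tuple([q] * config.read_length)
    p = config.per_base_error

    read_index = 0
    for name in sorted(counts):
        count = counts[name]
        if count == 0:
            continue
        template = _template(recognitions[name], probes.p3, config.read_length)
        block = np.tile(
            np.frombuffer(template.encode(), dtype=np.uint8), (count, 1)
        ).copy()
        block = _mutate(block, p, rng)
        for row in block:
            yield Read(
                id=f"sim-{read_index:08d}:{name}",
                sequence=row.tobytes().decode(),
                qualities=qualities,
            )
            read_index += 1


def simulate_fastq(
    probes: ProbeSet,
    composition: PoolComposition,
    config: SimConfig,
    path: str | Path,
) -> None:
    """Simulate and write straight to FASTQ (gzip-transparent)."""
    write_fastq(simulate_reads(probes, composition, config), path)


# ---------------------------------------------------------------------------
# Closed-form error statistics
# ---------------------------------------------------------------------------

def expected_error_stats(q_score: float, read_length: int) -> dict[str, float]:
    """Analytic Phred arithmetic for a run at mean quality ``q_score``.

    Returns per-base error probability ``10**(-q/10)``, its reciprocal (base
    calls per error), and the chance a ``read_length``-nt read carries at
    least one error, ``1 - (1-p)**L``.
    """
    if q_score <= 0:
        raise ValueError("q_score must be positive")
    p = 10.0 ** (-q_score / 10.0)
    return {
        "per_base_error": p,
        "base_calls_per_error": 1.0 / p,
        "frac_reads_with_error": 1.0 - (1.0 - p) ** read_length,
    }
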