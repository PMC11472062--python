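"""Spike-in standard-addition calibration and absolute quantification.

Standard addition: known masses of an in vitro transcript targeting one probe
("anchor" family) are added to aliquots of the sample; the anchor's signal
(RPM by default) is regressed on the spiked mass. The y-intercept is the
zero-spike signal of the native analyte, which converts to nanograms through
the total input mass:

    ng = (rpm / 1e6) * total_input_ng

e.g. 37,000 RPM in a 25 ng pool is 0.925 ng. Once one family's absolute mass
is known, every other family's mass follows from relative abundance.

The classical standard-addition estimate (the magnitude of the x-intercept,
``intercept/slope``) is also computed; the y-intercept conversion is the
default because RPM has a known absolute scale here (reads are proportional
to mass across the whole pool), which the classical formulation does not
assume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .quantify import AbundanceTable

__all__ = [
    "DegenerateSeriesError",
    "AnchorMissingError",
    "CalibrationSeries",
    "CalibrationFit",
    "fit_standard_addition",
    "rpm_to_ng",
    "absolute_pool",
]


class DegenerateSeriesError(ValueError):
    """All spike levels identical — no regression possible."""


class AnchorMissingError(KeyError):
    """Anchor family absent from the abundance table (or has zero counts)."""


@dataclass(frozen=True)
class CalibrationSeries:
    """A standard-addition series for one anchor family.

    ``points`` are (spike_ng, signal) pairs; ``signal`` is the anchor's RPM
    (default) or raw count. ``total_input_ng`` is the unspiked pool mass used
    for the RPM-to-mass conversion.
    """

    points: tuple[tuple[float, float], ...]
    total_input_ng: float
    anchor_family: str = ""
    signal_is_rpm: bool = True

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("need >= 2 calibration points")
        if self.total_input_ng <= 0:
            raise ValueError("total_input_ng must be positive")
        if any(s < 0 for s, _ in self.points):
            raise ValueError("spike masses must be >= 0")

    @property
    def spikes(self) -> np.ndarray:
        return np.array([s for s, _ in self.points], dtype=float)

    @property
    def signals(self) -> np.ndarray:
        return np.array([y for _, y in self.points], dtype=float)


@dataclass(frozen=True)
class CalibrationFit:
    """OLS result of signal on spiked mass, plus the derived endogenous mass."""

    slope: float  # signal per ng of spike
    intercept: float  # signal at zero spike
    r_squared: float
    endogenous_ng: float  # from the y-intercept (rpm_to_ng) when signal is rpm
    x_intercept_ng: float  # classical standard-addition estimate |intercept/slope|
    stderr_slope: float
    flags: tuple[str, ...] = ()


def fit_standard_addition(series: CalibrationSeries) -> CalibrationFit:
    """Ordinary least squares of signal on spike mass.

    R² is the squared Pearson correlation. A zero-slope (constant-signal)
    series yields R² = 0 with a ``"zero_slope"`` flag rather than NaN; a
    negative endogenous estimate is reported with a ``"negative_mass"`` flag,
    not clipped.
    """
    x, y = series.spikes, series.signals
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("all spike levels identical")
    result = stats.linregress(x, y)
    flags: list[str] = []
    if np.ptp(y) == 0 or result.slope == 0:
        r_squared = 0.0
        flags.append("zero_slope")
    else:
        r_squared = float(result.rvalue**2)

    if series.signal_is_rpm:
        # inline conversion: a (noisy) negative intercept is reported, not rejected
        endogenous = float(result.intercept) / 1e6 * series.total_input_ng
    else:
        # raw-count mode: counts have no absolute scale; fall back to the
        # classical x-intercept estimate
        endogenous = (
            abs(float(result.intercept) / float(result.slope))
            if result.slope != 0
            else float("nan")
        )
    if endogenous < 0:
        flags.append("negative_mass")

    x_intercept = (
        abs(float(result.intercept) / float(result.slope))
        if result.slope != 0
        else float("nan")
    )
    return CalibrationFit(
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=r_squared,
        endogenous_ng=float(endogenous),
        x_intercept_ng=x_intercept,
        stderr_slope=float(result.stderr) if result.stderr is not None else 0.0,
        flags=tuple(flags),
    )


def rpm_to_ng(rpm: float, total_input_ng: float) -> float:
    """Convert reads-per-million into nanograms of a ``total_input_ng`` pool."""
    if rpm < 0:
        raise ValueError("rpm must be >= 0")
    if total_input_ng <= 0:
        raise ValueError("total_input_ng must be positive")
    return (rpm / 1e6) * total_input_ng


def absolute_pool(
    table: AbundanceTable, anchor_family: str, anchor_ng: float
) -> dict[str, float]:
    """Absolute mass of every family, scaled from the calibrated anchor.

    ``ng_f = anchor_ng * fraction_f / fraction_anchor``; the anchor maps to
    ``anchor_ng`` exactly and mass ratios equal fraction ratios.
    """
    fractions = table.fractions
    anchor_fraction = fractions.get(anchor_family, 0.0)
    if anchor_family not in fractions or anchor_fraction == 0.0:
        raise AnchorMissingError(
            f"anchor family {anchor_family!r} absent or unobserved"
        )
    scale = anchor_ng / anchor_fraction
    out = {name: scale * frac for name, frac in fractions.items()}
    out[anchor_family] = anchor_ng
    return out


def write_fit_json(fit: CalibrationFit, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "endogenous_ng": fit.endogenous_ng,
                "x_intercept_ng": fit.x_intercept_ng,
                "stderr_slope": fit.stderr_slope,
                "flags": list(fit.flags),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
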