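"""Measurement uncertainty budget for ambient neutron monitor campaigns.

Components (all relative, k = 1):

* positioning — detectors are placed with finite precision; the induced dose
  uncertainty is read off a simulated dose mesh by volume-averaging the dose
  over the detector at the nominal position and at positions shifted along
  ±x, ±y, ±z, then taking the standard deviation of a uniform distribution
  between the lowest and highest of those averages, (max-min)/sqrt(12);
* statistical — Poisson counting, 1/sqrt(counts);
* calibration — instrument-specific, user supplied;
* energy response — |1 - expected response| when the monitor reading is not
  corrected for its imperfect energy response (when the correction is
  applied, its residual uncertainty should be entered instead);
* target dose — uncertainty of the delivered dose the results are
  normalized to.

Independent components combine in quadrature (root sum of squares).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DoseMesh",
    "UncertaintyBudget",
    "EnergyResponseComponent",
    "counting_uncertainty",
    "positioning_uncertainty",
    "energy_response_component",
    "combine_budget",
]


@dataclass(frozen=True)
class DoseMesh:
    """H*(10) values on a regular 3-D lattice (µSv/Gy), spacing in cm."""

    values: np.ndarray
    spacing: float  # cm, isotropic
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 3:
            raise ValueError("mesh must be a 3-D lattice")
        if np.any(v <= 0):
            raise ValueError("mesh values must be positive")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    def detector_average(self, center: np.ndarray, radius: float) -> float:
        """Mean dose over the lattice points within ``radius`` cm of ``center``.

        Raises if the detector sphere is not fully covered by the mesh.
        """
        center = np.asarray(center, dtype=float)
        origin = np.asarray(self.origin, dtype=float)
        hi = origin + (np.array(self.values.shape) - 1) * self.spacing
        if np.any(center - radius < origin - 1e-9) or np.any(center + radius > hi + 1e-9):
            raise ValueError("mesh does not cover the detector volume")
        axes = [origin[i] + self.spacing * np.arange(self.values.shape[i]) for i in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        mask = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius**2
        if not mask.any():
            raise ValueError("detector radius smaller than the mesh spacing")
        return float(self.values[mask].mean())


@dataclass(frozen=True)
class EnergyResponseComponent:
    fraction: float
    direction: str  # "over", "under" or "exact"


@dataclass(frozen=True)
class UncertaintyBudget:
    """Named relative uncertainty components and their quadrature combination."""

    components: dict[str, float]
    combined: float


def counting_uncertainty(counts: int) -> float:
    """Relative Poisson counting uncertainty, 1/sqrt(counts)."""
    if counts < 1:
        raise ValueError("counts must be at least 1")
    return 1.0 / math.sqrt(counts)


def positioning_uncertainty(
    mesh: DoseMesh,
    nominal_position: tuple[float, float, float],
    shift: float = 5.0,
    detector_radius: float = 10.0,
) -> float:
    """Relative positioning uncertainty from a dose mesh.

    Volume-averages the dose at the nominal position and at the six
    positions shifted by ±``shift`` cm along each axis, then returns
    (max - min) / (sqrt(12) * nominal average): the k = 1 standard
    deviation of a uniform distribution spanning the observed dose range,
    relative to the nominal dose.
    """
    if shift < 0 or detector_radius <= 0:
        raise ValueError("shift must be >= 0 and radius > 0")
    nominal = np.asarray(nominal_position, dtype=float)
    offsets = [np.zeros(3)]
    for axis in range(3):
        for sign in (+1.0, -1.0):
            off = np.zeros(3)
            off[axis] = sign * shift
            offsets.append(off)
    averages = [mesh.detector_average(nominal + off, detector_radius) for off in offsets]
    nominal_avg = averages[0]
    return (max(averages) - min(averages)) / (math.sqrt(12.0) * nominal_avg)


def energy_response_component(expected_response: float) -> EnergyResponseComponent:
    """Uncertainty component for an uncorrected imperfect energy response.

    |1 - R| with metadata on whether the monitor over- or under-responds.
    """
    if expected_response <= 0:
        raise ValueError("expected response must be positive")
    dev = expected_response - 1.0
    direction = "over" if dev > 0 else "under" if dev < 0 else "exact"
    return EnergyResponseComponent(fraction=abs(dev), direction=direction)


def combine_budget(components: dict[str, float]) -> UncertaintyBudget:
    """Quadrature combination of independent k = 1 relative components."""
    for name, value in components.items():
        if value < 0:
            raise ValueError(f"component {name!r} is negative")
    combined = math.sqrt(sum(v * v for v in components.values()))
    return UncertaintyBudget(components=dict(components), combined=combined)
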