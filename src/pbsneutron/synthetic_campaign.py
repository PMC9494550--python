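"""Synthetic measurement-campaign generator.

Stands in for the combination of Monte Carlo room simulations and monitor
measurement campaigns: builds factorial treatment-plan grids over the
clinical parameter domain, evaluates ground-truth doses from a known
scaling model at the six room positions, optionally applies a per-position
monitor response bias, and adds multiplicative lognormal measurement noise
(doses are positive and uncertainties are quoted relatively, so lognormal
is the natural noise model; the default per-position sigmas sit in the
15-30 % band typical of such campaigns).

The default truth model is a fixture, not a claim about any facility: its
baselines and slopes were chosen once so that the generated campaigns echo
the qualitative behaviour of measured treatment rooms — doses of order
1-300 µSv/Gy falling with distance and backward angle (B highest, then F,
then E >= D), a range factor of ~3 from 10 to 25 cm, a ~40 % modulation
effect from 3 to 20 cm, and a range-shifter factor below 2.5 except at the
position with line of sight to the shifter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scaling import (
    CAMPAIGN_COLUMNS,
    CampaignTable,
    Position,
    PositionCoefficients,
    ScalingModel,
    TreatmentPlan,
    predict_h10,
)

__all__ = [
    "CampaignDesign",
    "GroundTruth",
    "default_positions",
    "default_truth_model",
    "default_design",
    "generate_plan_grid",
    "generate_campaign",
]


def default_positions() -> dict[str, Position]:
    """The six monitor positions around the phantom.

    B, D, E and F follow the campaign geometry (B at 1 m in the beam
    direction, F at 1.5 m perpendicular, D and E at 2.25 m perpendicular
    and backward).  The A and C entries are synthetic placeholders — their
    true distances and angles were never published — and should be replaced
    by facility values when available.
    """
    return {
        "A": Position("A", 1.8, 45.0),  # synthetic placeholder
        "B": Position("B", 1.0, 0.0),
        "C": Position("C", 2.0, 30.0),  # synthetic placeholder
        "D": Position("D", 2.25, 90.0),
        "E": Position("E", 2.25, 180.0),
        "F": Position("F", 1.5, 90.0),
    }


def default_truth_model() -> ScalingModel:
    """The fixture truth model used by the synthetic campaigns (see module docstring)."""
    coefficients = {
        "A": PositionCoefficients(a0=30.0, c_range=0.08, c_mod1=0.04, c_mod2=-5e-4),
        "B": PositionCoefficients(a0=66.0, c_range=0.10, c_mod1=0.04, c_mod2=-5e-4),
        "C": PositionCoefficients(a0=20.0, c_range=0.09, c_mod1=0.04, c_mod2=-5e-4),
        "D": PositionCoefficients(a0=1.0, c_range=0.12, c_mod1=0.04, c_mod2=-5e-4),
        "E": PositionCoefficients(a0=3.0, c_range=0.06, c_mod1=0.04, c_mod2=-5e-4),
        "F": PositionCoefficients(a0=10.0, c_range=0.08, c_mod1=0.04, c_mod2=-5e-4),
    }
    return ScalingModel(coefficients=coefficients, positions=default_positions())


DEFAULT_NOISE_SIGMA = {
    "A": 0.20,
    "B": 0.15,
    "C": 0.30,
    "D": 0.25,
    "E": 0.20,
    "F": 0.18,
}


@dataclass(frozen=True)
class CampaignDesign:
    """Plan axes, positions and noise model of a synthetic campaign."""

    field_sizes_cm2: tuple[float, ...] = (9.0, 25.0, 100.0, 400.0, 625.0)
    ranges_cm: tuple[float, ...] = (8.0, 10.0, 15.0, 20.0, 25.0)
    modulations_cm: tuple[float, ...] = (3.0, 5.0, 10.0)
    range_shifter_options: tuple[bool, ...] = (False,)
    air_gaps_cm: tuple[float, ...] = (10.0,)
    positions: dict[str, Position] = field(default_factory=default_positions)
    noise_sigma: dict[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SIGMA)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.field_sizes_cm2 and self.ranges_cm and self.modulations_cm):
            raise ValueError("plan axes must be non-empty")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def sigma_for(self, position: str) -> float:
        if isinstance(self.noise_sigma, dict):
            return float(self.noise_sigma[position])
        return float(self.noise_sigma)


@dataclass(frozen=True)
class GroundTruth:
    """The generating model and the per-row true doses of a campaign."""

    model: ScalingModel
    true_doses: pd.DataFrame  # columns: irradiation_id, position, h10_uSv_per_Gy


def generate_plan_grid(design: CampaignDesign) -> list[TreatmentPlan]:
    """Full factorial plan grid over the design axes.

    Combinations with modulation exceeding the range are dropped (they are
    physically impossible); the number of dropped combinations is reported
    via the returned list's length versus the factorial size.  Air gaps are
    attached only when the range shifter is in.
    """
    plans: list[TreatmentPlan] = []
    n_dropped = 0
    for fs, r, m, rs in itertools.product(
        design.field_sizes_cm2,
        design.ranges_cm,
        design.modulations_cm,
        design.range_shifter_options,
    ):
        if m > r:
            n_dropped += 1
            continue
        gaps = design.air_gaps_cm if rs else (None,)
        for gap in gaps:
            plans.append(
                TreatmentPlan(
                    field_size_cm2=fs,
                    range_cm=r,
                    modulation_cm=m,
                    range_shifter=rs,
                    air_gap_cm=gap,
                )
            )
    if not plans:
        raise ValueError(
            f"no valid plans: all {n_dropped} combinations violate modulation <= range"
        )
    return plans


def generate_campaign(
    design: CampaignDesign,
    truth_model: ScalingModel | None = None,
    monitor_response: dict[str, float] | None = None,
) -> tuple[CampaignTable, CampaignTable, GroundTruth]:
    """Generate (measured, true, ground-truth) campaign tables.

    True doses come from the truth model; measured doses are the true doses
    times an optional per-position monitor response factor times unit-median
    lognormal noise with the design's per-position sigma.  Fully reproducible
    for a fixed design seed.
    """
    if truth_model is None:
        truth_model = default_truth_model()
    rng = np.random.default_rng(design.seed)
    plans = generate_plan_grid(design)
    records_true = []
    records_meas = []
    for i, plan in enumerate(plans, start=1):
        irr = f"irr{i:04d}"
        for pos in sorted(design.positions):
            true = predict_h10(truth_model, plan, pos)
            bias = monitor_response.get(pos, 1.0) if monitor_response else 1.0
            sigma = design.sigma_for(pos)
            noise = float(np.exp(sigma * rng.standard_normal())) if sigma > 0 else 1.0
            base = {
                "irradiation_id": irr,
                "field_size_cm2": plan.field_size_cm2,
                "range_cm": plan.range_cm,
                "modulation_cm": plan.modulation_cm,
                "range_shifter": plan.range_shifter,
                "air_gap_cm": np.nan if plan.air_gap_cm is None else plan.air_gap_cm,
                "position": pos,
            }
            records_true.append({**base, "h10_uSv_per_Gy": true, "rel_uncertainty": 0.0})
            records_meas.append(
                {**base, "h10_uSv_per_Gy": true * bias * noise, "rel_uncertainty": sigma}
            )
    true_table = CampaignTable(pd.DataFrame.from_records(records_true, columns=CAMPAIGN_COLUMNS))
    meas_table = CampaignTable(pd.DataFrame.from_records(records_meas, columns=CAMPAIGN_COLUMNS))
    truth = GroundTruth(
        model=truth_model,
        true_doses=true_table.rows[["irradiation_id", "position", "h10_uSv_per_Gy"]].copy(),
    )
    return meas_table, true_table, truth
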