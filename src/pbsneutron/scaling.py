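"""Scaling-law model of out-of-field neutron H*(10) versus plan parameters.

Around a scanned proton field, the ambient neutron dose equivalent per unit
target dose varies over orders of magnitude with position, and with the
treatment plan roughly as: linearly with field-size area, approximately
linearly with range, and quadratically with the spread-out-Bragg-peak
modulation width.  Inserting a range shifter acts, to first order, like
increasing the range by the shifter's water-equivalent thickness; the air
gap between shifter and patient has no significant effect at room positions.

The model here is multiplicative and per-position:

    H(plan, pos) = A0_pos * (FS / FS_ref)
                 * (1 + cR_pos (R_eff - R_ref))
                 * (1 + cM1_pos M + cM2_pos M^2) / (1 + cM1_pos M_ref + cM2_pos M_ref^2)

normalized so that the reference plan maps to the baseline A0.  Coefficients
are fitted per position by least squares in log space (doses span four
decades, so relative errors are what matter).  Multiplicative separability
is a modelling choice: the underlying physics has interdependencies between
the axes, which per-position coefficients absorb only partly; the fit
diagnostics report the residual spread so users can judge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TreatmentPlan",
    "Position",
    "PositionCoefficients",
    "ScalingModel",
    "CampaignTable",
    "FitResult",
    "OrganDoseEstimate",
    "REFERENCE_PLAN",
    "effective_range",
    "predict_h10",
    "fit_scaling_model",
    "extrapolate_inverse_square",
    "estimate_organ_dose",
]

logger = logging.getLogger(__name__)

#: Treatment-plan domain covered by the underlying campaigns.
PLAN_DOMAIN = {
    "field_size_cm2": (9.0, 625.0),
    "range_cm": (8.0, 25.0),
    "modulation_cm": (3.0, 25.0),
    "air_gap_cm": (5.5, 23.0),
}

CAMPAIGN_COLUMNS = [
    "irradiation_id",
    "field_size_cm2",
    "range_cm",
    "modulation_cm",
    "range_shifter",
    "air_gap_cm",
    "position",
    "h10_uSv_per_Gy",
    "rel_uncertainty",
]


@dataclass(frozen=True)
class TreatmentPlan:
    """Plan parameters of a rectangular scanned proton field."""

    field_size_cm2: float
    range_cm: float
    modulation_cm: float
    range_shifter: bool = False
    air_gap_cm: float | None = None
    rs_wet_cm: float = 3.1  # water-equivalent thickness of the range shifter

    def __post_init__(self) -> None:
        if self.field_size_cm2 <= 0 or self.range_cm <= 0 or self.modulation_cm <= 0:
            raise ValueError("plan parameters must be positive")
        if self.modulation_cm > self.range_cm:
            raise ValueError("modulation width cannot exceed the range")
        if self.rs_wet_cm < 0:
            raise ValueError("range-shifter WET must be non-negative")
        for name, (lo, hi) in PLAN_DOMAIN.items():
            if name == "air_gap_cm":
                continue
            v = getattr(self, name)
            if not (lo <= v <= hi):
                warnings.warn(
                    f"{name} = {v:g} outside the campaign domain [{lo:g}, {hi:g}]"
                )
        if self.range_shifter and self.air_gap_cm is not None:
            lo, hi = PLAN_DOMAIN["air_gap_cm"]
            if not (lo <= self.air_gap_cm <= hi):
                warnings.warn(
                    f"air_gap_cm = {self.air_gap_cm:g} outside [{lo:g}, {hi:g}]"
                )


#: Central plan used as the normalization point of the scaling law.
REFERENCE_PLAN = TreatmentPlan(field_size_cm2=100.0, range_cm=15.0, modulation_cm=10.0)


@dataclass(frozen=True)
class Position:
    """A monitor position: label, distance to isocenter (m), angle to beam (deg)."""

    label: str
    distance_m: float
    angle_deg: float

    def __post_init__(self) -> None:
        if self.distance_m <= 0:
            raise ValueError("distance must be positive")
        if not (0.0 <= self.angle_deg <= 180.0):
            raise ValueError("angle must lie in [0, 180] degrees")


@dataclass(frozen=True)
class PositionCoefficients:
    """Per-position scaling coefficients."""

    a0: float  # µSv/Gy at the reference plan
    c_range: float  # per cm of (effective) range
    c_mod1: float  # per cm of modulation width
    c_mod2: float  # per cm^2 of modulation width

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("baseline A0 must be positive")


@dataclass(frozen=True)
class ScalingModel:
    """Multiplicative per-position scaling law with a fixed reference plan."""

    coefficients: dict[str, PositionCoefficients]
    reference_plan: TreatmentPlan = REFERENCE_PLAN
    rs_mode: str = "effective_range"  # or "flat_factor"
    flat_factor: float = 2.0
    positions: dict[str, Position] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("model needs at least one position")
        if self.rs_mode not in ("effective_range", "flat_factor"):
            raise ValueError("rs_mode must be 'effective_range' or 'flat_factor'")
        if self.flat_factor <= 0:
            raise ValueError("flat_factor must be positive")


@dataclass(frozen=True)
class CampaignTable:
    """Irradiation x position H*(10) table backed by a pandas DataFrame."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in CAMPAIGN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"campaign table missing columns: {missing}")
        if (df["h10_uSv_per_Gy"] <= 0).any():
            raise ValueError("H*(10) values must be positive")
        dup = df.duplicated(subset=["irradiation_id", "position"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["irradiation_id", "position"]].tolist()
            raise ValueError(f"duplicate (irradiation, position) key: {key}")

    def __len__(self) -> int:
        return len(self.rows)

    def plan(self, row) -> TreatmentPlan:
        """Reconstruct the TreatmentPlan of a table row."""
        gap = row["air_gap_cm"]
        return TreatmentPlan(
            field_size_cm2=float(row["field_size_cm2"]),
            range_cm=float(row["range_cm"]),
            modulation_cm=float(row["modulation_cm"]),
            range_shifter=bool(row["range_shifter"]),
            air_gap_cm=None if pd.isna(gap) else float(gap),
        )


@dataclass(frozen=True)
class FitResult:
    model: ScalingModel
    diagnostics: dict[str, dict]


@dataclass(frozen=True)
class OrganDoseEstimate:
    dose_uSv_per_Gy: float
    factors: dict[str, float]


def effective_range(plan: TreatmentPlan) -> float:
    """Nominal range plus the range-shifter WET when a shifter is inserted."""
    return plan.range_cm + (plan.rs_wet_cm if plan.range_shifter else 0.0)


def _mod_term(c: PositionCoefficients, m: float) -> float:
    return 1.0 + c.c_mod1 * m + c.c_mod2 * m * m


def _range_term(c: PositionCoefficients, r_eff: float, r_ref: float) -> float:
    return 1.0 + c.c_range * (r_eff - r_ref)


def predict_h10(model: ScalingModel, plan: TreatmentPlan, position: str) -> float:
    """Predicted neutron H*(10) in µSv per Gy target dose at a position.

    Exactly linear in field-size area; the air gap is accepted but ignored
    (it was found to have no significant effect at room positions).
    """
    if position not in model.coefficients:
        raise KeyError(f"model has no coefficients for position {position!r}")
    if plan.air_gap_cm is not None and not getattr(predict_h10, "_air_gap_warned", False):
        logger.warning(
            "air gap (%.3g cm) has no effect on the prediction by design "
            "(further occurrences suppressed)",
            plan.air_gap_cm,
        )
        predict_h10._air_gap_warned = True  # type: ignore[attr-defined]
    c = model.coefficients[position]
    ref = model.reference_plan
    if model.rs_mode == "effective_range":
        r_eff = effective_range(plan)
        rs_factor = 1.0
    else:
        r_eff = plan.range_cm
        rs_factor = model.flat_factor if plan.range_shifter else 1.0
    r_ref = effective_range(ref)
    h = (
        c.a0
        * (plan.field_size_cm2 / ref.field_size_cm2)
        * _range_term(c, r_eff, r_ref)
        * _mod_term(c, plan.modulation_cm)
        / _mod_term(c, ref.modulation_cm)
        * rs_factor
    )
    if h <= 0 or not np.isfinite(h):
        raise ValueError(
            f"model predicts a non-positive dose at position {position!r}; "
            "coefficients are invalid over this plan domain"
        )
    return float(h)


def _check_design(df: pd.DataFrame) -> None:
    requirements = {
        "field_size_cm2": 2,
        "range_cm": 2,
        "modulation_cm": 3,  # quadratic term needs three support points
    }
    for col, n_req in requirements.items():
        if df[col].nunique() < n_req:
            raise ValueError(
                f"rank-deficient design: need at least {n_req} distinct "
                f"values of {col.removesuffix('_cm2').removesuffix('_cm')}"
            )


def fit_scaling_model(
    campaign: CampaignTable,
    reference_plan: TreatmentPlan = REFERENCE_PLAN,
    rs_mode: str = "effective_range",
    positions: dict[str, Position] | None = None,
) -> FitResult:
    """Fit per-position scaling coefficients by least squares in log space.

    The field-size dependence is structural (exactly linear in area); the
    range slope and the two modulation coefficients are estimated per
    position together with the baseline.  Rows are sorted by irradiation id
    so the fit is deterministic under row permutation.  Diagnostics carry
    the log-space RMSE and coefficient standard errors per position.
    """
    df = campaign.rows.sort_values(["position", "irradiation_id"]).reset_index(drop=True)
    _check_design(df)
    r_ref = effective_range(reference_plan)
    m_ref = reference_plan.modulation_cm
    coefficients: dict[str, PositionCoefficients] = {}
    diagnostics: dict[str, dict] = {}

    for pos, grp in df.groupby("position", sort=True):
        fs = grp["field_size_cm2"].to_numpy(float)
        rng_nominal = grp["range_cm"].to_numpy(float)
        rs = grp["range_shifter"].to_numpy(bool)
        if rs_mode == "effective_range":
            r_eff = rng_nominal + np.where(rs, reference_plan.rs_wet_cm, 0.0)
        else:
            r_eff = rng_nominal
        mod = grp["modulation_cm"].to_numpy(float)
        log_h = np.log(grp["h10_uSv_per_Gy"].to_numpy(float))
        log_fs = np.log(fs / reference_plan.field_size_cm2)

        def residuals(theta: np.ndarray) -> np.ndarray:
            log_a0, c_r, c1, c2 = theta
            range_term = 1.0 + c_r * (r_eff - r_ref)
            mod_term = (1.0 + c1 * mod + c2 * mod * mod) / (
                1.0 + c1 * m_ref + c2 * m_ref * m_ref
            )
            pred = log_a0 + log_fs + np.log(np.clip(range_term, 1e-9, None)) + np.log(
                np.clip(mod_term, 1e-9, None)
            )
            return pred - log_h

        x0 = np.array([np.mean(log_h - log_fs), 0.05, 0.02, 0.0])
        sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
        log_a0, c_r, c1, c2 = sol.x
        coefficients[str(pos)] = PositionCoefficients(
            a0=float(np.exp(log_a0)), c_range=float(c_r), c_mod1=float(c1), c_mod2=float(c2)
        )
        n, p = len(grp), 4
        ssr = float(np.sum(sol.fun**2))
        dof = max(n - p, 1)
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * ssr / dof
            stderr = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            stderr = np.full(p, np.nan)
        diagnostics[str(pos)] = {
            "n_rows": n,
            "rmse_log": float(np.sqrt(ssr / n)),
            "stderr": {
                "log_a0": float(stderr[0]),
                "c_range": float(stderr[1]),
                "c_mod1": float(stderr[2]),
                "c_mod2": float(stderr[3]),
            },
        }

    model = ScalingModel(
        coefficients=coefficients,
        reference_plan=reference_plan,
        rs_mode=rs_mode,
        positions=positions or {},
    )
    return FitResult(model=model, diagnostics=diagnostics)


def extrapolate_inverse_square(h10: float, d_ref: float, d_target: float) -> float:
    """Rescale a dose from distance ``d_ref`` to ``d_target`` (both in m)."""
    if d_ref <= 0 or d_target <= 0:
        raise ValueError("distances must be positive")
    return h10 * (d_ref / d_target) ** 2


def estimate_organ_dose(
    reference_h10: float,
    reference_plan: TreatmentPlan,
    target_plan: TreatmentPlan,
    position: Position,
    target_distance_m: float,
    model: ScalingModel,
) -> OrganDoseEstimate:
    """Rough organ-level dose estimate from a measured/simulated reference.

    Applies, in order: a field-size factor (ratio of areas), a range factor
    and a modulation factor from the model's per-position law between the
    two plans, and the inverse-square distance law from the position's
    distance to the target distance.  Each factor is returned separately;
    their product times ``reference_h10`` is the estimate.
    """
    if reference_h10 <= 0:
        raise ValueError("reference dose must be positive")
    if target_distance_m <= 0:
        raise ValueError("target distance must be positive")
    if position.label not in model.coefficients:
        raise KeyError(f"model has no coefficients for position {position.label!r}")
    c = model.coefficients[position.label]
    r_ref_model = effective_range(model.reference_plan)
    factors = {
        "field_size": target_plan.field_size_cm2 / reference_plan.field_size_cm2,
        "range": _range_term(c, effective_range(target_plan), r_ref_model)
        / _range_term(c, effective_range(reference_plan), r_ref_model),
        "modulation": _mod_term(c, target_plan.modulation_cm)
        / _mod_term(c, reference_plan.modulation_cm),
        "inverse_square": (position.distance_m / target_distance_m) ** 2,
    }
    dose = reference_h10
    for f in factors.values():
        dose *= f
    return OrganDoseEstimate(dose_uSv_per_Gy=float(dose), factors=factors)
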