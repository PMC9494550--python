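"""Fluence-to-H*(10) conversion and ambient neutron monitor response.

An area neutron monitor reports ambient dose equivalent H*(10), but its
energy response R(E) — reading per unit true H*(10) as a function of neutron
energy — deviates from unity, most severely for the high-energy (cascade)
neutrons present in proton therapy rooms.  Given a neutron fluence spectrum,
this module computes the true H*(10) via tabulated fluence-to-H*(10)
conversion coefficients h*(E), the expected (H*(10)-weighted mean) response
of a monitor, and the reading the monitor would display, plus per-position
summaries of simulated-over-measured reading ratios.

Interpolation is log-log linear: both h*(E) and R(E) vary over many decades
of energy.  Response tables containing zeros (hard high-energy cutoffs) fall
back to linear interpolation of R against log E.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .spectra import NeutronSpectrum

__all__ = [
    "ConversionTable",
    "ResponseFunction",
    "ReadingComparison",
    "COMPARISON_CASES",
    "h10_from_spectrum",
    "expected_monitor_response",
    "predict_reading",
    "ratio_summary",
]

COMPARISON_CASES = ("no_room", "with_room", "no_room_energy_corrected")

_PSV_TO_USV = 1e-6


def _loglog_interp(e: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return np.exp(np.interp(np.log(e), np.log(xs), np.log(ys)))


def _loglin_interp(e: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return np.interp(np.log(e), np.log(xs), ys)


@dataclass(frozen=True)
class ConversionTable:
    """Tabulated fluence-to-H*(10) conversion coefficients h*(E).

    Energies in MeV, coefficients in pSv cm^2 per neutron.
    """

    energies: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        c = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "coefficients", c)
        if e.ndim != 1 or e.size < 2 or e.shape != c.shape:
            raise ValueError("table needs matching 1-D energies and coefficients")
        if np.any(np.diff(e) <= 0):
            raise ValueError("table energies must be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("conversion coefficients must be positive")

    @property
    def span(self) -> tuple[float, float]:
        return (float(self.energies[0]), float(self.energies[-1]))

    def __call__(self, e: np.ndarray) -> np.ndarray:
        e = np.asarray(e, dtype=float)
        lo, hi = self.span
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError("energy outside the conversion table span")
        return _loglog_interp(e, self.energies, self.coefficients)

    @classmethod
    def default(cls) -> "ConversionTable":
        """The bundled synthetic h*(10) table (extended to 240 MeV)."""
        from ._io import read_conversion_csv

        with resources.as_file(
            resources.files("pbsneutron.data") / "h10_conversion_synthetic.csv"
        ) as path:
            return read_conversion_csv(path)


@dataclass(frozen=True)
class ResponseFunction:
    """Tabulated dimensionless H*(10) energy response of a monitor.

    Inside ``valid_range`` but beyond the tabulated energies, R extends as a
    constant at the nearest tabulated value.  Evaluating non-zero weight
    outside ``valid_range`` is an error: silently returning zero would
    fabricate a cutoff the instrument may not have.
    """

    monitor_id: str
    energies: np.ndarray
    response: np.ndarray
    valid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "response", r)
        if e.ndim != 1 or e.size < 2 or e.shape != r.shape:
            raise ValueError("response needs matching 1-D energies and values")
        if np.any(np.diff(e) <= 0):
            raise ValueError("response energies must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("response values must be non-negative")
        vr = self.valid_range
        if vr is None:
            vr = (float(e[0]), float(e[-1]))
        if vr[0] >= vr[1]:
            raise ValueError("valid_range must be an increasing interval")
        object.__setattr__(self, "valid_range", (float(vr[0]), float(vr[1])))

    def __call__(self, e: np.ndarray) -> np.ndarray:
        e = np.asarray(e, dtype=float)
        lo, hi = self.valid_range
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside the valid range of monitor {self.monitor_id!r}"
            )
        ec = np.clip(e, self.energies[0], self.energies[-1])
        if np.all(self.response > 0):
            return _loglog_interp(ec, self.energies, self.response)
        return _loglin_interp(ec, self.energies, self.response)


@dataclass(frozen=True)
class ReadingComparison:
    """Per-position simulated/measured H*(10) ratio summary."""

    position: str
    ratios: np.ndarray
    case: str

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        object.__setattr__(self, "ratios", r)
        if np.any(r <= 0):
            raise ValueError("ratios must be positive")
        if self.case not in COMPARISON_CASES:
            raise ValueError(f"case must be one of {COMPARISON_CASES}")

    @property
    def average(self) -> float:
        return float(self.ratios.mean())


def h10_from_spectrum(spectrum: NeutronSpectrum, table: ConversionTable) -> float:
    """Ambient dose equivalent H*(10) in µSv per Gy target dose.

    H = sum_i fluence_i * h*(E_i), with E_i the geometric-mean bin energy.
    """
    fl = spectrum.fluence
    nz = fl > 0
    if not nz.any():
        return 0.0
    e_rep = spectrum.grid.geometric_means
    lo, hi = table.span
    if np.any(e_rep[nz] < lo) or np.any(e_rep[nz] > hi):
        raise ValueError("non-zero fluence outside the conversion table span")
    return float(np.sum(fl[nz] * table(e_rep[nz]))) * _PSV_TO_USV


def expected_monitor_response(
    spectrum: NeutronSpectrum, rf: ResponseFunction, table: ConversionTable
) -> float:
    """H*(10)-weighted mean response of a monitor in the given field.

    response = sum_i fluence_i h*(E_i) R(E_i) / sum_i fluence_i h*(E_i).
    Scale-free in the spectrum; lies between min and max of R over the bins
    carrying dose.
    """
    fl = spectrum.fluence
    nz = fl > 0
    if not nz.any():
        raise ValueError("expected response is undefined for an all-zero spectrum")
    e_rep = spectrum.grid.geometric_means[nz]
    w = fl[nz] * table(e_rep)
    return float(np.sum(w * rf(e_rep)) / np.sum(w))


def predict_reading(
    spectrum: NeutronSpectrum, rf: ResponseFunction, table: ConversionTable
) -> float:
    """Monitor reading in µSv per Gy: true H*(10) times the expected response."""
    return h10_from_spectrum(spectrum, table) * expected_monitor_response(
        spectrum, rf, table
    )


def ratio_summary(sim, meas, case: str = "no_room"):
    """Per-position simulated/measured ratio averages and the grand average.

    Parameters are campaign tables (see :class:`pbsneutron.scaling.CampaignTable`)
    sharing (irradiation_id, position) keys.  Entries present in only one
    table are skipped and counted.  Returns ``(comparisons, grand_average,
    n_missing)`` where ``comparisons`` maps position label to
    :class:`ReadingComparison` and the grand average is the unweighted mean
    of the per-position averages.
    """
    if case not in COMPARISON_CASES:
        raise ValueError(f"case must be one of {COMPARISON_CASES}")
    keys = ["irradiation_id", "position"]
    s = sim.rows[keys + ["h10_uSv_per_Gy"]].rename(columns={"h10_uSv_per_Gy": "sim"})
    m = meas.rows[keys + ["h10_uSv_per_Gy"]].rename(columns={"h10_uSv_per_Gy": "meas"})
    merged = pd.merge(s, m, on=keys, how="outer", indicator=True)
    matched = merged[merged["_merge"] == "both"]
    n_missing = int((merged["_merge"] != "both").sum())
    if matched.empty:
        raise ValueError("no overlapping (irradiation, position) keys")
    if (matched["meas"] <= 0).any() or (matched["sim"] <= 0).any():
        raise ValueError("H*(10) values must be positive")
    comparisons: dict[str, ReadingComparison] = {}
    for pos, grp in matched.groupby("position", sort=True):
        comparisons[str(pos)] = ReadingComparison(
            position=str(pos), ratios=(grp["sim"] / grp["meas"]).to_numpy(), case=case
        )
    grand = float(np.mean([c.average for c in comparisons.values()]))
    return comparisons, grand, n_missing
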