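"""Conversion, monitor response convolution, and reading-ratio summaries."""

import numpy as np
import pandas as pd
import pytest

from pbsneutron import response as resp
from pbsneutron.response import (
    ConversionTable,
    ResponseFunction,
    expected_monitor_response,
    h10_from_spectrum,
    predict_reading,
    ratio_summary,
)
from pbsneutron.scaling import CAMPAIGN_COLUMNS, CampaignTable
from pbsneutron.spectra import NeutronSpectrum, build_lethargy_grid, synthesize_spectrum
from pbsneutron.spectra import ProtonSource

from conftest import make_spectrum


def unity_response(valid=(1e-9, 300.0)):
    e = np.logspace(-9, np.log10(300.0), 20)
    return ResponseFunction("unity", e, np.ones_like(e), valid)


def constant_response(value, valid=(1e-9, 300.0)):
    e = np.logspace(-9, np.log10(300.0), 20)
    return ResponseFunction("const", e, np.full_like(e, value), valid)


# --- independent brute-force oracle, deliberately separate from the package path ---

def brute_force_h10(spectrum, table):
    total_psv = 0.0
    for lo, hi, f in zip(spectrum.grid.lower, spectrum.grid.upper, spectrum.fluence):
        if f == 0:
            continue
        e = (lo * hi) ** 0.5
        # log-log interpolation by hand
        xs, ys = np.log(table.energies), np.log(table.coefficients)
        h = np.exp(np.interp(np.log(e), xs, ys))
        total_psv += f * h
    return total_psv * 1e-6


def brute_force_expected_response(spectrum, rf, table):
    num = den = 0.0
    for lo, hi, f in zip(spectrum.grid.lower, spectrum.grid.upper, spectrum.fluence):
        if f == 0:
            continue
        e = (lo * hi) ** 0.5
        h = np.exp(np.interp(np.log(e), np.log(table.energies), np.log(table.coefficients)))
        r = float(rf(np.array([e]))[0])
        num += f * h * r
        den += f * h
    return num / den


class TestH10FromSpectrum:
    def test_all_zero_spectrum(self, small_grid, flat_conversion):
        s = NeutronSpectrum(small_grid, np.zeros(small_grid.n_bins))
        assert h10_from_spectrum(s, flat_conversion) == 0.0

    def test_single_bin_hand_arithmetic(self, small_grid, flat_conversion):
        # 1e6 n/cm2/Gy at h* = 400 pSv cm2 -> 4e8 pSv = 400 µSv
        s = make_spectrum(small_grid, [(1.0, 1e6)])
        assert h10_from_spectrum(s, flat_conversion) == pytest.approx(400.0, rel=1e-12)

    def test_linearity(self, small_grid, flat_conversion):
        s = make_spectrum(small_grid, [(0.5, 1e4), (50.0, 2e4)])
        h1 = h10_from_spectrum(s, flat_conversion)
        h2 = h10_from_spectrum(s.scaled(2.0), flat_conversion)
        assert h2 == pytest.approx(2 * h1, rel=1e-12)

    def test_fluence_outside_table_span_rejected(self, small_grid):
        narrow = ConversionTable(np.array([1.0, 10.0]), np.array([400.0, 400.0]))
        s = make_spectrum(small_grid, [(100.0, 1.0)])
        with pytest.raises(ValueError):
            h10_from_spectrum(s, narrow)


class TestExpectedResponse:
    def test_unity_response_gives_one(self, small_grid, flat_conversion):
        rng = np.random.default_rng(3)
        s = NeutronSpectrum(small_grid, rng.uniform(0, 1, small_grid.n_bins))
        r = expected_monitor_response(s, unity_response(), flat_conversion)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_response_above_cutoff(self, small_grid, flat_conversion):
        e = np.array([1e-9, 10.0, 20.0, 300.0])
        rf = ResponseFunction("cutoff", e, np.array([1.0, 1.0, 0.0, 0.0]), (1e-9, 300.0))
        s = make_spectrum(small_grid, [(100.0, 1e4)])
        assert expected_monitor_response(s, rf, flat_conversion) == pytest.approx(0.0, abs=1e-9)

    def test_equal_weight_two_bin_mean(self, small_grid, flat_conversion):
        # equal H*(10) weight in bins where R = 0.4 and R = 0.8 -> 0.6
        s = make_spectrum(small_grid, [(0.01, 1e4), (50.0, 1e4)])
        e = np.array([1e-9, 0.5, 1.0, 300.0])
        rf = ResponseFunction("step", e, np.array([0.4, 0.4, 0.8, 0.8]), (1e-9, 300.0))
        r = expected_monitor_response(s, rf, flat_conversion)
        assert r == pytest.approx(0.6, rel=1e-9)

    def test_scale_invariance(self, small_grid, flat_conversion):
        s = make_spectrum(small_grid, [(0.1, 5.0), (30.0, 2.0)])
        rf = constant_response(0.7)
        r1 = expected_monitor_response(s, rf, flat_conversion)
        r2 = expected_monitor_response(s.scaled(137.0), rf, flat_conversion)
        assert r1 == pytest.approx(r2, rel=1e-14)

    def test_all_zero_spectrum_rejected(self, small_grid, flat_conversion):
        s = NeutronSpectrum(small_grid, np.zeros(small_grid.n_bins))
        with pytest.raises(ValueError):
            expected_monitor_response(s, unity_response(), flat_conversion)

    def test_outside_valid_range_rejected(self, small_grid, flat_conversion):
        rf = unity_response(valid=(1e-9, 10.0))
        s = make_spectrum(small_grid, [(100.0, 1.0)])
        with pytest.raises(ValueError):
            expected_monitor_response(s, rf, flat_conversion)


class TestPredictReading:
    def test_factorization_identity(self, small_grid, flat_conversion):
        rng = np.random.default_rng(11)
        s = NeutronSpectrum(small_grid, rng.uniform(0, 10, small_grid.n_bins))
        rf = constant_response(0.5)
        reading = predict_reading(s, rf, flat_conversion)
        assert reading == pytest.approx(
            h10_from_spectrum(s, flat_conversion)
            * expected_monitor_response(s, rf, flat_conversion),
            rel=1e-12,
        )
        assert reading == pytest.approx(0.5 * h10_from_spectrum(s, flat_conversion), rel=1e-12)

    def test_underresponding_monitor_reads_low_on_hard_spectrum(self, flat_conversion):
        """A monitor blind above ~20 MeV under-reads a high-energy-rich field."""
        grid = build_lethargy_grid(1e-9, 260.0, 0.26)
        spec = synthesize_spectrum(ProtonSource(((212.0, 1.0),)), grid=grid)
        e = np.array([1e-9, 10.0, 20.0, 50.0, 300.0])
        rf = ResponseFunction("lb-like", e, np.array([1.0, 1.0, 0.5, 0.05, 0.01]), (1e-9, 300.0))
        assert predict_reading(spec, rf, flat_conversion) < h10_from_spectrum(spec, flat_conversion)

    def test_bounded_by_h10_for_sub_unity_response(self, small_grid, flat_conversion):
        s = make_spectrum(small_grid, [(0.1, 5.0), (30.0, 2.0)])
        rf = constant_response(0.9)
        assert predict_reading(s, rf, flat_conversion) <= h10_from_spectrum(s, flat_conversion)


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_on_sparse_spectra(self, small_grid, seed):
        rng = np.random.default_rng(seed)
        table = ConversionTable(
            np.logspace(-9, np.log10(300.0), 15),
            rng.uniform(5, 600, 15),
        )
        e_resp = np.logspace(-9, np.log10(300.0), 10)
        rf = ResponseFunction("rand", e_resp, rng.uniform(0.2, 1.5, 10), (1e-9, 300.0))
        fl = np.zeros(small_grid.n_bins)
        fl[rng.choice(small_grid.n_bins, size=5, replace=False)] = rng.uniform(1, 100, 5)
        s = NeutronSpectrum(small_grid, fl)
        assert h10_from_spectrum(s, table) == pytest.approx(brute_force_h10(s, table), rel=1e-12)
        assert expected_monitor_response(s, rf, table) == pytest.approx(
            brute_force_expected_response(s, rf, table), rel=1e-12
        )


def _campaign_from_values(values):
    rows = []
    for (irr, pos), h in values.items():
        rows.append(
            {
                "irradiation_id": irr,
                "field_size_cm2": 100.0,
                "range_cm": 15.0,
                "modulation_cm": 10.0,
                "range_shifter": False,
                "air_gap_cm": float("nan"),
                "position": pos,
                "h10_uSv_per_Gy": h,
                "rel_uncertainty": 0.1,
            }
        )
    return CampaignTable(pd.DataFrame.from_records(rows, columns=CAMPAIGN_COLUMNS))


class TestRatioSummary:
    def test_identical_tables_give_unity(self):
        t = _campaign_from_values({("i1", "B"): 10.0, ("i2", "B"): 5.0, ("i1", "F"): 2.0})
        comps, grand, missing = ratio_summary(t, t)
        assert all(c.average == pytest.approx(1.0) for c in comps.values())
        assert grand == pytest.approx(1.0)
        assert missing == 0

    def test_doubled_position_average(self):
        meas = _campaign_from_values({("i1", "B"): 10.0, ("i1", "F"): 4.0})
        sim = _campaign_from_values({("i1", "B"): 20.0, ("i1", "F"): 4.0})
        comps, grand, _ = ratio_summary(sim, meas)
        assert comps["B"].average == pytest.approx(2.0)
        assert grand == pytest.approx(1.5)

    def test_mean_of_asymmetric_ratios(self):
        meas = _campaign_from_values({("i1", "B"): 2.0, ("i2", "B"): 2.0})
        sim = _campaign_from_values({("i1", "B"): 1.0, ("i2", "B"): 3.0})
        comps, _, _ = ratio_summary(sim, meas)
        assert comps["B"].average == pytest.approx(1.0)

    def test_missing_entries_counted(self):
        meas = _campaign_from_values({("i1", "B"): 2.0, ("i2", "B"): 2.0})
        sim = _campaign_from_values({("i1", "B"): 2.0, ("i3", "B"): 2.0})
        _, _, missing = ratio_summary(sim, meas)
        assert missing == 2

    def test_disjoint_keys_rejected(self):
        meas = _campaign_from_values({("i1", "B"): 2.0})
        sim = _campaign_from_values({("i2", "F"): 2.0})
        with pytest.raises(ValueError):
            ratio_summary(sim, meas)

    def test_invalid_case_rejected(self):
        t = _campaign_from_values({("i1", "B"): 1.0})
        with pytest.raises(ValueError):
            ratio_summary(t, t, case="bogus")
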