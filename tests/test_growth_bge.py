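"""Biovolume, bacterial carbon, growth rates, logistic fits and BGE."""

import math

import numpy as np
import pytest

from sipgrad.growth_bge import (
    bacterial_carbon,
    bge,
    bge_percent,
    biovolume,
    expected_doc_from_yield,
    round_half_up,
    specific_growth_rate,
    stationary_time,
    summarize_treatment,
    tdaa_yield,
)
from sipgrad.tables_io import GrowthSeries, TablesIOError


def _series(times, BA, L=None, W=None, DOC=None, TDAA=None, tid="t"):
    n = len(times)
    fill = lambda v: np.full(n, np.nan) if v is None else np.asarray(v, float)
    return GrowthSeries(
        treatment_id=tid,
        times=np.asarray(times, float),
        BA=np.asarray(BA, float),
        cell_L=fill(L),
        cell_W=fill(W),
        DOC=fill(DOC),
        TDAA_C=fill(TDAA),
    )


class TestBiovolume:
    def test_rod_with_hemispherical_ends(self):
        assert biovolume(2.0, 1.0) == pytest.approx(
            math.pi / 4 + math.pi / 6, abs=1e-12
        )

    def test_sphere(self):
        assert biovolume(1.0, 1.0) == pytest.approx(math.pi / 6, abs=1e-12)

    def test_aspect_boundary_takes_cylinder_branch(self):
        v = math.pi * 0.5 * 1 / 4 + math.pi / 6
        assert biovolume(1.5, 1.0) == pytest.approx(v, abs=1e-4)
        assert v == pytest.approx(0.9163, abs=1e-4)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            biovolume(0.0, 1.0)
        with pytest.raises(ValueError):
            biovolume(0.5, 1.0)


class TestBacterialCarbon:
    def test_zero_cells(self):
        assert bacterial_carbon(0.0, 0.1) == 0.0

    def test_unit_conversion(self):
        # 1e9 cells/L x 0.1 um^3 x 148 fg/um^3 = 1.48e10 fg C/L = 1.232 uM C
        assert bacterial_carbon(1e9, 0.1) == pytest.approx(1.232, abs=1e-3)

    def test_linearity(self):
        assert bacterial_carbon(2e9, 0.1) == pytest.approx(
            2 * bacterial_carbon(1e9, 0.1), rel=1e-12
        )


class TestSpecificGrowthRate:
    def test_exact_doubling(self):
        s = _series([0, 1, 2], [1e8, 2e8, 4e8])
        fit = specific_growth_rate(s)
        assert fit.mu == pytest.approx(math.log(2), abs=1e-12)

    def test_constant_ba_zero_rate(self):
        s = _series([0, 1, 2, 3], [1e8] * 4)
        assert specific_growth_rate(s).mu == pytest.approx(0.0, abs=1e-12)

    def test_noisy_exponential_recovered(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 2, 8)
        mu = 1.1
        ba = 1e8 * np.exp(mu * t) * np.exp(rng.normal(0, 0.05, t.size))
        fit = specific_growth_rate(_series(t, ba), window=(0, 2))
        assert fit.mu == pytest.approx(mu, rel=0.10)

    def test_window_restricts_points(self):
        s = _series([0, 1, 2, 3, 4], [1e8, 2e8, 4e8, 4e8, 4e8])
        fit = specific_growth_rate(s, window=(0, 2))
        assert fit.mu == pytest.approx(math.log(2), abs=1e-9)
        assert fit.n_points == 3

    def test_too_few_points_rejected(self):
        with pytest.raises(TablesIOError):
            specific_growth_rate(_series([0, 1], [1e8, 2e8]))


def _logistic(t, K, N0, r):
    return K / (1 + ((K - N0) / N0) * np.exp(-r * t))


class TestStationaryTime:
    def test_exact_logistic_midpoint(self):
        K, N0, r = 2e9, 1e8, 2.5
        t_mid = math.log((K - N0) / N0) / r  # = 1.1776 d for these values
        t = np.linspace(0, 4, 12)
        fit = stationary_time(_series(t, _logistic(t, K, N0, r)))
        assert fit.converged
        assert fit.t_mid == pytest.approx(t_mid, rel=1e-6)
        assert fit.t_stationary == pytest.approx(2 * t_mid, rel=1e-6)
        assert fit.t_stationary == 2 * fit.t_mid  # exact identity

    def test_declining_series_reports_no_fit(self):
        t = np.linspace(0, 3, 6)
        ba = 1e9 * np.exp(-0.5 * t)
        fit = stationary_time(_series(t, ba))
        assert fit.no_fit
        assert np.isnan(fit.t_stationary)


class TestBGE:
    @pytest.mark.parametrize(
        "int_bc, int_doc, expected",
        [(0.48, 2.1, 23), (0.85, 5.2, 16), (0.33, 2.5, 13), (1.0, 1.0, 100)],
    )
    def test_percent_from_integrals(self, int_bc, int_doc, expected):
        assert bge_percent(int_bc, int_doc) == expected

    def _growth_series(self):
        t = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        ba = _logistic(t, 2e9, 2e8, 3.0)
        doc = 50 - 4 * (ba - ba[0]) / (2e9 - 2e8)  # DOC drops as BC grows
        return _series(t, ba, L=[1.0] * 5, W=[0.5] * 5, DOC=doc)

    def test_full_computation_resolvable(self):
        res = bge(self._growth_series(), t_stationary=1.6)
        assert res.resolvable
        assert 0 < res.bge_percent <= 100
        # numerator/denominator share the time normalization
        assert res.bge_percent == bge_percent(res.int_bc, res.int_doc)

    def test_scale_invariance(self):
        s = self._growth_series()
        res1 = bge(s, t_stationary=1.6)
        scaled = _series(
            s.times, s.BA * 3, L=s.cell_L, W=s.cell_W,
            DOC=50 + (s.DOC - 50) * 3,
        )
        res2 = bge(scaled, t_stationary=1.6, doc_resolution=0.0)
        assert res2.int_bc == pytest.approx(3 * res1.int_bc, rel=1e-9)
        assert res2.int_doc == pytest.approx(3 * res1.int_doc, rel=1e-9)
        assert res2.bge_percent == res1.bge_percent

    def test_unresolvable_doc_flagged(self):
        t = np.array([0.0, 0.5, 1.0, 1.5])
        s = _series(
            t, [2e8, 3e8, 4e8, 4e8], L=[1] * 4, W=[0.5] * 4,
            DOC=[50.0, 49.9, 49.8, 49.7],  # change below ~1 uM resolution
        )
        res = bge(s, t_stationary=1.2)
        assert not res.resolvable
        assert res.bge_percent is None

    def test_trapezoid_matches_fine_riemann(self):
        # BC production is piecewise linear between samples, so the
        # trapezoid rule must agree with a dense Riemann sum on it
        t = np.linspace(0, 2, 9)
        prod = np.interp(t, [0, 2], [0, 4])
        dense_t = np.linspace(0, 2, 200_001)
        dense = np.interp(dense_t, t, prod)
        riemann = np.sum((dense[1:] + dense[:-1]) / 2 * np.diff(dense_t))
        assert np.trapezoid(prod, t) == pytest.approx(riemann, abs=1e-9)


class TestTDAAYield:
    @pytest.mark.parametrize(
        "tdaa, doc, expected", [(3.98, 6.2, 64), (1.11, 4.1, 27), (5.0, 5.0, 100)]
    )
    def test_table_values(self, tdaa, doc, expected):
        assert tdaa_yield(tdaa, doc) == expected

    def test_expected_doc_back_calculation(self):
        assert expected_doc_from_yield(3.85, 0.64) == pytest.approx(6.0, abs=0.05)
        assert expected_doc_from_yield(1.11, 0.27) == pytest.approx(4.1, abs=0.05)
        assert expected_doc_from_yield(2.5, 1.0) == 2.5

    def test_mutual_inverses_up_to_rounding(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            doc = rng.uniform(1, 10)
            tdaa = doc * rng.uniform(0.05, 1.0)
            y = tdaa_yield(tdaa, doc)
            assert tdaa_yield(tdaa, expected_doc_from_yield(tdaa, y / 100)) == y

    def test_round_half_up(self):
        assert round_half_up(0.5) == 1
        assert round_half_up(22.857) == 23
        assert round_half_up(13.2) == 13

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            tdaa_yield(1.0, 0.0)
        with pytest.raises(ValueError):
            expected_doc_from_yield(1.0, 0.0)


def test_summarize_treatment_end_to_end():
    t = np.linspace(0, 3, 10)
    ba = _logistic(t, 1.5e9, 1e8, 2.0)
    doc = 52 - 5 * (ba - ba[0]) / (1.5e9 - 1e8)
    tdaa = 3.0 - 2.5 * (ba - ba[0]) / (1.5e9 - 1e8)
    s = _series(t, ba, L=[1.2] * 10, W=[0.6] * 10, DOC=doc, TDAA=tdaa, tid="amended")
    summary = summarize_treatment(s, amended_doc=5.0, amended_tdaa_c=3.0)
    assert summary.logistic_converged
    assert summary.t_stationary == pytest.approx(2 * summary.t_mid)
    assert summary.mu > 0
    assert summary.bge_pct is not None and 0 < summary.bge_pct <= 100
    assert summary.tdaa_yield_pct == 60
    assert summary.doc_removal_pct == pytest.approx(100 * 5 / 5, rel=0.05)
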