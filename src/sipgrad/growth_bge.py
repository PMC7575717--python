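"""Growth, bacterial carbon, and growth-efficiency calculations.

Cell biovolume treats cells as cylinders with hemispherical ends when
elongated (L/W >= 1.5) and as spheres otherwise:

    V = pi (L - W) W^2 / 4 + pi W^3 / 6      (elongated)
    V = pi W^3 / 6                           (coccoid)

Bacterial carbon converts abundance and biovolume with a carbon conversion
factor of 148 fg C um^-3.  The specific growth rate is the least-squares
slope of ln(BA) against time over the exponential window.  Stationary time
is defined as twice the logistic midpoint t_mid, the time when abundance
reaches half the fitted carrying capacity.  Bacterial growth efficiency is
the ratio of the time-normalized trapezoidal integral of bacterial-carbon
production to that of DOC removal from T0 to the stationary time:

    BGE = int BC dt / int DOC_removed dt × 100%

DOC removal below the analytical resolution (~1 umol C L^-1) leaves BGE
not resolvable rather than reporting a meaningless ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .tables_io import GrowthSeries, TablesIOError

__all__ = [
    "CARBON_CONVERSION_FACTOR",
    "CARBON_MOLAR_MASS",
    "DOC_RESOLUTION",
    "biovolume",
    "bacterial_carbon",
    "GrowthRateFit",
    "specific_growth_rate",
    "LogisticFit",
    "stationary_time",
    "BGEResult",
    "bge",
    "bge_percent",
    "tdaa_yield",
    "expected_doc_from_yield",
    "round_half_up",
    "TreatmentGrowthSummary",
    "summarize_treatment",
]

CARBON_CONVERSION_FACTOR = 148.0  # fg C per um^3
CARBON_MOLAR_MASS = 12.011  # g mol^-1
DOC_RESOLUTION = 1.0  # umol C L^-1, analytical detection of DOC change
CYLINDER_ASPECT = 1.5  # L/W at or above which the cell is treated as a rod


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def biovolume(L: float, W: float, aspect_threshold: float = CYLINDER_ASPECT) -> float:
    """Cell biovolume (um^3) from major (L) and minor (W) axes (um).

    L/W exactly at the aspect threshold takes the cylinder branch (the two
    formulas are discontinuous there, so a convention is required).
    """
    if W <= 0 or L <= 0:
        raise ValueError("cell dimensions must be positive")
    if L < W:
        raise ValueError("major axis L must be >= minor axis W")
    if L / W >= aspect_threshold:
        return math.pi * (L - W) * W**2 / 4 + math.pi * W**3 / 6
    return math.pi * W**3 / 6


def bacterial_carbon(
    BA: float, V: float, ccf: float = CARBON_CONVERSION_FACTOR
) -> float:
    """Bacterial carbon (umol C L^-1) from abundance (cells L^-1) and
    biovolume (um^3 per cell)."""
    if BA < 0:
        raise ValueError("BA must be >= 0")
    if V <= 0:
        raise ValueError("biovolume must be positive")
    fg_per_liter = BA * V * ccf
    # fg -> g (1e-15), / molar mass, mol -> umol (1e6)
    return fg_per_liter * 1e-15 / CARBON_MOLAR_MASS * 1e6


@dataclass
class GrowthRateFit:
    mu: float  # d^-1
    window: tuple[float, float]  # [t_start, t_end] days
    r_squared: float
    n_points: int


def specific_growth_rate(
    series: GrowthSeries, window: tuple[float, float] | None = None
) -> GrowthRateFit:
    """Specific growth rate: slope of ln(BA) vs time over the exponential
    window.

    When ``window`` is None the contiguous window of >= 3 points with the
    highest R^2 (preferring positive slope, then more points on ties) is
    selected automatically.
    """
    ok = np.isfinite(series.BA) & (series.BA > 0)
    t = series.times[ok]
    ln_ba = np.log(series.BA[ok])
    if window is not None:
        t0, t1 = window
        mask = (t >= t0) & (t <= t1)
        if mask.sum() < 3:
            raise TablesIOError("fewer than 3 positive-BA points in window")
        res = linregress(t[mask], ln_ba[mask])
        return GrowthRateFit(
            mu=float(res.slope),
            window=(float(t[mask][0]), float(t[mask][-1])),
            r_squared=float(res.rvalue**2),
            n_points=int(mask.sum()),
        )
    n = t.size
    if n < 3:
        raise TablesIOError("fewer than 3 positive-BA points")
    best: GrowthRateFit | None = None
    best_key: tuple[float, float, int] | None = None
    for i in range(n - 2):
        for j in range(i + 3, n + 1):
            res = linregress(t[i:j], ln_ba[i:j])
            r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
            key = (1.0 if res.slope > 0 else 0.0, r2, j - i)
            if best_key is None or key > best_key:
                best_key = key
                best = GrowthRateFit(
                    mu=float(res.slope),
                    window=(float(t[i]), float(t[j - 1])),
                    r_squared=r2,
                    n_points=j - i,
                )
    assert best is not None
    return best


@dataclass
class LogisticFit:
    """Logistic growth fit N(t) = K / (1 + ((K - N0)/N0) e^{-r t}).

    ``converged`` is False when no biologically sensible logistic could be
    fit (e.g. declining series); t_mid/t_stationary are NaN in that case
    rather than raising, mirroring a "no fit" report.
    """

    converged: bool
    K: float = float("nan")
    N0: float = float("nan")
    r: float = float("nan")
    t_mid: float = float("nan")
    t_stationary: float = float("nan")

    @property
    def no_fit(self) -> bool:
        return not self.converged


def _logistic(t: np.ndarray, K: float, N0: float, r: float) -> np.ndarray:
    return K / (1 + ((K - N0) / N0) * np.exp(-r * t))


def stationary_time(series: GrowthSeries) -> LogisticFit:
    """Fit a logistic growth model to BA(t) and report the stationary time
    2·t_mid, where N(t_mid) = K/2."""
    ok = np.isfinite(series.BA) & (series.BA > 0)
    t = series.times[ok]
    ba = series.BA[ok]
    if t.size < 4:
        return LogisticFit(converged=False)
    k0 = float(ba.max()) * 1.05
    n0 = float(ba[0])
    # crude initial rate from endpoint log ratio
    dt = float(t[-1] - t[0])
    r0 = max(np.log(max(ba[-1] / ba[0], 1.01)) / max(dt, 1e-6), 0.1)
    try:
        popt, _ = curve_fit(
            _logistic,
            t,
            ba,
            p0=[k0, n0, r0],
            bounds=([1e-12, 1e-12, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError):
        return LogisticFit(converged=False)
    K, N0, r = (float(v) for v in popt)
    if not (K > N0 > 0) or r <= 0:
        return LogisticFit(converged=False)
    t_mid = math.log((K - N0) / N0) / r
    if not np.isfinite(t_mid) or t_mid <= 0:
        return LogisticFit(converged=False)
    return LogisticFit(
        converged=True, K=K, N0=N0, r=r, t_mid=t_mid, t_stationary=2 * t_mid
    )


def _interp_series(
    times: np.ndarray, values: np.ndarray, t_end: float
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a series to [t0, t_end], linearly interpolating the value
    at t_end when it is not a sampled timepoint."""
    ok = np.isfinite(values)
    t = times[ok]
    v = values[ok]
    if t.size < 2:
        raise TablesIOError("need >= 2 finite points to integrate")
    t_end = min(t_end, float(t[-1]))
    keep = t < t_end
    tt = np.append(t[keep], t_end)
    vv = np.append(v[keep], np.interp(t_end, t, v))
    return tt, vv


@dataclass
class BGEResult:
    bge_percent: int | None  # None when DOC change is not resolvable
    int_bc: float  # umol C L^-1, time-normalized
    int_doc: float | None
    resolvable: bool


def bge_percent(int_bc: float, int_doc: float) -> int:
    """BGE (%) from time-normalized integrals, rounded half-up."""
    if int_doc <= 0:
        raise ValueError("int_DOC must be positive")
    return round_half_up(100.0 * int_bc / int_doc)


def bge(
    series: GrowthSeries,
    t_stationary: float,
    doc_resolution: float = DOC_RESOLUTION,
) -> BGEResult:
    """Bacterial growth efficiency over [T0, t_stationary].

    The numerator is the trapezoidal integral of bacterial-carbon
    production (BC_t - BC_T0, clipped at 0); the denominator is that of
    DOC removal (DOC_T0 - DOC_t, clipped at 0); both are divided by the
    elapsed time.  When the total DOC change stays below the analytical
    resolution the result is flagged not resolvable.
    """
    ok = np.isfinite(series.BA) & np.isfinite(series.cell_L) & np.isfinite(series.cell_W)
    bc = np.full_like(series.times, np.nan)
    for i in np.flatnonzero(ok):
        bc[i] = bacterial_carbon(
            series.BA[i], biovolume(series.cell_L[i], series.cell_W[i])
        )
    t_bc, v_bc = _interp_series(series.times, bc, t_stationary)
    prod = np.clip(v_bc - v_bc[0], 0.0, None)
    span = t_bc[-1] - t_bc[0]
    if span <= 0:
        raise TablesIOError("degenerate integration window")
    int_bc = float(np.trapezoid(prod, t_bc) / span)

    t_doc, v_doc = _interp_series(series.times, series.DOC, t_stationary)
    removal = np.clip(v_doc[0] - v_doc, 0.0, None)
    if removal.max() < doc_resolution:
        return BGEResult(
            bge_percent=None, int_bc=int_bc, int_doc=None, resolvable=False
        )
    span_doc = t_doc[-1] - t_doc[0]
    int_doc = float(np.trapezoid(removal, t_doc) / span_doc)
    if int_doc <= 0:
        return BGEResult(
            bge_percent=None, int_bc=int_bc, int_doc=None, resolvable=False
        )
    return BGEResult(
        bge_percent=bge_percent(int_bc, int_doc),
        int_bc=int_bc,
        int_doc=int_doc,
        resolvable=True,
    )


def tdaa_yield(tdaa_c: float, doc: float) -> int:
    """TDAA-C as a percent of DOC, rounded half-up to an integer."""
    if doc <= 0:
        raise ValueError("DOC must be positive")
    return round_half_up(100.0 * tdaa_c / doc)


def expected_doc_from_yield(tdaa_c: float, yield_fraction: float) -> float:
    """Back-calculate DOC (umol C L^-1) from TDAA-C and a known TDAA-C
    yield fraction (0 < yield <= 1)."""
    if not 0 < yield_fraction <= 1:
        raise ValueError("yield_fraction must be in (0, 1]")
    return tdaa_c / yield_fraction


@dataclass
class TreatmentGrowthSummary:
    treatment_id: str
    mu: float
    exp_window: tuple[float, float]
    t_mid: float
    t_stationary: float
    int_bc: float
    int_doc: float | None
    bge_pct: int | None
    tdaa_yield_pct: int | None
    tdaa_removal_pct: float | None
    doc_removal_pct: float | None
    logistic_converged: bool


def summarize_treatment(
    series: GrowthSeries,
    amended_doc: float | None = None,
    amended_tdaa_c: float | None = None,
    doc_resolution: float = DOC_RESOLUTION,
) -> TreatmentGrowthSummary:
    """Compute the full growth/BGE summary for one treatment.

    Removal percentages are reported relative to the amended substrate
    concentrations when those are supplied, otherwise left None.
    """
    rate = specific_growth_rate(series)
    fit = stationary_time(series)
    if fit.converged:
        result = bge(series, fit.t_stationary, doc_resolution)
    else:
        result = BGEResult(
            bge_percent=None, int_bc=float("nan"), int_doc=None, resolvable=False
        )

    def _removal(values: np.ndarray, amended: float | None) -> float | None:
        if amended is None or amended <= 0:
            return None
        finite = values[np.isfinite(values)]
        if finite.size < 2:
            return None
        return float(100.0 * (finite[0] - finite[-1]) / amended)

    yield_pct = None
    if amended_doc and amended_tdaa_c:
        yield_pct = tdaa_yield(amended_tdaa_c, amended_doc)
    return TreatmentGrowthSummary(
        treatment_id=series.treatment_id,
        mu=rate.mu,
        exp_window=rate.window,
        t_mid=fit.t_mid,
        t_stationary=fit.t_stationary,
        int_bc=result.int_bc,
        int_doc=result.int_doc,
        bge_pct=result.bge_percent,
        tdaa_yield_pct=yield_pct,
        tdaa_removal_pct=_removal(series.TDAA_C, amended_tdaa_c),
        doc_removal_pct=_removal(series.DOC, amended_doc),
        logistic_converged=fit.converged,
    )
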