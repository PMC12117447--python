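"""Formulation analytics: CAC breakpoint, calibration, EE%, release curves.

The CAC estimator mirrors the graphical-intersection construction used for
scattered-light count-rate data: in log10-log10 space the response is a
horizontal plateau below the critical aggregation concentration and a
straight line with positive slope above it. The continuous two-segment
model is fitted by exhaustive search over a deterministic breakpoint grid
(interior observed concentrations and adjacent log-midpoints) with
closed-form least squares at each candidate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    MalformedInputError,
    MassBalanceError,
    NoAggregationError,
    ParameterError,
)
from .io import ConcentrationSeries


@dataclass
class CACResult:
    """Two-segment breakpoint fit of a concentration series."""

    cac: float  # molar
    pre_level: float  # log10 response plateau
    post_slope: float  # log-log slope above the CAC
    residual_sum: float  # SSE in log10 space
    n_pre: int
    n_post: int
    at_edge: bool = False  # breakpoint at the search-range edge (unreliable)

    def to_dict(self) -> dict:
        return {
            "cac_M": self.cac,
            "pre_level_log10": self.pre_level,
            "post_slope": self.post_slope,
            "residual_sum": self.residual_sum,
            "n_pre": self.n_pre,
            "n_post": self.n_post,
            "at_edge": self.at_edge,
        }


def _segment_sse(x: np.ndarray, y: np.ndarray, xb: float):
    """LS fit of {y = b (x<=xb); y = b + m (x-xb) (x>xb)} -> (sse, b, m)."""
    left = x <= xb
    n_l = int(left.sum())
    n_r = x.size - n_l
    if n_l < 2 or n_r < 2:
        return None
    xr = x[~left] - xb
    # normal equations for (b, m): minimize |y_l - b|^2 + |y_r - b - m xr|^2
    n = x.size
    sx = xr.sum()
    sxx = (xr * xr).sum()
    sy = y.sum()
    sxy = (xr * y[~left]).sum()
    det = n * sxx - sx * sx
    if det <= 0:
        return None
    b = (sxx * sy - sx * sxy) / det
    m = (n * sxy - sx * sy) / det
    resid = np.concatenate([y[left] - b, y[~left] - b - m * xr])
    return float(resid @ resid), float(b), float(m)


def fit_cac(series: ConcentrationSeries) -> CACResult:
    """Estimate the critical aggregation concentration of a dilution series.

    Requires >= 6 distinct concentrations spanning >= 1.5 decades. Raises
    :class:`NoAggregationError` when no breakpoint with a positive
    post-slope exists (flat series).
    """
    conc = series.concentration
    resp = series.response
    # collapse replicates to means per distinct concentration
    uconc, inv = np.unique(conc, return_inverse=True)
    uresp = np.zeros_like(uconc)
    for i in range(uconc.size):
        uresp[i] = resp[inv == i].mean()
    if uconc.size < 6:
        raise MalformedInputError("need >= 6 distinct concentrations")
    span = math.log10(uconc[-1] / uconc[0])
    if span < 1.5:
        raise MalformedInputError(
            f"concentration range spans {span:.2f} decades (need >= 1.5)"
        )
    if np.any(uresp <= 0):
        raise MalformedInputError("responses must be positive for log-log fitting")

    x = np.log10(uconc)
    y = np.log10(uresp)

    # deterministic breakpoint grid: interior sample points + adjacent midpoints
    mids = 0.5 * (x[:-1] + x[1:])
    grid = np.unique(np.concatenate([x[1:-1], mids]))

    best = None
    for xb in grid:
        res = _segment_sse(x, y, xb)
        if res is None:
            continue
        sse, b, m = res
        if best is None or sse < best[0] - 1e-15:
            best = (sse, b, m, xb)
    if best is None:
        raise MalformedInputError("not enough points on each side of any breakpoint")
    sse, b, m, xb = best
    if m <= 0:
        raise NoAggregationError(
            "best post-breakpoint slope is non-positive: series shows no aggregation"
        )
    at_edge = bool(xb <= grid[0] or xb >= grid[-1])
    if at_edge:
        warnings.warn("CAC breakpoint at edge of searched range; estimate unreliable")
    n_pre = int((x <= xb).sum())
    return CACResult(
        cac=float(10.0 ** xb),
        pre_level=b,
        post_slope=m,
        residual_sum=sse,
        n_pre=n_pre,
        n_post=int(x.size - n_pre),
        at_edge=at_edge,
    )


@dataclass
class CalibrationCurve:
    """Ordinary least-squares line: response = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    conc_range: tuple  # (min, max) of fitted standards
    response_range: tuple

    def __post_init__(self):
        if self.slope <= 0:
            raise ParameterError(f"calibration slope must be positive, got {self.slope}")

    def invert(self, response: float):
        """Concentration for a response; returns (concentration, extrapolated)."""
        conc = (response - self.intercept) / self.slope
        lo, hi = self.response_range
        return conc, bool(response < lo or response > hi)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "conc_range": list(self.conc_range),
            "response_range": list(self.response_range),
        }


def fit_calibration(concentration: Sequence[float], response: Sequence[float]) -> CalibrationCurve:
    """Fit a linear calibration curve by OLS."""
    c = np.asarray(concentration, dtype=float)
    r = np.asarray(response, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise MalformedInputError("concentration and response must be equal-length 1D")
    if c.size < 4:
        raise MalformedInputError("need >= 4 standards")
    if np.unique(c).size < 3:
        raise MalformedInputError("need >= 3 distinct concentrations")
    A = np.column_stack([c, np.ones_like(c)])
    coef, res_ss, rank, _ = np.linalg.lstsq(A, r, rcond=None)
    if rank < 2:
        raise MalformedInputError("singular calibration design")
    slope, intercept = float(coef[0]), float(coef[1])
    fitted = A @ coef
    resid = r - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((r - r.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = max(c.size - 2, 1)
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        residual_sd=math.sqrt(ss_res / dof),
        conc_range=(float(c.min()), float(c.max())),
        response_range=(float(fitted.min()), float(fitted.max())),
    )


@dataclass
class EEResult:
    ee_percent: float
    sd_percent: Optional[float] = None
    n_replicates: int = 1

    def to_dict(self) -> dict:
        return {
            "ee_percent": self.ee_percent,
            "sd_percent": self.sd_percent,
            "n_replicates": self.n_replicates,
        }


def encapsulation_efficiency(measured, total: float, tolerance_sd: float = 2.0) -> EEResult:
    """EE% = 100 * measured / total, with replicate SD propagation.

    ``measured`` may be a scalar or a sequence of replicate measurements
    (same units as ``total``). Raises when measured exceeds total by more
    than ``tolerance_sd`` replicate standard deviations.
    """
    if total <= 0:
        raise ParameterError(f"total drug must be positive, got {total}")
    arr = np.atleast_1d(np.asarray(measured, dtype=float))
    if np.any(arr < 0):
        raise ParameterError("measured drug must be non-negative")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    if mean > total + tolerance_sd * sd:
        raise MassBalanceError(
            f"measured drug ({mean:g}) exceeds total ({total:g}) beyond uncertainty"
        )
    ee = 100.0 * mean / total
    return EEResult(
        ee_percent=ee,
        sd_percent=(100.0 * sd / total) if arr.size > 1 else None,
        n_replicates=int(arr.size),
    )


@dataclass
class ReleaseCurve:
    """Cumulative release fractions corrected for sampling with replacement."""

    timepoints: np.ndarray  # hours
    fraction_percent: np.ndarray
    sd_percent: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        out = {
            "time_h": self.timepoints.tolist(),
            "cumulative_percent": self.fraction_percent.tolist(),
        }
        if self.sd_percent is not None:
            out["sd_percent"] = self.sd_percent.tolist()
        return out


def cumulative_release(
    times: Sequence[float],
    concentrations,
    medium_volume: float,
    aliquot_volume: float,
    total_loaded: float,
    tolerance: float = 1.0,
) -> ReleaseCurve:
    """Cumulative released fraction from aliquot concentrations.

    Corrects for analyte withdrawn and replaced with fresh medium:
    mass_n = C_n * V_medium + sum_{i<n} C_i * V_aliquot.

    ``concentrations`` may be 1D (single run) or 2D (replicates x time);
    replicate SD is then propagated per timepoint. ``tolerance`` is the
    allowed overshoot above 100% before a mass-balance error is raised.
    """
    t = np.asarray(times, dtype=float)
    C = np.asarray(concentrations, dtype=float)
    if C.ndim == 1:
        C = C[None, :]
    if t.ndim != 1 or C.shape[1] != t.size:
        raise MalformedInputError("times and concentrations shapes disagree")
    if np.any(np.diff(t) <= 0):
        raise MalformedInputError("times must be strictly increasing")
    if medium_volume <= 0 or aliquot_volume <= 0:
        raise ParameterError("volumes must be positive")
    if aliquot_volume >= medium_volume:
        raise ParameterError("aliquot volume must be smaller than medium volume")
    if total_loaded <= 0:
        raise ParameterError("total loaded mass must be positive")
    if np.any(C < 0):
        raise ParameterError("concentrations must be non-negative")

    withdrawn = np.concatenate(
        [np.zeros((C.shape[0], 1)), np.cumsum(C[:, :-1] * aliquot_volume, axis=1)],
        axis=1,
    )
    mass = C * medium_volume + withdrawn
    frac = 100.0 * mass / total_loaded
    mean_frac = frac.mean(axis=0)
    if np.any(mean_frac > 100.0 + tolerance):
        raise MassBalanceError(
            f"cumulative release reaches {mean_frac.max():.2f}% (> 100% + tolerance)"
        )
    sd = frac.std(axis=0, ddof=1) if C.shape[0] > 1 else None
    return ReleaseCurve(timepoints=t, fraction_percent=mean_frac, sd_percent=sd)
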