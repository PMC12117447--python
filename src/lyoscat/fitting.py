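"""Constrained least-squares fitting of the composite scattering model.

Positivity and the piecewise-continuity constraints are enforced by
construction: scale and length parameters are optimized in log space, the
cylinder term's second radius is parameterized through the positive gap
v = (2/3) Rg2^2 - Rg1^2 - Rg1^2/(d-1) so that its crossovers stay real and
ordered, and all crossover scales are derived inside the forward model.
Optimization is trust-region reflective least squares (scipy) with
multistart jitter; the best start wins and runs are bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage, signal
from scipy.optimize import least_squares

from .exceptions import FitError, MalformedInputError, ParameterError
from .forward import (
    CompositeModel,
    CylinderGuinierPorod,
    GuinierPorodLevel,
    LorentzianPeak,
)
from .io import ScatteringCurve

_LOG_LO, _LOG_HI = -60.0, 60.0  # generic bounds for log-scale parameters
_D_BOUNDS = (1.5, 4.0)  # Porod exponent bounds when free


@dataclass
class PeakCandidate:
    """A detected peak: position, prominence (intensity units), HWHM guess."""

    q_position: float
    prominence: float
    width: float  # nm^-1, half width at half maximum estimate

    def __post_init__(self):
        if self.prominence <= 0:
            raise ParameterError("prominence must be positive")


def detect_peaks(
    curve: ScatteringCurve,
    min_prominence_rel: float = 0.03,
    smooth_window: Optional[int] = None,
) -> List[PeakCandidate]:
    """Find Bragg-peak candidates on a background-detrended curve.

    The local baseline is a morphological opening (running minimum then
    maximum) of the log-intensity, which is the identity on the smooth
    monotone continuum and clips peaks narrower than the window (default:
    a quarter of the curve length). A candidate must rise by a factor of
    at least ``1 + min_prominence_rel`` above that baseline. Deterministic
    for fixed options; an empty list is a valid result.
    """
    if len(curve) < 32:
        raise MalformedInputError("need >= 32 points for peak detection")
    y = np.log(np.maximum(curve.intensity, 1e-300))
    n = y.size
    if smooth_window is None:
        smooth_window = max(11, (n // 4) | 1)
    if smooth_window % 2 == 0:
        smooth_window += 1
    baseline = ndimage.grey_opening(y, size=min(smooth_window, n), mode="nearest")
    detrended = y - baseline
    if n >= 9:  # light smoothing so shot noise does not fake candidates
        detrended = signal.savgol_filter(detrended, 9, 2)
    prom = math.log1p(min_prominence_rel)
    idx, props = signal.find_peaks(detrended, prominence=prom)
    if idx.size == 0:
        return []
    widths, _, _, _ = signal.peak_widths(detrended, idx, rel_height=0.5)
    dq = float(np.median(np.diff(curve.q)))
    out = []
    for i, w, p in zip(idx, widths, props["prominences"]):
        height = curve.intensity[i]
        out.append(
            PeakCandidate(
                q_position=float(curve.q[i]),
                prominence=float(height * (1.0 - math.exp(-p))),
                width=float(max(w * dq / 2.0, dq)),
            )
        )
    out.sort(key=lambda c: c.q_position)
    return out


def _guinier_rg(q: np.ndarray, I: np.ndarray) -> tuple:
    """Slope fit of ln I vs q^2 -> (Rg, G) or (None, None) if slope >= 0."""
    x = q * q
    y = np.log(np.maximum(I, 1e-300))
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = coef
    if slope >= 0:
        return None, None
    return math.sqrt(-3.0 * slope), math.exp(intercept)


def initialize_model(
    curve: ScatteringCurve,
    candidates: Optional[List[PeakCandidate]] = None,
    d: float = 4.0,
) -> CompositeModel:
    """Data-driven starting model for :func:`fit_composite`.

    Rg comes from a Guinier fit on the lowest-q decade, refined once to
    the region q*Rg < 1.3; a non-negative low-q slope triggers a warning
    and the fallback Rg = 2 pi / q_min. The cylinder is seeded at
    Rg2 = Rg/3, Rg1 = 1 nm; peaks come from the supplied candidates; the
    background is the 5th percentile of the highest-q decade.
    """
    q, I = curve.q, curve.intensity
    Imax = float(I.max())
    if Imax <= 0:
        raise MalformedInputError("curve has no positive intensity")

    low = q <= min(10.0 * q[0], q[-1])
    Rg, G = _guinier_rg(q[low], I[low])
    if Rg is None:
        warnings.warn("low-q Guinier fit has non-negative slope; seeding Rg = 2pi/q_min")
        Rg = 2.0 * math.pi / q[0]
        G = Imax
    else:
        for _ in range(3):  # refine to the actual Guinier window
            win = q * Rg < 1.3
            if win.sum() < 5:
                break
            Rg2_, G2_ = _guinier_rg(q[win], I[win])
            if Rg2_ is None:
                break
            Rg, G = Rg2_, G2_

    hi = q >= q[-1] / 10.0 ** 0.5  # top half-decade
    background = float(np.percentile(I[hi], 5))
    background = max(background, 1e-10 * Imax)

    Rg1 = 1.0
    Rg2 = max(Rg / 3.0, 1.5 * Rg1)
    # rod-regime scale from intensity where the cylinder term should dominate
    first_peak_q = candidates[0].q_position if candidates else q[-1]
    q_star = min(0.5 * first_peak_q, q[-1])
    i_star = int(np.searchsorted(q, q_star))
    i_star = min(max(i_star, 0), q.size - 1)
    G1 = max((I[i_star] - background) * q[i_star], 1e-8 * Imax)

    peaks = []
    for c in candidates or []:
        sigma = c.width
        peaks.append(
            LorentzianPeak(k=c.prominence * math.pi * sigma, sigma=sigma, q_max=c.q_position)
        )

    return CompositeModel(
        level1=GuinierPorodLevel(G=max(G, 1e-8 * Imax), Rg=Rg, d=d),
        cylinder=CylinderGuinierPorod(G1=G1, Rg1=Rg1, Rg2=Rg2, d=d),
        peaks=peaks,
        background=background,
    )


@dataclass
class FitOptions:
    fix_d: bool = True
    share_d: bool = True
    weight_mode: str = "auto"  # 'auto' | 'uncertainty' | 'poisson'
    max_peaks: int = 3
    multistart: int = 8
    seed: int = 0
    jitter: float = 0.1
    max_nfev: Optional[int] = None
    eps_rel: float = 1e-12  # floor for Poisson-like weights, relative to max I


class _Packer:
    """Bijective map between a CompositeModel and the optimizer vector."""

    def __init__(self, template: CompositeModel, opts: FitOptions):
        self.has_level1 = template.level1 is not None
        self.has_cyl = template.cylinder is not None
        self.n_peaks = len(template.peaks)
        self.fix_d = opts.fix_d
        self.share_d = opts.share_d
        self.d_fixed = template.level1.d if self.has_level1 else (
            template.cylinder.d if self.has_cyl else 4.0
        )
        self.names: List[str] = []
        if self.has_level1:
            self.names += ["log_G", "log_Rg"]
            if not self.fix_d:
                self.names += ["d"]
        if self.has_cyl:
            self.names += ["log_G1", "log_Rg1", "log_v"]
            if not self.fix_d and not self.share_d:
                self.names += ["d_cyl"]
        for i in range(self.n_peaks):
            self.names += [f"log_k{i}", f"log_sigma{i}", f"log_qmax{i}"]
        self.names += ["log_bg"]

    def pack(self, model: CompositeModel) -> np.ndarray:
        theta = []
        if self.has_level1:
            theta += [math.log(model.level1.G), math.log(model.level1.Rg)]
            if not self.fix_d:
                theta += [model.level1.d]
        if self.has_cyl:
            c = model.cylinder
            u = (2.0 / 3.0) * c.Rg2 ** 2 - c.Rg1 ** 2
            v = u - c.Rg1 ** 2 / (c.d - 1.0)
            if v <= 0:  # nudge inside the feasible region
                v = 0.1 * u
            theta += [math.log(c.G1), math.log(c.Rg1), math.log(v)]
            if not self.fix_d and not self.share_d:
                theta += [c.d]
        for p in model.peaks:
            theta += [math.log(p.k), math.log(p.sigma), math.log(p.q_max)]
        theta += [math.log(max(model.background, 1e-300))]
        return np.array(theta)

    def unpack(self, theta: np.ndarray) -> CompositeModel:
        it = iter(theta)
        level1 = cylinder = None
        d = self.d_fixed
        if self.has_level1:
            G = math.exp(next(it))
            Rg = math.exp(next(it))
            if not self.fix_d:
                d = next(it)
            level1 = GuinierPorodLevel(G=G, Rg=Rg, d=d)
        if self.has_cyl:
            G1 = math.exp(next(it))
            Rg1 = math.exp(next(it))
            v = math.exp(next(it))
            d_cyl = d
            if not self.fix_d and not self.share_d:
                d_cyl = next(it)
            u = v + Rg1 ** 2 / (d_cyl - 1.0)
            Rg2 = math.sqrt(1.5 * (Rg1 ** 2 + u))
            cylinder = CylinderGuinierPorod(G1=G1, Rg1=Rg1, Rg2=Rg2, d=d_cyl)
        peaks = []
        for _ in range(self.n_peaks):
            k = math.exp(next(it))
            sigma = math.exp(next(it))
            q_max = math.exp(next(it))
            peaks.append(LorentzianPeak(k=k, sigma=sigma, q_max=q_max))
        background = math.exp(next(it))
        return CompositeModel(
            level1=level1, cylinder=cylinder, peaks=peaks, background=background
        )

    def bounds(self, q_min: float, q_max: float):
        lo, hi = [], []
        for name in self.names:
            if name in ("d", "d_cyl"):
                lo.append(_D_BOUNDS[0])
                hi.append(_D_BOUNDS[1])
            elif name.startswith("log_qmax"):
                lo.append(math.log(q_min))
                hi.append(math.log(q_max))
            elif name.startswith("log_sigma"):
                lo.append(math.log(1e-4))
                hi.append(math.log(10.0 * (q_max - q_min)))
            elif name.startswith("log_Rg"):
                lo.append(math.log(1e-2))
                hi.append(math.log(1e4))
            else:
                lo.append(_LOG_LO)
                hi.append(_LOG_HI)
        return np.array(lo), np.array(hi)


@dataclass
class FitResult:
    """Fitted model plus diagnostics and reproducibility provenance."""

    model: CompositeModel
    uncertainties: dict  # physical-parameter standard errors
    redchi: float
    residuals: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.provenance.get("converged", False))


def _weights(curve: ScatteringCurve, opts: FitOptions) -> np.ndarray:
    mode = opts.weight_mode
    if mode == "auto":
        # a constant uncertainty column (e.g. the zero-noise floor) carries
        # no per-point information; fall back to Poisson-like weights
        informative = (
            curve.uncertainty is not None
            and np.ptp(curve.uncertainty) > 1e-9 * curve.uncertainty.max()
        )
        mode = "uncertainty" if informative else "poisson"
    if mode == "uncertainty":
        if curve.uncertainty is None:
            raise ParameterError("curve has no uncertainty column")
        return 1.0 / curve.uncertainty
    if mode == "poisson":
        eps = opts.eps_rel * float(curve.intensity.max())
        return 1.0 / np.maximum(curve.intensity, eps)
    raise ParameterError(f"unknown weight mode {opts.weight_mode!r}")


def fit_composite(
    curve: ScatteringCurve,
    init: CompositeModel,
    opts: Optional[FitOptions] = None,
) -> FitResult:
    """Weighted least-squares fit of the composite model to a curve.

    Returns the best of ``opts.multistart`` jittered starts (start 0 is
    the unperturbed initialization); deterministic for a fixed seed.
    Raises :class:`FitError` carrying the best attempt when no start
    converges.
    """
    opts = opts or FitOptions()
    if len(init.peaks) > opts.max_peaks:
        init = CompositeModel(
            level1=init.level1,
            cylinder=init.cylinder,
            peaks=sorted(init.peaks, key=lambda p: -p.k)[: opts.max_peaks],
            background=init.background,
        )
    packer = _Packer(init, opts)
    theta0 = packer.pack(init)
    n_free = theta0.size
    if len(curve) <= n_free:
        raise MalformedInputError(
            f"curve has {len(curve)} points but the model has {n_free} free parameters"
        )
    w = _weights(curve, opts)
    lo, hi = packer.bounds(curve.q[0], curve.q[-1])
    theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)

    def resid(theta):
        try:
            model = packer.unpack(theta)
            return (model(curve.q) - curve.intensity) * w
        except ParameterError:
            return np.full(len(curve), 1e12)

    rng = np.random.default_rng(opts.seed)
    best = None
    total_nfev = 0
    for start in range(max(opts.multistart, 1)):
        theta_s = theta0.copy()
        if start > 0:
            theta_s = np.clip(
                theta0 + opts.jitter * rng.standard_normal(n_free),
                lo + 1e-9,
                hi - 1e-9,
            )
        try:
            res = least_squares(
                resid,
                theta_s,
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                max_nfev=opts.max_nfev,
            )
        except Exception:  # singular jacobians on absurd jitters: skip start
            continue
        total_nfev += res.nfev
        if best is None or res.cost < best.cost:
            best = res
            best_start = start
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("no optimizer start converged", best_result=best)

    model = packer.unpack(best.x)
    r = best.fun
    dof = max(len(curve) - n_free, 1)
    redchi = float(r @ r) / dof

    # standard errors: s^2 (J^T J)^-1, delta method back to physical scale
    try:
        JTJ = best.jac.T @ best.jac
        cov = np.linalg.pinv(JTJ) * (float(r @ r) / dof)
        se_theta = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except Exception:
        se_theta = np.full(n_free, np.nan)
    uncertainties = {}
    flat = model.to_dict()
    phys_names = _physical_names(packer)
    for name, th, se in zip(packer.names, best.x, se_theta):
        pname = phys_names[name]
        if name.startswith("log_"):
            uncertainties[pname] = float(math.exp(th) * se)
        else:
            uncertainties[pname] = float(se)

    at_bound = [
        packer.names[i]
        for i in range(n_free)
        if best.x[i] - lo[i] < 1e-6 or hi[i] - best.x[i] < 1e-6
    ]
    warns = []
    if at_bound:
        warns.append(f"parameters at bounds: {', '.join(at_bound)}")
        warnings.warn(warns[-1])

    provenance = {
        "initialization": {n: float(v) for n, v in zip(packer.names, theta0)},
        "n_starts": int(max(opts.multistart, 1)),
        "best_start": int(best_start),
        "nfev": int(total_nfev),
        "converged": bool(best.status > 0),
        "seed": opts.seed,
        "weight_mode": opts.weight_mode,
        "fix_d": opts.fix_d,
        "cost": float(best.cost),
        "warnings": warns,
        "parameters": {k: float(v) for k, v in flat.items()},
    }
    return FitResult(
        model=model,
        uncertainties=uncertainties,
        redchi=redchi,
        residuals=r,
        provenance=provenance,
    )


def _physical_names(packer: _Packer) -> dict:
    out = {}
    for name in packer.names:
        if name == "log_G":
            out[name] = "g1.G"
        elif name == "log_Rg":
            out[name] = "g1.Rg"
        elif name == "d":
            out[name] = "g1.d"
        elif name == "log_G1":
            out[name] = "cyl.G1"
        elif name == "log_Rg1":
            out[name] = "cyl.Rg1"
        elif name == "log_v":
            out[name] = "cyl.Rg2_gap"
        elif name == "d_cyl":
            out[name] = "cyl.d"
        elif name == "log_bg":
            out[name] = "background"
        elif name.startswith("log_k"):
            out[name] = f"peak[{name[5:]}].k"
        elif name.startswith("log_sigma"):
            out[name] = f"peak[{name[9:]}].sigma"
        elif name.startswith("log_qmax"):
            out[name] = f"peak[{name[8:]}].qmax"
    return out


def fit_curve(
    curve: ScatteringCurve,
    opts: Optional[FitOptions] = None,
    min_prominence_rel: float = 0.03,
) -> FitResult:
    """Full pipeline: detect peaks, initialize, fit."""
    opts = opts or FitOptions()
    candidates = detect_peaks(curve, min_prominence_rel=min_prominence_rel)
    if len(candidates) > opts.max_peaks:
        candidates = sorted(candidates, key=lambda c: -c.prominence)[: opts.max_peaks]
        candidates.sort(key=lambda c: c.q_position)
    init = initialize_model(curve, candidates)
    return fit_composite(curve, init, opts)
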