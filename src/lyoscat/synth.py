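"""Synthetic data generators for every pipeline input.

All generators are pure functions of (parameters, seed). The three model
presets encode the fitted hexosome systems (unloaded, LEF-loaded and
LEF-glucoside-loaded): cylinder radii of gyration are back-computed from
the target cross-section radius Rc and length L via Rg1 = Rc/sqrt(2) and
Rg2 = sqrt((L^2 + 6 Rc^2)/12), peak positions from the target hexagonal
lattice constants via q = 4 pi / (sqrt(3) a), and peak widths from the
target correlation lengths via sigma = 2 pi / l_c. Scale factors (G, G1,
peak weights, background) are not pinned by the targets and are chosen to
give a first-peak-to-background contrast of about 10.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .exceptions import ParameterError, SamplingError
from .forward import (
    CompositeModel,
    CylinderGuinierPorod,
    GuinierPorodLevel,
    LorentzianPeak,
    eval_composite,
)
from .images import CalibratedImage
from .io import ConcentrationSeries, CurveMeta, ScatteringCurve

#: Instrument q range (nm^-1) used as the default synthetic grid.
DEFAULT_Q_MIN = 0.074
DEFAULT_Q_MAX = 1.70

_SQRT3 = math.sqrt(3.0)


def _hex_q(a: float) -> float:
    """q of the (100) reflection for hexagonal lattice constant a."""
    return 4.0 * math.pi / (_SQRT3 * a)


def _cyl_from_rc_l(G1: float, Rc: float, L: float, d: float = 4.0) -> CylinderGuinierPorod:
    Rg1 = Rc / math.sqrt(2.0)
    Rg2 = math.sqrt((L * L + 6.0 * Rc * Rc) / 12.0)
    return CylinderGuinierPorod(G1=G1, Rg1=Rg1, Rg2=Rg2, d=d)


def _peak(a_hex: float, l_c: float, height_over_bg: float, background: float) -> LorentzianPeak:
    sigma = 2.0 * math.pi / l_c
    # Lorentzian peak height = k / (pi sigma)
    k = height_over_bg * background * math.pi * sigma
    return LorentzianPeak(k=k, sigma=sigma, q_max=_hex_q(a_hex))


_PRESET_TARGETS = {
    # name: Rg, Rc, L, lattice constants a (nm), correlation length l_c (nm)
    "unloaded": {"Rg": 20.0, "Rc": 1.27, "L": 20.3, "a": (6.42, 7.72), "l_c": 67.0},
    "LEF": {"Rg": 26.6, "Rc": 1.09, "L": 20.6, "a": (6.48,), "l_c": 33.0},
    "LEF_G": {"Rg": 30.3, "Rc": 1.13, "L": 18.7, "a": (6.48,), "l_c": 65.0},
}

_PRESET_BACKGROUND = 0.1
_PRESET_G = 1.0e4
_PRESET_G1 = 1.0


def preset_names():
    return list(_PRESET_TARGETS)


def preset_targets(name: str) -> dict:
    """Target derived metrics a preset must reproduce (3 s.f. by construction)."""
    try:
        return dict(_PRESET_TARGETS[name])
    except KeyError:
        raise ParameterError(f"unknown preset {name!r}") from None


def preset_model(name: str) -> CompositeModel:
    """Composite model whose derived metrics match the preset targets."""
    t = preset_targets(name)
    peaks = [
        _peak(a, t["l_c"], height_over_bg=10.0, background=_PRESET_BACKGROUND)
        for a in t["a"]
    ]
    return CompositeModel(
        level1=GuinierPorodLevel(G=_PRESET_G, Rg=t["Rg"], d=4.0),
        cylinder=_cyl_from_rc_l(_PRESET_G1, t["Rc"], t["L"], d=4.0),
        peaks=peaks,
        background=_PRESET_BACKGROUND,
    )


def make_q_grid(
    q_min: float = DEFAULT_Q_MIN,
    q_max: float = DEFAULT_Q_MAX,
    n: int = 400,
    spacing: str = "linear",
) -> np.ndarray:
    if q_min <= 0 or q_max <= q_min:
        raise ParameterError("need 0 < q_min < q_max")
    if n < 32:
        raise ParameterError("need n >= 32 grid points")
    if spacing == "linear":
        return np.linspace(q_min, q_max, n)
    if spacing == "log":
        return np.geomspace(q_min, q_max, n)
    raise ParameterError(f"unknown spacing {spacing!r}")


def synth_saxs_curve(
    model: CompositeModel,
    q: Optional[np.ndarray] = None,
    noise_model: str = "gaussian_multiplicative",
    noise_level: float = 0.01,
    seed: Optional[int] = None,
    label: str = "synthetic",
    temperature: Optional[float] = None,
) -> ScatteringCurve:
    """Evaluate a composite model on a grid and add counting-style noise.

    The uncertainty column holds the nominal noise SD per point (with a
    small floor so it stays positive at zero noise level).
    """
    if noise_level < 0:
        raise ParameterError("noise level must be >= 0")
    if q is None:
        q = make_q_grid()
    q = np.asarray(q, dtype=float)
    ideal = eval_composite(model, q)
    rng = np.random.default_rng(seed)
    if noise_model == "gaussian_multiplicative":
        sd = noise_level * ideal
    elif noise_model == "poisson_like":
        sd = noise_level * np.sqrt(ideal * ideal.max())
    else:
        raise ParameterError(f"unknown noise model {noise_model!r}")
    intensity = ideal + rng.standard_normal(q.size) * sd
    intensity = np.maximum(intensity, 1e-12 * ideal.max())
    floor = 1e-12 * ideal.max()
    meta = CurveMeta(label=label, temperature=temperature)
    return ScatteringCurve(
        q=q,
        intensity=intensity,
        uncertainty=np.maximum(sd, floor),
        meta=meta,
    )


def synth_preset_curve(
    name: str,
    noise_level: float = 0.01,
    seed: Optional[int] = None,
    n: int = 400,
    noise_model: str = "gaussian_multiplicative",
) -> ScatteringCurve:
    """Convenience wrapper: preset model on the instrument grid + noise."""
    return synth_saxs_curve(
        preset_model(name),
        q=make_q_grid(n=n),
        noise_model=noise_model,
        noise_level=noise_level,
        seed=seed,
        label=name,
    )


def synth_cac_series(
    cac: float = 2.1e-4,
    decades: float = 3.0,
    n: int = 12,
    post_slope: float = 2.0,
    plateau: float = 10.0,
    noise_level: float = 0.0,
    seed: Optional[int] = None,
    include_cac_point: bool = True,
) -> ConcentrationSeries:
    """Two-regime log-log concentration series with a breakpoint at ``cac``.

    Concentrations are log-spaced over ``decades`` centred so the CAC lies
    inside the range (and, by default, exactly on a sample point so that
    noiseless recovery is exact). Response is flat below the CAC and
    rises as (c/cac)^post_slope above; noise is multiplicative Gaussian.
    """
    if cac <= 0 or plateau <= 0:
        raise ParameterError("cac and plateau must be positive")
    if n < 6:
        raise ParameterError("need n >= 6 points")
    lo = math.log10(cac) - decades / 2.0
    hi = math.log10(cac) + decades / 2.0
    logc = np.linspace(lo, hi, n)
    if include_cac_point:
        # snap the nearest grid point onto the breakpoint
        logc[np.argmin(np.abs(logc - math.log10(cac)))] = math.log10(cac)
    conc = 10.0 ** np.sort(logc)
    if not (conc[0] <= cac <= conc[-1]):
        raise ParameterError("cac must lie inside the concentration range")
    resp = np.where(conc <= cac, plateau, plateau * (conc / cac) ** post_slope)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        resp = resp * np.exp(noise_level * rng.standard_normal(n))
    return ConcentrationSeries(concentration=conc, response=resp)


def synth_lattice_image(
    spacing: float = 5.7,
    pixel_size: float = 0.2,
    size: int = 512,
    pattern: str = "stripes",
    rotation_deg: float = 0.0,
    noise_level: float = 0.0,
    seed: Optional[int] = None,
) -> CalibratedImage:
    """Periodic grayscale test image with known row spacing (nm).

    ``pattern='stripes'`` is a single sinusoidal grating; ``'hexagonal'``
    sums three gratings at 120 degrees, giving a dot lattice whose row
    spacing equals ``spacing``. Raises :class:`SamplingError` below the
    Nyquist limit (spacing <= 2 pixels).
    """
    if spacing <= 2.0 * pixel_size:
        raise SamplingError(
            f"spacing {spacing} nm violates Nyquist for pixel {pixel_size} nm"
        )
    if size < 64:
        raise ParameterError("image size must be >= 64")
    yy, xx = np.mgrid[0:size, 0:size] * pixel_size
    theta0 = math.radians(rotation_deg)
    freq = 2.0 * math.pi / spacing
    if pattern == "stripes":
        angles = [theta0]
    elif pattern == "hexagonal":
        angles = [theta0, theta0 + 2.0 * math.pi / 3.0, theta0 + 4.0 * math.pi / 3.0]
    else:
        raise ParameterError(f"unknown pattern {pattern!r}")
    img = np.zeros((size, size))
    for th in angles:
        img += np.cos(freq * (xx * math.cos(th) + yy * math.sin(th)))
    img /= len(angles)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        img = img + noise_level * rng.standard_normal(img.shape)
    return CalibratedImage(data=img, pixel_size=pixel_size)


def synth_calibration(
    slope: float = 2.0,
    intercept: float = 0.0,
    concentrations=None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
):
    """Linear calibration standards with homoscedastic Gaussian noise."""
    if concentrations is None:
        concentrations = np.linspace(0.05, 0.5, 8)
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    r = slope * c + intercept
    if noise_sd > 0:
        r = r + noise_sd * rng.standard_normal(c.size)
    return c, r


def synth_release_samples(
    rate: float = 0.1,
    times=None,
    medium_volume: float = 45.0,
    aliquot_volume: float = 1.0,
    total_loaded: float = 300.0,
    noise_level: float = 0.0,
    seed: Optional[int] = None,
):
    """First-order release sampled with aliquot replacement.

    True cumulative fraction is 100 (1 - exp(-rate t)). The measured
    aliquot concentrations account for analyte removed at earlier
    timepoints, exactly matching the bookkeeping that
    :func:`lyoscat.assays.cumulative_release` inverts.

    Returns (times, concentrations, true_fraction_percent).
    """
    if rate <= 0:
        raise ParameterError("release rate must be positive")
    if times is None:
        times = np.array([1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0])
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0) or np.any(t <= 0):
        raise ParameterError("times must be positive and strictly increasing")
    frac = 1.0 - np.exp(-rate * t)
    mass = total_loaded * frac
    conc = np.zeros_like(t)
    removed = 0.0
    for i in range(t.size):
        conc[i] = (mass[i] - removed) / medium_volume
        removed += conc[i] * aliquot_volume
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        conc = conc * (1.0 + noise_level * rng.standard_normal(t.size))
        conc = np.maximum(conc, 0.0)
    return t, conc, 100.0 * frac


def synth_assay_data(kind: str, seed: Optional[int] = None, **params):
    """Dispatch generator for assay fixtures (``calibration`` or ``release``)."""
    if kind == "calibration":
        return synth_calibration(seed=seed, **params)
    if kind == "release":
        return synth_release_samples(seed=seed, **params)
    raise ParameterError(f"unknown assay data kind {kind!r}")
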