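"""Composite small-angle scattering intensity model and derived metrics.

The model is a sum of four contributions:

* a one-level Guinier-Porod term for the overall particle envelope,
* a two-level (cylinder) Guinier-Porod term for the rod-like internal
  structure,
* a sum of Lorentzian lattice peaks, and
* a flat background.

All crossover scales of the piecewise Guinier-Porod branches are derived
from continuity of value and first derivative, never fitted independently,
so every parameter set evaluates to a C^1 curve by construction.

Lengths are in nm, q in nm^-1 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .exceptions import ConfigurationError, GeometryError, ParameterError

#: Dsphere / Rg for a homogeneous sphere with equal radius of gyration.
SPHERE_DIAMETER_FACTOR = 2.0 * math.sqrt(5.0 / 3.0)


@dataclass
class GuinierPorodLevel:
    """One-level Guinier-Porod term: Guinier knee joined to a q^-d tail."""

    G: float
    Rg: float
    d: float = 4.0

    def __post_init__(self):
        if not (self.G > 0):
            raise ParameterError(f"G must be positive, got {self.G}")
        if not (self.Rg > 0):
            raise ParameterError(f"Rg must be positive, got {self.Rg}")
        if not (1.0 < self.d <= 4.0):
            raise ParameterError(f"Porod exponent d must be in (1, 4], got {self.d}")

    @property
    def q1(self) -> float:
        """Guinier/Porod crossover: q1 = sqrt(3 d / 2) / Rg."""
        return math.sqrt(1.5 * self.d) / self.Rg

    @property
    def porod_scale(self) -> float:
        """D = G exp(-d/2) (3d/2)^(d/2) / Rg^d (value+slope continuity at q1)."""
        return (
            self.G
            * math.exp(-self.d / 2.0)
            * (1.5 * self.d) ** (self.d / 2.0)
            / self.Rg ** self.d
        )

    def __call__(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if np.any(q <= 0):
            raise ParameterError("q must be positive")
        guinier = self.G * np.exp(-q * q * self.Rg ** 2 / 3.0)
        porod = self.porod_scale * q ** (-self.d)
        return np.where(q <= self.q1, guinier, porod)


@dataclass
class CylinderGuinierPorod:
    """Two-level Guinier-Porod term for cylinder-like scatterers.

    Branches (low to high q): overall Guinier with Rg2; rod regime
    (G1/q) exp(-q^2 Rg1^2 / 2); Porod tail D q^-d. The crossovers q2 and
    q1 and the scales G2 and D follow from continuity.
    """

    G1: float
    Rg1: float
    Rg2: float
    d: float = 4.0

    def __post_init__(self):
        if not (self.G1 > 0):
            raise ParameterError(f"G1 must be positive, got {self.G1}")
        if not (0 < self.Rg1 < self.Rg2):
            raise ParameterError(
                f"need 0 < Rg1 < Rg2, got Rg1={self.Rg1}, Rg2={self.Rg2}"
            )
        if not (1.0 < self.d <= 4.0):
            raise ParameterError(f"Porod exponent d must be in (1, 4], got {self.d}")
        if (2.0 / 3.0) * self.Rg2 ** 2 - self.Rg1 ** 2 <= 0:
            raise ParameterError(
                "q2 is not real: (2/3) Rg2^2 - Rg1^2 must be positive "
                f"(Rg1={self.Rg1}, Rg2={self.Rg2})"
            )
        if self.q2 >= self.q1:
            raise ParameterError(
                f"crossover order violated: q2={self.q2:.4g} >= q1={self.q1:.4g}"
            )

    @property
    def q2(self) -> float:
        """Guinier/rod crossover: q2 = [(2/3) Rg2^2 - Rg1^2]^(-1/2)."""
        return ((2.0 / 3.0) * self.Rg2 ** 2 - self.Rg1 ** 2) ** -0.5

    @property
    def q1(self) -> float:
        """Rod/Porod crossover: q1 = sqrt(d - 1) / Rg1."""
        return math.sqrt(self.d - 1.0) / self.Rg1

    @property
    def G2(self) -> float:
        """Overall Guinier scale from value continuity at q2: (G1/q2) e^(1/2)."""
        return self.G1 / self.q2 * math.exp(0.5)

    @property
    def porod_scale(self) -> float:
        """D = G1 q1^(d-1) exp(-(d-1)/2) (value+slope continuity at q1)."""
        return self.G1 * self.q1 ** (self.d - 1.0) * math.exp(-(self.d - 1.0) / 2.0)

    def __call__(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if np.any(q <= 0):
            raise ParameterError("q must be positive")
        guinier = self.G2 * np.exp(-q * q * self.Rg2 ** 2 / 3.0)
        rod = self.G1 / q * np.exp(-q * q * self.Rg1 ** 2 / 2.0)
        porod = self.porod_scale * q ** (-self.d)
        return np.where(q <= self.q2, guinier, np.where(q <= self.q1, rod, porod))


@dataclass
class LorentzianPeak:
    """Lorentzian lattice peak with integrated weight k and HWHM sigma."""

    k: float
    sigma: float
    q_max: float

    def __post_init__(self):
        if not (self.k > 0):
            raise ParameterError(f"peak weight k must be positive, got {self.k}")
        if not (self.sigma > 0):
            raise ParameterError(f"sigma must be positive, got {self.sigma}")
        if not (self.q_max > 0):
            raise ParameterError(f"q_max must be positive, got {self.q_max}")

    @property
    def correlation_length(self) -> float:
        """Lattice correlation length l_c = 2 pi / sigma."""
        return 2.0 * math.pi / self.sigma

    def __call__(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return self.k * self.sigma / (
            math.pi * (self.sigma ** 2 + (q - self.q_max) ** 2)
        )


def eval_peaks(peaks: List[LorentzianPeak], q) -> np.ndarray:
    """Sum of Lorentzian peak profiles on a q grid."""
    q = np.asarray(q, dtype=float)
    out = np.zeros_like(q)
    for p in peaks:
        out += p(q)
    return out


def eval_gp1(level: GuinierPorodLevel, q) -> np.ndarray:
    """Evaluate the one-level Guinier-Porod term."""
    return level(q)


def eval_cylinder_gp(cyl: CylinderGuinierPorod, q) -> np.ndarray:
    """Evaluate the two-level cylinder Guinier-Porod term."""
    return cyl(q)


@dataclass
class CompositeModel:
    """Full intensity model: envelope + cylinder + peaks + background."""

    level1: Optional[GuinierPorodLevel] = None
    cylinder: Optional[CylinderGuinierPorod] = None
    peaks: List[LorentzianPeak] = field(default_factory=list)
    background: float = 0.0

    def __post_init__(self):
        if self.background < 0:
            raise ParameterError(f"background must be >= 0, got {self.background}")
        self.peaks = sorted(self.peaks, key=lambda p: p.q_max)

    @property
    def enabled_components(self):
        names = []
        if self.level1 is not None:
            names.append("level1")
        if self.cylinder is not None:
            names.append("cylinder")
        if self.peaks:
            names.append("peaks")
        if self.background > 0:
            names.append("background")
        return names

    def __call__(self, q) -> np.ndarray:
        if not self.enabled_components:
            raise ConfigurationError("all model components are disabled")
        q = np.asarray(q, dtype=float)
        out = np.full_like(q, float(self.background))
        if self.level1 is not None:
            out += self.level1(q)
        if self.cylinder is not None:
            out += self.cylinder(q)
        if self.peaks:
            out += eval_peaks(self.peaks, q)
        return out

    def to_dict(self) -> dict:
        """Flat key-value serialization (documented parameter names)."""
        out = {"background": self.background}
        if self.level1 is not None:
            out.update(
                {"g1.G": self.level1.G, "g1.Rg": self.level1.Rg, "g1.d": self.level1.d}
            )
        if self.cylinder is not None:
            out.update(
                {
                    "cyl.G1": self.cylinder.G1,
                    "cyl.Rg1": self.cylinder.Rg1,
                    "cyl.Rg2": self.cylinder.Rg2,
                    "cyl.d": self.cylinder.d,
                }
            )
        for i, p in enumerate(self.peaks):
            out[f"peak[{i}].k"] = p.k
            out[f"peak[{i}].sigma"] = p.sigma
            out[f"peak[{i}].qmax"] = p.q_max
        return out

    @classmethod
    def from_dict(cls, params: dict) -> "CompositeModel":
        level1 = cylinder = None
        if "g1.Rg" in params:
            level1 = GuinierPorodLevel(
                G=float(params["g1.G"]),
                Rg=float(params["g1.Rg"]),
                d=float(params.get("g1.d", 4.0)),
            )
        if "cyl.Rg1" in params:
            cylinder = CylinderGuinierPorod(
                G1=float(params["cyl.G1"]),
                Rg1=float(params["cyl.Rg1"]),
                Rg2=float(params["cyl.Rg2"]),
                d=float(params.get("cyl.d", params.get("g1.d", 4.0))),
            )
        peaks = []
        i = 0
        while f"peak[{i}].qmax" in params:
            peaks.append(
                LorentzianPeak(
                    k=float(params[f"peak[{i}].k"]),
                    sigma=float(params[f"peak[{i}].sigma"]),
                    q_max=float(params[f"peak[{i}].qmax"]),
                )
            )
            i += 1
        return cls(
            level1=level1,
            cylinder=cylinder,
            peaks=peaks,
            background=float(params.get("background", 0.0)),
        )


def eval_composite(model: CompositeModel, q) -> np.ndarray:
    """Evaluate the composite model (sum of enabled components)."""
    return model(q)


def hexagonal_lattice_constant(q_100: float) -> float:
    """Hexagonal lattice constant from the (100) peak: a = 4 pi / (sqrt(3) q)."""
    if q_100 <= 0:
        raise ParameterError("q_100 must be positive")
    return 4.0 * math.pi / (math.sqrt(3.0) * q_100)


def sphere_equivalent_diameter(Rg: float) -> float:
    """Diameter of the homogeneous sphere with the same Rg: 2 sqrt(5/3) Rg."""
    if Rg <= 0:
        raise ParameterError("Rg must be positive")
    return SPHERE_DIAMETER_FACTOR * Rg


@dataclass
class PeakMetrics:
    q_max: float
    d_spacing: float
    a_hex: float
    l_c: float


@dataclass
class StructuralReport:
    """Derived structural metrics with the formulas that produced them."""

    Rg: Optional[float] = None
    Dsphere: Optional[float] = None
    Rc: Optional[float] = None
    L: Optional[float] = None
    peaks: List[PeakMetrics] = field(default_factory=list)
    formulas: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for k in ("Rg", "Dsphere", "Rc", "L"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        for i, p in enumerate(self.peaks):
            out[f"peak[{i}].qmax"] = p.q_max
            out[f"peak[{i}].d_spacing"] = p.d_spacing
            out[f"peak[{i}].a_hex"] = p.a_hex
            out[f"peak[{i}].l_c"] = p.l_c
        out["formulas"] = dict(self.formulas)
        return out


_FORMULAS = {
    "Dsphere": "Dsphere = 2*sqrt(5/3)*Rg",
    "Rc": "Rc = sqrt(2)*Rg1",
    "L": "L = sqrt(12*Rg2^2 - 6*Rc^2)",
    "a_hex": "a = 4*pi/(sqrt(3)*q_max)  [valid for the (100) reflection]",
    "l_c": "l_c = 2*pi/sigma",
    "d_spacing": "d = 2*pi/q_max",
}


def derived_metrics(model: CompositeModel) -> StructuralReport:
    """Compute all structural metrics the model parameters imply.

    Raises :class:`GeometryError` when the cylinder length has no real
    solution (12 Rg2^2 <= 6 Rc^2).
    """
    report = StructuralReport(formulas=dict(_FORMULAS))
    if model.level1 is not None:
        report.Rg = model.level1.Rg
        report.Dsphere = sphere_equivalent_diameter(model.level1.Rg)
    if model.cylinder is not None:
        Rc = math.sqrt(2.0) * model.cylinder.Rg1
        radicand = 12.0 * model.cylinder.Rg2 ** 2 - 6.0 * Rc ** 2
        if radicand <= 0:
            raise GeometryError(
                "cylinder length undefined: 12*Rg2^2 <= 6*Rc^2 "
                f"(Rg1={model.cylinder.Rg1}, Rg2={model.cylinder.Rg2})"
            )
        report.Rc = Rc
        report.L = math.sqrt(radicand)
    for p in model.peaks:
        report.peaks.append(
            PeakMetrics(
                q_max=p.q_max,
                d_spacing=2.0 * math.pi / p.q_max,
                a_hex=hexagonal_lattice_constant(p.q_max),
                l_c=p.correlation_length,
            )
        )
    return report
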