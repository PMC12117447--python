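"""Reading and writing of scattering curves and assay tables.

The canonical internal q unit is nm^-1. Angstrom^-1 input is accepted and
converted on load (factor 10); the original unit is kept in the curve
metadata. Unit auto-detection first looks for a unit tag in the header
comments, then falls back to a magnitude heuristic (max(q) < 0.5 suggests
Angstrom^-1), which is always recorded in the load report.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DuplicateAbscissaError, MalformedInputError, UnitError

logger = logging.getLogger(__name__)

#: Canonical unit tags.
UNIT_NM = "nm^-1"
UNIT_ANGSTROM = "A^-1"

_UNIT_ALIASES = {
    "nm^-1": UNIT_NM,
    "nm-1": UNIT_NM,
    "1/nm": UNIT_NM,
    "nm⁻¹": UNIT_NM,
    "a^-1": UNIT_ANGSTROM,
    "a-1": UNIT_ANGSTROM,
    "1/a": UNIT_ANGSTROM,
    "å^-1": UNIT_ANGSTROM,
    "å⁻¹": UNIT_ANGSTROM,
    "ang^-1": UNIT_ANGSTROM,
    "angstrom^-1": UNIT_ANGSTROM,
}

# Matches e.g. "q(A^-1)", "q / nm^-1", "q [1/A]" in header comments.
_HEADER_UNIT_RE = re.compile(
    r"q\s*[(\[/ ]\s*(1/)?(?P<unit>(nm|a|å|ang(strom)?))\s*(\^?-?1)?\s*[)\]]?",
    re.IGNORECASE,
)

MIN_POINTS = 8


def normalize_unit(tag: str) -> str:
    """Map a unit spelling to a canonical tag, or raise :class:`UnitError`."""
    key = str(tag).strip().lower()
    try:
        return _UNIT_ALIASES[key]
    except KeyError:
        raise UnitError(f"unknown q unit tag: {tag!r}") from None


def convert_q_units(values, from_unit: str, to_unit: str):
    """Convert q magnitudes between Angstrom^-1 and nm^-1.

    A^-1 -> nm^-1 multiplies by 10; the inverse divides by 10; identity
    conversion returns the input unchanged.
    """
    src = normalize_unit(from_unit)
    dst = normalize_unit(to_unit)
    values = np.asarray(values, dtype=float)
    if src == dst:
        return values
    if src == UNIT_ANGSTROM and dst == UNIT_NM:
        return values * 10.0
    return values / 10.0


@dataclass
class CurveMeta:
    """Provenance metadata attached to a :class:`ScatteringCurve`."""

    source_unit: str = UNIT_NM
    label: str = ""
    temperature: Optional[float] = None  # degrees C
    instrument: Optional[str] = None
    background_subtracted: bool = False
    n_dropped: int = 0  # non-finite rows discarded on load
    unit_detection: Optional[str] = None  # 'hint' | 'header' | 'heuristic' | None


@dataclass
class ScatteringCurve:
    """A 1D scattering curve on a strictly increasing q grid (nm^-1)."""

    q: np.ndarray
    intensity: np.ndarray
    uncertainty: Optional[np.ndarray] = None
    meta: CurveMeta = field(default_factory=CurveMeta)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.q.ndim != 1 or self.q.size == 0:
            raise MalformedInputError("q must be a non-empty 1D array")
        if self.intensity.shape != self.q.shape:
            raise MalformedInputError("intensity length must match q")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.intensity)):
            raise MalformedInputError("q and intensity must be finite")
        if np.any(self.q <= 0):
            raise MalformedInputError("q values must be positive")
        dq = np.diff(self.q)
        if np.any(dq == 0):
            raise DuplicateAbscissaError("duplicate q values")
        if np.any(dq < 0):
            raise MalformedInputError("q must be strictly increasing")
        if self.uncertainty is not None:
            if self.uncertainty.shape != self.q.shape:
                raise MalformedInputError("uncertainty length must match q")
            if np.any(~np.isfinite(self.uncertainty)) or np.any(self.uncertainty <= 0):
                raise MalformedInputError("uncertainties must be finite and positive")
        if np.any(self.intensity < 0) and not self.meta.background_subtracted:
            raise MalformedInputError(
                "negative intensities require background_subtracted metadata"
            )

    def __len__(self) -> int:
        return self.q.size

    def with_intensity(self, intensity, uncertainty=None) -> "ScatteringCurve":
        return ScatteringCurve(
            q=self.q.copy(),
            intensity=np.asarray(intensity, dtype=float),
            uncertainty=None if uncertainty is None else np.asarray(uncertainty, float),
            meta=replace(self.meta),
        )


@dataclass
class ConcentrationSeries:
    """Concentration vs detector response (e.g. scattered-light kcps)."""

    concentration: np.ndarray  # molar
    response: np.ndarray
    replicate: Optional[np.ndarray] = None

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
        if self.concentration.shape != self.response.shape:
            raise MalformedInputError("concentration and response lengths differ")
        if np.any(self.concentration <= 0):
            raise MalformedInputError("concentrations must be positive")
        if np.any(self.response < 0):
            raise MalformedInputError("responses must be non-negative")
        if np.unique(self.concentration).size < 4:
            raise MalformedInputError("need at least 4 distinct concentrations")


def _detect_unit_from_header(header_lines) -> Optional[str]:
    for line in header_lines:
        m = _HEADER_UNIT_RE.search(line)
        if m:
            token = m.group("unit").lower()
            return UNIT_NM if token == "nm" else UNIT_ANGSTROM
    return None


def _sniff_table(text: str) -> np.ndarray:
    """Parse delimited numeric text, trying comma, tab, then whitespace."""
    for sep in (",", "\t", None):
        try:
            arr = np.genfromtxt(
                _io.StringIO(text), delimiter=sep, comments="#", dtype=float
            )
        except ValueError:
            continue
        if arr.ndim == 1 and arr.size:
            arr = arr.reshape(1, -1)
        if arr.ndim == 2 and arr.shape[1] >= 2 and np.isfinite(arr[:, 0]).any():
            return arr
    raise MalformedInputError("could not parse a numeric table with >= 2 columns")


def read_curve(path, unit_hint: Optional[str] = None) -> ScatteringCurve:
    """Load a delimited-text scattering curve, converting q to nm^-1.

    Comment lines start with '#'. A third numeric column, when present, is
    read as per-point uncertainty. Non-finite rows are dropped and counted
    in ``meta.n_dropped``.
    """
    path = Path(path)
    text = path.read_text()
    header = [ln for ln in text.splitlines() if ln.lstrip().startswith("#")]
    # Non-comment, non-numeric first line is treated as a column header.
    for ln in text.splitlines():
        s = ln.strip()
        if not s or s.startswith("#"):
            continue
        if not re.match(r"^[\s0-9+\-.eE,\t;]+$", s):
            header.append(s)
            text = text.replace(ln, "# " + ln, 1)
        break

    arr = _sniff_table(text)
    if arr.shape[1] < 2:
        raise MalformedInputError(f"{path}: expected >= 2 numeric columns")

    cols = arr[:, :3] if arr.shape[1] >= 3 else arr[:, :2]
    finite = np.all(np.isfinite(cols), axis=1)
    n_dropped = int((~finite).sum())
    cols = cols[finite]
    if cols.shape[0] < MIN_POINTS:
        raise MalformedInputError(
            f"{path}: only {cols.shape[0]} valid points (need >= {MIN_POINTS})"
        )

    order = np.argsort(cols[:, 0], kind="stable")
    cols = cols[order]
    if np.any(np.diff(cols[:, 0]) == 0):
        raise DuplicateAbscissaError(f"{path}: duplicate q values")

    detection = None
    if unit_hint is not None:
        unit = normalize_unit(unit_hint)
        detection = "hint"
    else:
        unit = _detect_unit_from_header(header)
        if unit is not None:
            detection = "header"
        else:
            unit = UNIT_ANGSTROM if cols[-1, 0] < 0.5 else UNIT_NM
            detection = "heuristic"
            logger.info(
                "%s: q unit auto-detected as %s (max q = %.4g)",
                path.name, unit, cols[-1, 0],
            )

    q = convert_q_units(cols[:, 0], unit, UNIT_NM)
    unc = cols[:, 2] if cols.shape[1] == 3 else None
    meta = CurveMeta(
        source_unit=unit,
        label=path.stem,
        background_subtracted=bool(np.any(cols[:, 1] < 0)),
        n_dropped=n_dropped,
        unit_detection=detection,
    )
    return ScatteringCurve(q=q, intensity=cols[:, 1], uncertainty=unc, meta=meta)


def write_curve(curve: ScatteringCurve, path) -> Path:
    """Write a curve as delimited text (q in nm^-1); bit-stable output."""
    curve.validate()
    path = Path(path)
    lines = [
        "# lyoscat scattering curve",
        f"# q_unit: {UNIT_NM}",
        f"# source_unit: {curve.meta.source_unit}",
        f"# label: {curve.meta.label}",
    ]
    if curve.meta.temperature is not None:
        lines.append(f"# temperature_C: {curve.meta.temperature!r}")
    if curve.meta.background_subtracted:
        lines.append("# background_subtracted: true")
    ncol = 3 if curve.uncertainty is not None else 2
    lines.append("# columns: q_nm^-1 intensity" + (" uncertainty" if ncol == 3 else ""))
    for i in range(len(curve)):
        row = [curve.q[i], curve.intensity[i]]
        if ncol == 3:
            row.append(curve.uncertainty[i])
        lines.append("\t".join(format(v, ".17g") for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_concentration_series(path) -> ConcentrationSeries:
    """Read a CSV with columns concentration_M, response_kcps[, replicate]."""
    df = pd.read_csv(path, comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        conc = df[cols["concentration_m"]].to_numpy(float)
        resp = df[cols["response_kcps"]].to_numpy(float)
    except KeyError as exc:
        raise MalformedInputError(
            f"{path}: need columns concentration_M, response_kcps"
        ) from exc
    rep = df[cols["replicate"]].to_numpy() if "replicate" in cols else None
    return ConcentrationSeries(concentration=conc, response=resp, replicate=rep)


def write_concentration_series(series: ConcentrationSeries, path) -> Path:
    path = Path(path)
    data = {"concentration_M": series.concentration, "response_kcps": series.response}
    if series.replicate is not None:
        data["replicate"] = series.replicate
    pd.DataFrame(data).to_csv(path, index=False)
    return path
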