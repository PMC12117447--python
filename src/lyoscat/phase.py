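"""Mesophase peak indexing, lattice constants and transition detection.

Observed Bragg peak positions are matched against the allowed-reflection
ratio tables of the common lyotropic phases. The first observed peak is
tried as an anchor against every allowed reflection of a candidate phase
(weak or missing low-order reflections are common), remaining peaks are
matched greedily within a relative tolerance, and assignments are ranked
by number of matched peaks, then by RMS relative deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import MalformedInputError, ParameterError, PhaseStateError

HEXAGONAL = "hexagonal_HII"
PN3M = "cubic_Pn3m"
IM3M = "cubic_Im3m"
IA3D = "cubic_Ia3d"
LAMELLAR = "lamellar"
UNASSIGNED = "unassigned"

_SQ = math.sqrt

#: Allowed reflections: phase -> ordered list of (ratio, Miller index label).
#: Ratios are q_hkl / q_first-allowed with the first allowed ratio scaled to
#: its absolute sqrt(N) value so that lattice constants follow directly.
RATIO_TABLE: Dict[str, List[Tuple[float, str]]] = {
    HEXAGONAL: [(1.0, "(100)"), (_SQ(3.0), "(110)"), (_SQ(4.0), "(200)")],
    PN3M: [
        (_SQ(2.0), "(110)"),
        (_SQ(3.0), "(111)"),
        (_SQ(4.0), "(200)"),
        (_SQ(6.0), "(211)"),
        (_SQ(8.0), "(220)"),
        (_SQ(9.0), "(221)"),
    ],
    IM3M: [
        (_SQ(2.0), "(110)"),
        (_SQ(4.0), "(200)"),
        (_SQ(6.0), "(211)"),
        (_SQ(8.0), "(220)"),
        (_SQ(10.0), "(310)"),
        (_SQ(12.0), "(222)"),
    ],
    IA3D: [(_SQ(6.0), "(211)"), (_SQ(8.0), "(220)"), (_SQ(14.0), "(321)"), (_SQ(16.0), "(400)")],
    LAMELLAR: [(1.0, "(001)"), (2.0, "(002)"), (3.0, "(003)")],
}


def bragg_spacing(q: float) -> float:
    """Bragg d-spacing d = 2 pi / q (q in nm^-1, d in nm)."""
    if q <= 0:
        raise ParameterError(f"q must be positive, got {q}")
    return 2.0 * math.pi / q


def _lattice_constant_single(phase: str, ratio: float, q_obs: float) -> float:
    """Lattice constant implied by one indexed peak."""
    if phase == HEXAGONAL:
        # q_hk = (4 pi / (sqrt(3) a)) * sqrt(h^2 + hk + k^2); ratio = sqrt(...)
        return 4.0 * math.pi * ratio / (math.sqrt(3.0) * q_obs)
    if phase in (PN3M, IM3M, IA3D):
        # q_hkl = 2 pi sqrt(h^2+k^2+l^2) / a; ratio = sqrt(N)
        return 2.0 * math.pi * ratio / q_obs
    if phase == LAMELLAR:
        # q_00l = 2 pi l / a; ratio = l
        return 2.0 * math.pi * ratio / q_obs
    raise PhaseStateError(f"no lattice-constant formula for phase {phase!r}")


@dataclass
class MatchedPeak:
    q_obs: float
    index_label: str
    q_expected: float
    ratio: float
    relative_deviation: float


@dataclass
class PhaseAssignment:
    """Result of matching observed peaks against one phase's ratio table."""

    phase: str
    matched: List[MatchedPeak] = field(default_factory=list)
    lattice_constant: Optional[float] = None  # nm
    score: float = math.inf  # RMS relative deviation over matches
    n_gaps: int = 0  # allowed reflections skipped within the matched span
    note: str = ""

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def d_spacings(self) -> List[float]:
        return [bragg_spacing(m.q_obs) for m in self.matched]

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "lattice_constant_nm": self.lattice_constant,
            "score": None if math.isinf(self.score) else self.score,
            "n_matched": self.n_matched,
            "matched": [
                {
                    "q_obs": m.q_obs,
                    "index": m.index_label,
                    "q_expected": m.q_expected,
                    "relative_deviation": m.relative_deviation,
                    "d_spacing_nm": bragg_spacing(m.q_obs),
                }
                for m in self.matched
            ],
            "note": self.note,
        }


def _match_phase(
    q_obs: np.ndarray, phase: str, tol_rel: float
) -> Optional[PhaseAssignment]:
    """Best anchored greedy match of q_obs against one phase table."""
    table = RATIO_TABLE[phase]
    best: Optional[PhaseAssignment] = None
    for anchor_idx in range(len(table)):
        anchor_ratio = table[anchor_idx][0]
        scale = q_obs[0] / anchor_ratio  # q per unit ratio
        matched = [
            MatchedPeak(
                q_obs=float(q_obs[0]),
                index_label=table[anchor_idx][1],
                q_expected=float(q_obs[0]),
                ratio=anchor_ratio,
                relative_deviation=0.0,
            )
        ]
        j = anchor_idx + 1
        last_matched_idx = anchor_idx
        for q in q_obs[1:]:
            # advance through remaining allowed reflections, allowing gaps
            while j < len(table):
                q_exp = scale * table[j][0]
                dev = (q - q_exp) / q_exp
                if abs(dev) <= tol_rel:
                    matched.append(
                        MatchedPeak(
                            q_obs=float(q),
                            index_label=table[j][1],
                            q_expected=float(q_exp),
                            ratio=table[j][0],
                            relative_deviation=float(dev),
                        )
                    )
                    last_matched_idx = j
                    j += 1
                    break
                if q_exp > q * (1 + tol_rel):
                    break  # this observed peak has no reflection to match
                j += 1
        score = float(
            np.sqrt(np.mean([m.relative_deviation ** 2 for m in matched]))
        )
        n_gaps = (last_matched_idx - anchor_idx + 1) - len(matched)
        cand = PhaseAssignment(
            phase=phase, matched=matched, score=score, n_gaps=n_gaps
        )
        # prefer lower anchor index on ties: within-phase harmonics (e.g.
        # Pn3m (110):(111) vs (200):(211), both sqrt(3/2)) are otherwise
        # resolved by floating-point noise in the score
        key = (-cand.n_matched, cand.n_gaps, round(cand.score, 12), anchor_idx)
        if best is None or key < best_key:
            best, best_key = cand, key
    if best is not None:
        best.lattice_constant = lattice_constant(best)
    return best


def index_peaks(
    q_obs: Sequence[float],
    phases: Optional[Sequence[str]] = None,
    tol_rel: float = 0.02,
) -> List[PhaseAssignment]:
    """Rank candidate phase assignments for a sorted peak-position list.

    Returns assignments sorted by (n_matched descending, score ascending).
    With a single observed peak the result is ``unassigned`` unless exactly
    one candidate phase is requested.
    """
    q_obs = np.asarray(list(q_obs), dtype=float)
    if q_obs.size == 0:
        raise MalformedInputError("empty peak list")
    if np.any(q_obs <= 0):
        raise ParameterError("peak positions must be positive")
    if np.any(np.diff(q_obs) <= 0):
        raise MalformedInputError("peak positions must be sorted and distinct")
    phases = list(phases) if phases is not None else list(RATIO_TABLE)
    for ph in phases:
        if ph not in RATIO_TABLE:
            raise ParameterError(f"unknown phase {ph!r}")

    if q_obs.size == 1 and len(phases) != 1:
        return [
            PhaseAssignment(
                phase=UNASSIGNED,
                note="single peak cannot discriminate between candidate phases",
            )
        ]

    out = [a for ph in phases if (a := _match_phase(q_obs, ph, tol_rel)) is not None]
    # Stable sort: ties fall back to the candidate-phase preference order.
    # The score is rounded so exact cross-phase harmonics (identical ratio
    # subsets, scores differing only in floating-point noise) tie cleanly.
    out.sort(key=lambda a: (-a.n_matched, a.n_gaps, round(a.score, 12)))
    if not out or out[0].n_matched < min(2, q_obs.size):
        out.insert(
            0,
            PhaseAssignment(phase=UNASSIGNED, note="no phase matched enough peaks"),
        )
    return out


def lattice_constant(assignment: PhaseAssignment, regression: bool = False) -> float:
    """Lattice constant from an assignment.

    Default: mean of the per-peak constants implied by each matched
    reflection (exactly the (100) / sqrt(N) formulas when a single peak is
    matched). ``regression=True`` instead least-squares a over all matched
    peaks in q = (2 pi sqrt(N)/a or hex equivalent) form, which weights
    higher-q reflections more.
    """
    if assignment.phase == UNASSIGNED:
        raise PhaseStateError("cannot compute a lattice constant for 'unassigned'")
    if not assignment.matched:
        raise PhaseStateError("assignment has no matched peaks")
    per_peak = np.array(
        [
            _lattice_constant_single(assignment.phase, m.ratio, m.q_obs)
            for m in assignment.matched
        ]
    )
    if not regression:
        return float(per_peak.mean())
    # q_i = c_i / a with c_i = per_peak_i * q_i; LS over a: minimize sum (q_i - c_i/a)^2
    q = np.array([m.q_obs for m in assignment.matched])
    c = per_peak * q
    return float(np.sum(c * c) / np.sum(c * q))


@dataclass
class TransitionPoint:
    temperature: float
    phase: str
    assignment: Optional[PhaseAssignment] = None


@dataclass
class TransitionReport:
    points: List[TransitionPoint]
    transitions: List[float]  # temperatures where the phase first changes

    def to_dict(self) -> dict:
        return {
            "points": [{"temperature_C": p.temperature, "phase": p.phase} for p in self.points],
            "transition_temperatures_C": list(self.transitions),
        }


def detect_transition(
    series: Sequence[Tuple[float, Sequence[float]]],
    phases: Optional[Sequence[str]] = None,
    tol_rel: float = 0.02,
) -> TransitionReport:
    """Assign a phase per temperature and report phase-change temperatures.

    ``series`` is a sorted list of (temperature_C, peak positions). Points
    with no peaks are marked unassigned and skipped by the transition logic
    (a change is only reported between consecutive *assigned* points).
    """
    if len(series) < 2:
        raise MalformedInputError("need at least 2 temperatures")
    temps = [t for t, _ in series]
    if any(t2 <= t1 for t1, t2 in zip(temps, temps[1:])):
        raise MalformedInputError("temperatures must be strictly increasing")

    points: List[TransitionPoint] = []
    for t, q_obs in series:
        if len(q_obs) == 0:
            points.append(TransitionPoint(temperature=t, phase=UNASSIGNED))
            continue
        ranked = index_peaks(q_obs, phases=phases, tol_rel=tol_rel)
        best = ranked[0]
        points.append(TransitionPoint(temperature=t, phase=best.phase, assignment=best))

    transitions: List[float] = []
    prev_phase: Optional[str] = None
    for p in points:
        if p.phase == UNASSIGNED:
            continue
        if prev_phase is not None and p.phase != prev_phase:
            transitions.append(p.temperature)
        prev_phase = p.phase
    return TransitionReport(points=points, transitions=transitions)
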