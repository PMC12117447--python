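import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lyoscat.exceptions import MalformedInputError, ParameterError, PhaseStateError
from lyoscat.phase import (
    HEXAGONAL,
    IA3D,
    IM3M,
    LAMELLAR,
    PN3M,
    RATIO_TABLE,
    UNASSIGNED,
    bragg_spacing,
    detect_transition,
    index_peaks,
    lattice_constant,
)


class TestBraggSpacing:
    def test_printed_first_peak(self):
        # 0.1140 A^-1 = 1.140 nm^-1
        # 2 pi / 1.140 = 5.5116; the printed 5.511 is truncated, not rounded
        assert bragg_spacing(1.140) == pytest.approx(5.511, abs=1e-3)

    def test_definition(self):
        assert bragg_spacing(2.0 * math.pi) == pytest.approx(1.0, rel=1e-15)

    def test_instrument_qmax(self):
        assert bragg_spacing(1.70) == pytest.approx(3.696, abs=5e-4)
        # the instrument quotes pi/q for its minimum resolvable size
        assert math.pi / 1.70 == pytest.approx(1.8, abs=0.05)

    def test_nonpositive_q(self):
        with pytest.raises(ParameterError):
            bragg_spacing(0.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_hexagonal_d100_identity(self, a):
        # q for (100) from a, then back through Bragg: d = a * sqrt(3)/2
        q100 = 4.0 * math.pi / (math.sqrt(3.0) * a)
        assert bragg_spacing(q100) == pytest.approx(a * math.sqrt(3.0) / 2.0, rel=1e-12)


class TestRatioTable:
    @pytest.mark.parametrize("phase", list(RATIO_TABLE))
    def test_ratios_strictly_increasing(self, phase):
        ratios = [r for r, _ in RATIO_TABLE[phase]]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_expected_phases_present(self):
        assert set(RATIO_TABLE) == {HEXAGONAL, PN3M, IM3M, IA3D, LAMELLAR}


class TestIndexPeaks:
    def test_hexagonal_exact_ratios(self):
        q0 = 1.140
        ranked = index_peaks([q0, q0 * math.sqrt(3.0), q0 * 2.0])
        best = ranked[0]
        assert best.phase == HEXAGONAL
        assert [m.index_label for m in best.matched] == ["(100)", "(110)", "(200)"]
        assert best.score < 1e-9

    def test_hexagonal_printed_rounded_values(self):
        best = index_peaks([1.140, 1.974, 2.280])[0]
        assert best.phase == HEXAGONAL
        assert best.score < 1e-3

    def test_pn3m_exact_ratios(self):
        scale = 1.0 / math.sqrt(2.0)
        q = [scale * math.sqrt(n) for n in (2, 3, 4, 6)]
        best = index_peaks(q)[0]
        assert best.phase == PN3M
        assert best.n_matched == 4
        assert best.score < 1e-9

    def test_pn3m_spec_rounded_values(self):
        best = index_peaks([1.000, 1.225, 1.414, 1.732])[0]
        assert best.phase == PN3M
        assert best.n_matched == 4

    def test_single_peak_unassigned(self):
        ranked = index_peaks([1.140])
        assert ranked[0].phase == UNASSIGNED
        assert ranked[0].note

    def test_single_peak_with_one_requested_phase(self):
        ranked = index_peaks([1.140], phases=[HEXAGONAL])
        assert ranked[0].phase == HEXAGONAL
        assert ranked[0].lattice_constant == pytest.approx(
            4 * math.pi / (math.sqrt(3.0) * 1.140), rel=1e-12
        )

    def test_empty_input(self):
        with pytest.raises(MalformedInputError):
            index_peaks([])

    def test_unknown_phase(self):
        with pytest.raises(ParameterError):
            index_peaks([1.0, 1.7], phases=["cubic_Fd3m"])

    def test_unsorted_input(self):
        with pytest.raises(MalformedInputError):
            index_peaks([1.5, 1.0])

    def test_scale_invariance(self):
        q = [1.0, math.sqrt(3.0), 2.0]
        for c in (0.25, 3.0, 17.0):
            base = index_peaks(q)[0]
            scaled = index_peaks([c * x for x in q])[0]
            assert scaled.phase == base.phase
            assert [m.index_label for m in scaled.matched] == [
                m.index_label for m in base.matched
            ]
            assert scaled.lattice_constant == pytest.approx(
                base.lattice_constant / c, rel=1e-12
            )

    # Subsets of consecutive reflections that contain at least one
    # phase-distinguishing ratio. Degenerate collisions (e.g. hexagonal
    # (110):(200) == Pn3m (211):(220) == 2/sqrt(3)) are inherently
    # ambiguous and excluded by construction.
    DISTINGUISHING = [
        (HEXAGONAL, 0, 3),
        (HEXAGONAL, 0, 2),
        (PN3M, 0, 2),
        (PN3M, 0, 3),
        (PN3M, 0, 6),
        (PN3M, 1, 4),
        (IM3M, 0, 6),
        (IA3D, 0, 4),
        (IA3D, 1, 4),
        (LAMELLAR, 0, 3),
    ]

    @pytest.mark.parametrize("phase,start,stop", DISTINGUISHING)
    @pytest.mark.parametrize("anchor_q", [0.7, 1.3])
    def test_generated_subsets_recovered(self, phase, start, stop, anchor_q):
        table = RATIO_TABLE[phase][start:stop]
        q = [anchor_q * r / table[0][0] for r, _ in table]
        best = index_peaks(q)[0]
        assert best.phase == phase
        assert best.n_matched == len(q)
        assert best.score < 1e-9
        assert [m.index_label for m in best.matched] == [lbl for _, lbl in table]


class TestLatticeConstant:
    def test_hexagonal_printed(self):
        best = index_peaks([1.140, 1.140 * math.sqrt(3.0)])[0]
        assert lattice_constant(best) == pytest.approx(6.364, abs=1e-3)

    def test_hexagonal_inverse_consistency(self):
        # a = 6.42 nm corresponds to q_100 = 4 pi / (sqrt(3) * 6.42)
        q100 = 4.0 * math.pi / (math.sqrt(3.0) * 6.42)
        assert q100 == pytest.approx(1.130, abs=1e-3)
        best = index_peaks([q100, q100 * math.sqrt(3.0)])[0]
        assert lattice_constant(best) == pytest.approx(6.42, rel=1e-12)

    def test_pn3m_single_110_identity(self):
        # a = 2 pi sqrt(2) / q; with q = 2 pi sqrt(2) this is exactly 1
        best = index_peaks([2.0 * math.pi * math.sqrt(2.0)], phases=[PN3M])[0]
        assert best.matched[0].index_label == "(110)"
        assert lattice_constant(best) == pytest.approx(1.0, rel=1e-12)
        # scaling down by 2 doubles the constant (same identity at a = 2)
        best2 = index_peaks([math.pi * math.sqrt(2.0)], phases=[PN3M])[0]
        assert lattice_constant(best2) == pytest.approx(2.0, rel=1e-12)

    def test_unassigned_raises(self):
        ranked = index_peaks([1.140])
        with pytest.raises(PhaseStateError):
            lattice_constant(ranked[0])

    def test_regression_mode_agrees_on_exact_data(self):
        q0 = 1.13
        best = index_peaks([q0, q0 * math.sqrt(3.0), q0 * 2.0])[0]
        assert lattice_constant(best, regression=True) == pytest.approx(
            lattice_constant(best), rel=1e-12
        )


class TestDetectTransition:
    @staticmethod
    def _series():
        hex_q = [1.13, 1.13 * math.sqrt(3.0), 2.26]
        pn3m_q = [math.sqrt(n) for n in (2, 3, 4, 6)]
        series = []
        for t in (21.0, 30.0, 40.0, 45.0):
            series.append((t, pn3m_q))
        for t in (50.0, 60.0, 75.0, 90.0):
            series.append((t, hex_q))
        return series

    def test_single_transition_at_50(self):
        report = detect_transition(self._series())
        assert [p.phase for p in report.points[:4]] == [PN3M] * 4
        assert [p.phase for p in report.points[4:]] == [HEXAGONAL] * 4
        assert report.transitions == [50.0]

    def test_all_hexagonal_no_transition(self):
        hex_q = [1.13, 1.13 * math.sqrt(3.0)]
        report = detect_transition([(t, hex_q) for t in (20.0, 40.0, 60.0)])
        assert report.transitions == []

    def test_unassigned_point_skipped(self):
        series = self._series()
        series[4] = (50.0, [])  # no peaks at 50 C -> unassigned, skipped
        report = detect_transition(series)
        assert report.points[4].phase == UNASSIGNED
        assert report.transitions == [60.0]

    def test_needs_two_temperatures(self):
        with pytest.raises(MalformedInputError):
            detect_transition([(25.0, [1.0, 1.7])])

    def test_non_monotone_temperatures(self):
        with pytest.raises(MalformedInputError):
            detect_transition([(50.0, [1.0, 1.7]), (25.0, [1.0, 1.7])])
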