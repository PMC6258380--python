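"""Oscillation summaries, synchrony grouping, labels, frequencies."""

import numpy as np
import pytest

from oscbind.classify import (
    InsufficientDataError,
    OscillationSummary,
    PhasePattern,
    UndefinedFrequencyError,
    classify_pattern,
    classify_trajectory,
    frequencies,
    summarize_oscillations,
)
from oscbind.model import simulate
from oscbind.params import StimulusProtocol, StimulusPulse


def _summary(pop, peaks, period, amp=8.0, disp=0.001):
    return OscillationSummary(
        population=pop, peak_times=np.asarray(peaks, float), period=period,
        t_active=20.0, t_quiet=period - 20.0, amplitude=amp,
        activity_class="active", dispersion=disp)


class TestSummaries:
    def test_single_population_statistics(self, so_trajectory):
        s = summarize_oscillations(so_trajectory)
        assert s[0].activity_class == "active"
        assert s[0].period == pytest.approx(49.9, abs=1.0)
        assert s[0].t_active + s[0].t_quiet == pytest.approx(s[0].period,
                                                             abs=0.2)
        for j in range(1, 5):
            assert s[j].activity_class == "quiescent"

    def test_duty_cycle(self, so_trajectory):
        s = summarize_oscillations(so_trajectory)[0]
        assert s.t_quiet / s.t_active == pytest.approx(1.3, abs=0.1)

    def test_constant_trajectory_quiescent(self, default_params):
        tr = simulate(default_params, None, t_end=600.0)
        s = summarize_oscillations(tr, window=(100.0, 600.0))
        assert all(x.activity_class == "quiescent" for x in s)
        assert all(x.peak_times.size == 0 for x in s)

    def test_window_too_short(self, so_trajectory):
        with pytest.raises(InsufficientDataError):
            summarize_oscillations(so_trajectory, window=(700.0, 780.0))


class TestClassifyPattern:
    def test_single_active_is_so(self):
        pat = classify_pattern([_summary(2, np.arange(0, 500, 50.0), 50.0)])
        assert pat.label == "SO"
        assert pat.groups == ((2,),)

    def test_synchronous_pair(self):
        peaks = np.arange(0.0, 500, 50.0)
        pat = classify_pattern([
            _summary(0, peaks, 50.0), _summary(1, peaks + 1.0, 50.0)])
        assert pat.label == "s_12"

    def test_antiphase_pair(self):
        peaks = np.arange(0.0, 500, 50.0)
        pat = classify_pattern([
            _summary(0, peaks, 50.0), _summary(1, peaks + 25.0, 50.0)])
        assert pat.label == "o_12"

    def test_transitive_closure(self):
        # 0~1 and 1~2 within eta, 0-2 slightly over: one group via closure
        peaks = np.arange(0.0, 1000, 50.0)
        pat = classify_pattern([
            _summary(0, peaks, 50.0),
            _summary(1, peaks + 4.0, 50.0),
            _summary(2, peaks + 8.0, 50.0)])
        assert pat.groups == ((0, 1, 2),)
        assert pat.label == "S"

    def test_tie_at_eta_unresolved(self):
        peaks = np.arange(0.0, 1000, 50.0)
        pat = classify_pattern([
            _summary(0, peaks, 50.0), _summary(1, peaks + 5.0, 50.0)])
        assert pat.unresolved
        assert pat.label == "unresolved"

    def test_nonstationary_unresolved(self):
        peaks = np.arange(0.0, 1000, 50.0)
        pat = classify_pattern([
            _summary(0, peaks, 50.0, disp=0.1),
            _summary(1, peaks + 20.0, 50.0)])
        assert pat.unresolved

    def test_mixed_phase_partition(self):
        peaks = np.arange(0.0, 1000, 60.0)
        pat = classify_pattern([
            _summary(0, peaks, 60.0),
            _summary(1, peaks + 1.5, 60.0),
            _summary(3, peaks + 30.0, 60.0)])
        assert pat.label == "MP(12)(4)"
        assert pat.groups == ((0, 1), (3,))

    def test_label_canonical_under_permutation(self):
        peaks = np.arange(0.0, 1000, 60.0)
        base = classify_pattern([
            _summary(0, peaks, 60.0),
            _summary(1, peaks + 1.5, 60.0),
            _summary(2, peaks + 30.0, 60.0)])
        # relabel 0->4, 1->0, 2->2
        perm = [4, 0, 2, 1, 3]
        moved = classify_pattern([
            _summary(4, peaks, 60.0),
            _summary(0, peaks + 1.5, 60.0),
            _summary(2, peaks + 30.0, 60.0)])
        assert base.permuted(perm).groups == moved.groups
        assert base.permuted(perm).label == moved.label

    def test_cyclic_order_rotation_invariant(self):
        peaks = np.arange(0.0, 1000, 60.0)
        pats = []
        for shift in (0.0, 20.0, 40.0):
            pats.append(classify_pattern([
                _summary(0, peaks + (0.0 + shift) % 60, 60.0),
                _summary(1, peaks + (20.0 + shift) % 60, 60.0),
                _summary(2, peaks + (40.0 + shift) % 60, 60.0)]))
        assert len({p.cyclic_order for p in pats}) == 1


class TestEndToEnd:
    def test_op_pair_from_simulation(self, op2_trajectory):
        pat = classify_trajectory(op2_trajectory)
        assert pat.label == "o_12"
        # out-of-phase: offsets near half a period
        s = summarize_oscillations(op2_trajectory)
        d = abs(np.median(s[1].peak_times[-5:] - s[0].peak_times[-5:]))
        assert d % pat.period == pytest.approx(pat.period / 2, abs=5.0)

    def test_simultaneous_pulses_synchronise(self, default_params):
        proto = StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 100.0),
                                  StimulusPulse(1, 2.0, 20.0, 100.0)))
        tr = simulate(default_params, proto, t_end=1500.0)
        assert classify_trajectory(tr).label == "s_12"


class TestFrequencies:
    def test_interpopulation_multiplier(self):
        pat = PhasePattern(groups=((0,), (1,), (2,)), cyclic_order=(0, 1, 2),
                           period=76.9)
        pop, inter = frequencies(pat)
        assert pop == pytest.approx(13.0, abs=0.1)
        assert inter == pytest.approx(39.0, abs=0.3)

    def test_single_group_equal(self):
        pat = PhasePattern(groups=((0, 1),), cyclic_order=(0,), period=50.0)
        pop, inter = frequencies(pat)
        assert pop == inter == pytest.approx(20.0)

    def test_no_active_raises(self):
        with pytest.raises(UndefinedFrequencyError):
            frequencies(PhasePattern(groups=()))
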