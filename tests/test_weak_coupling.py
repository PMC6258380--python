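"""Phase reduction: limit cycle, adjoint, interaction functions, basins."""

import numpy as np
import pytest

from oscbind.params import preset
from oscbind.classify import classify_trajectory
from oscbind.weak_coupling import (
    NoOscillationError,
    asymptotic_time_shift,
    compute_H,
    compute_limit_cycle,
    phase_flow_attractors,
    phase_interaction,
)


class TestLimitCycle:
    def test_period_matches_paper_scale(self, limit_cycle):
        assert limit_cycle.period == pytest.approx(50.0, rel=0.1)

    def test_orbit_closes(self, limit_cycle):
        assert limit_cycle.closure_residual < 1e-6

    def test_period_matches_classifier(self, limit_cycle, default_params):
        from oscbind.model import simulate
        from oscbind.params import StimulusProtocol, StimulusPulse
        p1 = default_params.with_(N=1)
        tr = simulate(p1, StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 100.0),)),
                      t_end=1300.0)
        T_cls = classify_trajectory(tr).period
        assert abs(limit_cycle.period - T_cls) / T_cls < 0.005

    def test_nmda_peaks_near_saturation(self, limit_cycle):
        assert limit_cycle.orbit[:, 2].max() > 0.95

    def test_phase_zero_at_u_peak(self, limit_cycle):
        assert np.argmax(limit_cycle.orbit[:, 0]) == 0

    def test_no_oscillation_raises(self, default_params):
        with pytest.raises(NoOscillationError):
            compute_limit_cycle(default_params.with_(tau_i=3.0))


class TestAdjoint:
    def test_normalization_identity(self, adjoint):
        assert adjoint.normalization_residual() < 1e-6

    def test_periodicity(self, adjoint):
        T = adjoint.cycle.period
        assert np.allclose(adjoint.at(0.3 * T), adjoint.at(1.3 * T), atol=1e-6)

    @pytest.mark.parametrize("phi", [5.0, 30.0, 44.0])
    def test_impulse_response_cross_check(self, adjoint, limit_cycle,
                                          default_params, phi):
        # a small impulse delta on u at phase phi shifts the asymptotic
        # phase by delta * Z_u(phi), measured by direct simulation
        delta = 1e-4
        y0 = limit_cycle.state_at(phi)
        y1 = y0.copy()
        y1[0] += delta
        measured = asymptotic_time_shift(default_params, y0, y1)
        predicted = delta * adjoint.at(phi)[0]
        assert measured == pytest.approx(predicted, rel=0.05)


class TestInteraction:
    def test_zero_pathway_is_zero(self, limit_cycle, adjoint, default_params):
        H = compute_H(limit_cycle, adjoint, "IE", default_params)  # c_ie = 0
        assert np.allclose(H, 0.0)

    def test_vanishes_at_zero_lag(self, default_params, limit_cycle):
        inter = phase_interaction(default_params, limit_cycle)
        assert abs(inter.H[0]) < 1e-12
        assert np.allclose(inter.psi_flow([0.0]), 0.0, atol=1e-10)

    def test_periodic(self, default_params, limit_cycle):
        inter = phase_interaction(default_params, limit_cycle)
        T = inter.period
        assert inter.h(0.25 * T + T) == pytest.approx(inter.h(0.25 * T),
                                                      abs=1e-10)

    def test_drift_rate_matches_full_model(self, default_params, limit_cycle):
        # N = 2, tiny inhibitory coupling: the peak-time difference drifts
        # at the rate predicted by the odd part of H
        from oscbind.model import simulate
        from oscbind.classify import summarize_oscillations
        p = default_params.with_(N=2, c_e=0.0, c_ei=1e-4)
        inter = phase_interaction(p, limit_cycle)
        T = limit_cycle.period
        for psi0 in (15.0, 35.0):
            y = np.empty(6)
            a = limit_cycle.state_at(0.0)
            b = limit_cycle.state_at(-psi0)
            y[0], y[2], y[4] = a
            y[1], y[3], y[5] = b
            tr = simulate(p, None, t_end=4000.0, initial=y)
            s = summarize_oscillations(tr, window=(100.0, 4000.0))
            t1, t2 = s[0].peak_times, s[1].peak_times
            k = min(t1.size, t2.size)
            d = (t2[:k] - t1[:k] + T / 2) % T - T / 2
            drift = np.polyfit(t1[:k], np.unwrap(d, period=T), 1)[0]
            predicted = float(inter.h(-psi0) - inter.h(psi0))
            assert drift == pytest.approx(predicted, rel=0.10)


@pytest.fixture(scope="module")
def ei_attractors(default_params, limit_cycle):
    inter = phase_interaction(default_params.with_(c_e=0.0, c_ei=0.03),
                              limit_cycle)
    return phase_flow_attractors(inter, 3)


class TestReducedFlow:
    def test_coexisting_attractor_classes(self, ei_attractors):
        fps, basins = ei_attractors
        stable = [q.label for q in fps if q.stable]
        assert "S" in stable
        assert "OP" in stable
        assert "MP" in stable

    def test_all_attractors_have_open_basins(self, ei_attractors):
        fps, basins = ei_attractors
        stable = [q for q in fps if q.stable]
        counts = np.bincount(basins.ravel(), minlength=len(stable))
        assert np.all(counts > 0)

    def test_splay_attractor_at_third_period(self, ei_attractors, limit_cycle):
        fps, _ = ei_attractors
        T = limit_cycle.period
        splays = [q for q in fps if q.stable and q.label == "OP"]
        assert any(
            np.allclose(sorted(q.psi), [T / 3, 2 * T / 3], atol=0.05 * T)
            for q in splays)

    def test_excitation_enlarges_synchronous_basin(self, default_params,
                                                   limit_cycle, ei_attractors):
        fps_ei, b_ei = ei_attractors
        inter = phase_interaction(
            default_params.with_(c_e=0.003, c_ei=0.03), limit_cycle)
        fps_ee, b_ee = phase_flow_attractors(inter, 3)

        def s_area(fps, b):
            stable = [q for q in fps if q.stable]
            idx = [i for i, q in enumerate(stable) if q.label == "S"]
            return sum(int((b == i).sum()) for i in idx) / b.size

        assert s_area(fps_ee, b_ee) > s_area(fps_ei, b_ei)
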