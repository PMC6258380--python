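"""Core model: firing rate, mixing rule, vector field, baseline, simulate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fsolve

from oscbind.params import (
    ModelParameters,
    ParameterError,
    StimulusProtocol,
    StimulusPulse,
    preset,
)
from oscbind.model import (
    baseline_state,
    find_baseline,
    firing_rate,
    firing_rate_deriv,
    mix_fields,
    simulate,
    vector_field,
)

# baseline fixed point at the default parameter set, pinned once from an
# independent root-finding pass at tolerance 1e-13
BASELINE_DEFAULT = (0.0923911038048657, 0.2021617492690831, 0.0167856633829248)


class TestFiringRate:
    def test_zero_limit(self):
        # removable singularity: the squared rate tends to 1/beta
        assert firing_rate(0.0) == pytest.approx(1.0, abs=1e-12)
        assert firing_rate(0.0, beta=4.0) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("x", [-50.0, -5.0, -0.5, 0.1, 3.0, 10.0, 25.0])
    def test_matches_direct_formula(self, x):
        direct = np.sqrt(x / (1.0 - np.exp(-x)))
        assert firing_rate(x) == pytest.approx(direct, rel=1e-12)

    def test_suprathreshold_is_square_root(self):
        # strongly driven QIF population fires at ~sqrt(input)
        assert firing_rate(400.0) == pytest.approx(20.0, rel=1e-10)

    def test_no_overflow_large_negative(self):
        assert firing_rate(-1e4) == 0.0
        assert np.isfinite(firing_rate(np.array([-1e8, -745.0, 1e8]))).all()

    def test_series_branch_continuity(self):
        xs = np.linspace(-2e-5, 2e-5, 41)
        y = firing_rate(xs)
        assert np.all(np.diff(y) > 0)
        assert np.max(np.abs(np.diff(y, 2))) < 1e-9

    def test_derivative_consistent(self):
        for x in (-4.0, -0.3, 0.0, 2.0, 15.0):
            h = 1e-6
            fd = (firing_rate(x + h) - firing_rate(x - h)) / (2 * h)
            assert firing_rate_deriv(x) == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_invalid_gain(self):
        with pytest.raises(ParameterError):
            firing_rate(1.0, beta=0.0)


class TestMixFields:
    def test_zero_coupling_is_identity(self):
        v = np.array([3.0, 1.0, 4.0])
        assert np.allclose(mix_fields(v, 0.0), v)

    def test_uniform_vector_fixed(self):
        v = np.full(5, 2.5)
        assert np.allclose(mix_fields(v, 0.7), v)

    def test_two_population_average(self):
        assert np.allclose(mix_fields([1.0, 0.0], 1.0, N=2), [0.5, 0.5])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mix_fields([1.0, 2.0], 0.1, N=3)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=6),
           st.floats(0, 5))
    def test_convex_hull(self, values, c_z):
        out = mix_fields(values, c_z)
        assert out.min() >= min(values) - 1e-12
        assert out.max() <= max(values) + 1e-12


class TestVectorField:
    def test_baseline_is_fixed_point(self, default_params):
        y = baseline_state(default_params)
        dy = vector_field(y, default_params)
        assert np.max(np.abs(dy)) < 1e-10

    def test_nmda_saturates(self, default_params):
        N = default_params.N
        y = baseline_state(default_params)
        y[2 * N:] = 1.0
        dy = vector_field(y, default_params)
        assert np.all(dy[2 * N:] < 0)
        assert dy[2 * N] == pytest.approx(-1.0 / default_params.tau_n, rel=1e-6)

    def test_decoupled_locality(self, default_params):
        p = default_params.with_(c_e=0.0, c_ei=0.0, c_ie=0.0)
        rng = np.random.default_rng(3)
        y = rng.uniform(0.05, 2.0, 3 * p.N)
        base = vector_field(y, p)
        y2 = y.copy()
        y2[1] += 0.5      # perturb population 2's u only
        d2 = vector_field(y2, p)
        changed = np.flatnonzero(np.abs(d2 - base) > 1e-14)
        assert set(changed) <= {1, 1 + p.N, 1 + 2 * p.N}

    def test_drive_enters_u_equation_only(self, default_params):
        y = baseline_state(default_params)
        N = default_params.N
        d0 = vector_field(y, default_params)
        d1 = vector_field(y, default_params, drive=[1.0] + [0.0] * (N - 1))
        diff = np.flatnonzero(np.abs(d1 - d0) > 1e-14)
        assert list(diff) == [0]


class TestBaseline:
    def test_pinned_default_value(self, default_params):
        u, v, n = find_baseline(default_params)
        assert u == pytest.approx(BASELINE_DEFAULT[0], abs=1e-9)
        assert v == pytest.approx(BASELINE_DEFAULT[1], abs=1e-9)
        assert n == pytest.approx(BASELINE_DEFAULT[2], abs=1e-9)

    def test_independent_oracle(self, default_params):
        # brute root-finding on the raw equations, independent of
        # find_baseline's seeding strategy
        p = default_params

        def eqs(x):
            u, v, n = x
            f = lambda z: np.sqrt(z / (1 - np.exp(-z))) if abs(z) > 1e-9 else 1.0
            return [
                -u + f(p.a_ee * u - p.a_ei * v + p.a_en * n - p.theta_e),
                -v + f(p.a_ie * u - p.a_ii * v + p.a_in * n - p.theta_i),
                -n + p.a_n * u ** p.p * (1 - n),
            ]

        sol = fsolve(eqs, [0.08, 0.2, 0.02], full_output=False)
        assert np.allclose(sol, find_baseline(p), atol=1e-8)

    def test_low_rate_is_nonzero(self, default_params):
        u, _, _ = find_baseline(default_params)
        assert 0.0 < u < 1.0

    def test_coupling_independent(self, default_params):
        # mixing a uniform vector is the identity, so the uniform fixed
        # point ignores the interpopulation couplings
        a = find_baseline(default_params)
        b = find_baseline(default_params.with_(c_e=0.3, c_ei=0.5))
        assert np.allclose(a, b, atol=1e-11)


class TestSimulate:
    def test_no_stimulus_stays_at_baseline(self, default_params):
        tr = simulate(default_params, None, t_end=400.0)
        y0 = baseline_state(default_params)
        N = default_params.N
        assert np.max(np.abs(tr.u - y0[:N])) < 1e-7
        assert np.max(np.abs(tr.n - y0[2 * N:])) < 1e-7

    def test_single_pulse_selective_activation(self, so_trajectory):
        # stimulated population enters a large oscillation; others stay low
        late = so_trajectory.window(700.0)
        assert late.u[:, 0].max() > 5.0
        assert late.u[:, 1:].max() < 0.5

    def test_boundedness(self, so_trajectory):
        assert so_trajectory.n.min() >= 0.0
        assert so_trajectory.n.max() <= 1.0
        assert so_trajectory.u.min() > 0.0
        assert so_trajectory.v.min() > 0.0

    def test_permutation_equivariance(self, default_params):
        proto = StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 100.0),
                                  StimulusPulse(1, 2.0, 20.0, 625.0)))
        perm = [2, 4, 0, 1, 3]
        a = simulate(default_params, proto, t_end=900.0)
        b = simulate(default_params, proto.permuted(perm), t_end=900.0)
        bp = b.permuted(np.argsort(perm))
        # b with columns mapped back equals a to solver tolerance
        assert np.max(np.abs(a.u - b.u[:, perm])) < 1e-6
        assert np.max(np.abs(a.n - b.n[:, perm])) < 1e-6

    def test_full_synchrony_reduces_to_single_population(self, default_params):
        # identical stimuli to all populations: mixing of a uniform vector
        # is the identity, so the network follows N copies of the N=1 system
        # regardless of the interpopulation inhibition
        for c_ei in (0.03, 0.4):
            p = default_params.with_(c_ei=c_ei)
            proto = StimulusProtocol(tuple(
                StimulusPulse(j, 2.0, 20.0, 100.0) for j in range(p.N)))
            full = simulate(p, proto, t_end=700.0)
            single = simulate(p.with_(N=1),
                              StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 100.0),)),
                              t_end=700.0)
            assert np.max(np.abs(full.u - single.u[:, :1])) < 1e-5

    def test_decoupling_matches_independent_runs(self, default_params):
        p = default_params.with_(c_e=0.0, c_ei=0.0)
        proto = StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 100.0),
                                  StimulusPulse(2, 2.0, 20.0, 250.0)))
        full = simulate(p, proto, t_end=700.0)
        p1 = p.with_(N=1)
        solo0 = simulate(p1, StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 100.0),)),
                         t_end=700.0)
        solo2 = simulate(p1, StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 250.0),)),
                         t_end=700.0)
        # adaptive step sequences differ between the 15- and 3-dimensional
        # systems, so agreement is limited by accumulated phase error
        assert np.max(np.abs(full.u[:, 0] - solo0.u[:, 0])) < 1e-3
        assert np.max(np.abs(full.u[:, 2] - solo2.u[:, 0])) < 1e-3

    def test_solver_cross_check(self, default_params):
        proto = StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 100.0),))
        a = simulate(default_params, proto, t_end=600.0)
        b = simulate(default_params, proto, t_end=600.0, solver="lsoda")
        assert np.max(np.abs(a.u - b.u)) < 1e-4

    def test_step_size_robustness(self, default_params):
        from oscbind.classify import classify_trajectory
        proto = StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 100.0),))
        T = []
        for rtol, atol in ((1e-8, 1e-10), (5e-9, 5e-11)):
            tr = simulate(default_params, proto, t_end=1300.0,
                          rtol=rtol, atol=atol)
            T.append(classify_trajectory(tr).period)
        assert abs(T[0] - T[1]) / T[0] < 1e-3

    @settings(max_examples=10, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(0, 4), st.floats(0.0, 4.0), st.floats(2.0, 40.0),
                  st.floats(0.0, 400.0)),
        min_size=1, max_size=4))
    def test_boundedness_random_protocols(self, pulses):
        p = preset("paper-default")
        proto = StimulusProtocol.from_pulses(pulses)
        tr = simulate(p, proto, t_end=proto.last_offset + 300.0)
        assert tr.n.min() >= 0.0 and tr.n.max() <= 1.0
        assert tr.u.min() > 0.0 and tr.v.min() > 0.0


class TestParameters:
    def test_paper_default_values(self):
        p = preset("paper-default")
        assert (p.N, p.tau_i, p.tau_n) == (5, 12.0, 144.0)
        assert (p.c_e, p.c_ei, p.c_ie) == (0.001, 0.03, 0.0)
        assert (p.a_ee, p.a_ei, p.a_en) == (14.0, 10.0, 4.0)
        assert (p.a_ie, p.a_ii, p.a_in) == (20.0, 8.0, 0.1)
        assert (p.theta_e, p.theta_i) == (6.0, 5.0)
        assert (p.a_n, p.beta, p.p) == (2.0, 1.0, 2.0)

    def test_regime_warning(self):
        with pytest.warns(UserWarning):
            ModelParameters(tau_i=200.0, tau_n=144.0)

    def test_negative_coupling_rejected(self):
        with pytest.raises(ParameterError):
            ModelParameters(a_ee=-1.0)

    def test_negative_pulse_width_rejected(self):
        with pytest.raises(ParameterError):
            StimulusPulse(0, 1.0, -5.0, 0.0)
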