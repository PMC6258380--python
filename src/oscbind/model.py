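"""Core network model: vector field, baseline fixed point, and simulation.

Each population j carries fast excitatory (AMPA) activity u_j, inhibitory
(GABA) activity v_j and slow excitatory (NMDA) activity n_j:

    u_j' = -u_j + f(a_ee*U_j - a_ei*V_j + a_en*Nm_j - theta_e + s_j(t))
    tau_i * v_j' = -v_j + f(a_ie*W_j - a_ii*v_j + a_in*n_j - theta_i)
    tau_n * n_j' = -n_j + a_n * u_j**p * (1 - n_j)

with firing rate f(x) = sqrt(x / (1 - exp(-beta*x))) and normalised all-to-all
mixing of the fields seen by the u equation:

    mix(alpha; c_z) = (alpha_j + c_z * sum_{k != j} alpha_k) / (1 + c_z*(N-1))

U and Nm mix with c_e, V mixes with c_ei; the inhibitory equation sees the
local u_j unless the optional E->I interpopulation coupling c_ie is nonzero,
in which case W mixes with c_ie.  The NMDA equation is purely local and
saturates at 1, providing the slow positive feedback that keeps a stimulated
population persistently active after the pulse ends.

The default integration path is an adaptive Dormand-Prince 5(4) kernel
compiled with numba (the system's timescale span, 1..tau_n, is mild enough
for an explicit method at the tolerances used); ``solver="lsoda"`` routes the
same problem through ``scipy.integrate.solve_ivp`` as an independent
cross-check.  Integration is restarted at every pulse edge so the square
stimulus waveform is represented exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import ModelParameters, ParameterError, StimulusProtocol

__all__ = [
    "firing_rate",
    "mix_fields",
    "vector_field",
    "find_baseline",
    "baseline_state",
    "simulate",
    "Trajectory",
    "SimulationError",
]

# Default solver settings (0.1 ms output grid; tolerances chosen so halving
# them moves measured periods by well under 0.1%).
RTOL = 1e-8
ATOL = 1e-10
OUTPUT_STEP = 0.1
#: largest negative-n excursion tolerated before simulate() raises
N_CLAMP_TOL = 1e-6


class SimulationError(RuntimeError):
    """Integration failure (step-size collapse or accuracy loss)."""


# ---------------------------------------------------------------------------
# firing rate and mixing rule
# ---------------------------------------------------------------------------

@njit(cache=True)
def _g(x: float, beta: float) -> float:
    # squared rate: x / (1 - exp(-beta*x)), limit 1/beta at x = 0
    bx = beta * x
    if bx > 30.0:
        return x
    if bx < -30.0:
        # x/(1 - e^{-bx}) = -x e^{bx} / (1 - e^{bx}); underflows to 0+
        return -x * np.exp(bx)
    if abs(bx) < 1e-5:
        return 1.0 / beta + x / 2.0 + beta * x * x / 12.0
    return x / (1.0 - np.exp(-bx))


@njit(cache=True)
def _f(x: float, beta: float) -> float:
    return np.sqrt(_g(x, beta))


@njit(cache=True)
def _gprime(x: float, beta: float) -> float:
    bx = beta * x
    if bx > 30.0:
        return 1.0
    if bx < -30.0:
        return (1.0 - bx) * np.exp(bx)
    if abs(bx) < 1e-5:
        return 0.5 + bx / 6.0
    e = np.exp(-bx)
    d = 1.0 - e
    return (d - bx * e) / (d * d)


@njit(cache=True)
def _fprime(x: float, beta: float) -> float:
    f = _f(x, beta)
    if f < 1e-300:
        return 0.0
    return _gprime(x, beta) / (2.0 * f)


def firing_rate(x, beta: float = 1.0):
    """Noisy-QIF firing rate f(x) = sqrt(x / (1 - exp(-beta*x))).

    The expression under the root tends to x for strongly suprathreshold
    input and to 0 exponentially for strongly subthreshold input, so f is a
    smooth, strictly positive, monotone approximation of the square-root f-I
    curve of a quadratic integrate-and-fire neuron driven by noise; the
    removable singularity at 0 is filled by its limit sqrt(1/beta)."""
    if beta <= 0:
        raise ParameterError("beta must be > 0")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xf = np.atleast_1d(x)
    out = np.empty_like(xf)
    for i, xi in enumerate(xf.flat):
        out.flat[i] = _f(float(xi), beta)
    return float(out[0]) if scalar else out.reshape(x.shape)


def firing_rate_deriv(x, beta: float = 1.0):
    """Derivative of the firing rate (used by the phase reduction)."""
    if beta <= 0:
        raise ParameterError("beta must be > 0")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xf = np.atleast_1d(x)
    out = np.empty_like(xf)
    for i, xi in enumerate(xf.flat):
        out.flat[i] = _fprime(float(xi), beta)
    return float(out[0]) if scalar else out.reshape(x.shape)


def mix_fields(values, c_z: float, N: int | None = None):
    """Normalised all-to-all mixing:
    (alpha_j + c_z * sum_{k != j} alpha_k) / (1 + c_z*(N-1)).

    The output is a convex combination of the inputs: c_z = 0 is the
    identity and a uniform input vector is a fixed point for any c_z.
    """
    values = np.asarray(values, dtype=float)
    if N is None:
        N = values.shape[-1]
    elif values.shape[-1] != N:
        raise ValueError(f"expected length-{N} vector, got {values.shape}")
    if N < 1 or c_z < 0:
        raise ParameterError("require N >= 1 and c_z >= 0")
    total = values.sum(axis=-1, keepdims=True)
    return (values + c_z * (total - values)) / (1.0 + c_z * (N - 1))


# ---------------------------------------------------------------------------
# vector field
# ---------------------------------------------------------------------------

# Parameter packing for the compiled kernels (see ModelParameters.as_array):
# [N, tau_i, tau_n, c_e, c_ei, c_ie, a_ee, a_ei, a_en, a_ie, a_ii, a_in,
#  theta_e, theta_i, a_n, p, beta]

@njit(cache=True)
def _rhs(y, s, P, dy):
    N = int(P[0])
    tau_i = P[1]; tau_n = P[2]
    c_e = P[3]; c_ei = P[4]; c_ie = P[5]
    a_ee = P[6]; a_ei = P[7]; a_en = P[8]
    a_ie = P[9]; a_ii = P[10]; a_in = P[11]
    th_e = P[12]; th_i = P[13]
    a_n = P[14]; p = P[15]; beta = P[16]

    su = 0.0; sv = 0.0; sn = 0.0
    for j in range(N):
        su += y[j]; sv += y[N + j]; sn += y[2 * N + j]
    de = 1.0 + c_e * (N - 1)
    di = 1.0 + c_ei * (N - 1)
    dw = 1.0 + c_ie * (N - 1)
    for j in range(N):
        u = y[j]; v = y[N + j]; n = y[2 * N + j]
        ut = (u + c_e * (su - u)) / de
        vt = (v + c_ei * (sv - v)) / di
        nt = (n + c_e * (sn - n)) / de
        wt = (u + c_ie * (su - u)) / dw
        dy[j] = -u + _f(a_ee * ut - a_ei * vt + a_en * nt - th_e + s[j], beta)
        dy[N + j] = (-v + _f(a_ie * wt - a_ii * v + a_in * n - th_i, beta)) / tau_i
        dy[2 * N + j] = (-n + a_n * (u ** p) * (1.0 - n)) / tau_n
    return dy


def vector_field(state, params: ModelParameters, drive=None) -> np.ndarray:
    """Time derivatives of the flat state ``[u_1..u_N, v_1..v_N, n_1..n_N]``
    under constant drive ``s`` (defaults to zero)."""
    y = np.asarray(state, dtype=float).ravel()
    N = params.N
    if y.size != 3 * N:
        raise ValueError(f"state must have 3*N = {3 * N} entries, got {y.size}")
    if drive is None:
        s = np.zeros(N)
    else:
        s = np.asarray(drive, dtype=float).ravel()
        if s.size != N:
            raise ValueError(f"drive must have N = {N} entries, got {s.size}")
    dy = np.empty(3 * N)
    _rhs(y, s, params.as_array(), dy)
    return dy


# ---------------------------------------------------------------------------
# baseline fixed point
# ---------------------------------------------------------------------------

def find_baseline(params: ModelParameters, tol: float = 1e-13):
    """Uniform low fixed point (u*, v*, n*) of the undriven system.

    Because mixing a uniform vector is the identity, the baseline is
    independent of the interpopulation couplings and is found by
    root-finding the single-population equations from a small positive seed.
    u* doubles as the threshold separating the active and quiescent phases
    of an oscillation.
    """
    p = params

    def eqs(x):
        u, v, n = x
        return [
            -u + firing_rate(p.a_ee * u - p.a_ei * v + p.a_en * n - p.theta_e, p.beta),
            -v + firing_rate(p.a_ie * u - p.a_ii * v + p.a_in * n - p.theta_i, p.beta),
            -n + p.a_n * abs(u) ** p.p * (1.0 - n),
        ]

    sol = None
    for seed in ((0.1, 0.1, 0.02), (0.02, 0.02, 0.001), (0.5, 0.5, 0.3)):
        cand = root(eqs, seed, method="hybr", tol=1e-14)
        res = np.max(np.abs(eqs(cand.x)))
        if cand.success and res < tol and cand.x[0] > 0:
            if sol is None or cand.x[0] < sol[0]:
                sol = cand.x
    if sol is None:
        raise SimulationError(
            f"baseline fixed point search did not converge (residual "
            f"{np.max(np.abs(eqs(cand.x))):.3e})"
        )
    return float(sol[0]), float(sol[1]), float(sol[2])


def baseline_state(params: ModelParameters) -> np.ndarray:
    """Flat state vector with every population at the baseline fixed point."""
    u, v, n = find_baseline(params)
    N = params.N
    y = np.empty(3 * N)
    y[:N] = u
    y[N:2 * N] = v
    y[2 * N:] = n
    return y


# ---------------------------------------------------------------------------
# Dormand-Prince 5(4) kernel with cubic-Hermite dense output
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dopri_segment(y, t0, t1, s, P, rtol, atol, tgrid, out):
    """Integrate from t0 to t1 under constant drive s, filling ``out`` rows
    for the (sorted) sample times in ``tgrid``.  Returns (status, n_excess)
    where status < 0 flags step-size collapse and n_excess is the largest
    NMDA excursion outside [0, 1] that was clamped."""
    m = y.size
    N = int(P[0])
    k1 = np.empty(m); k2 = np.empty(m); k3 = np.empty(m)
    k4 = np.empty(m); k5 = np.empty(m); k6 = np.empty(m); k7 = np.empty(m)
    ytmp = np.empty(m); ynew = np.empty(m)
    _rhs(y, s, P, k1)

    t = t0
    h = min(1.0, max(t1 - t0, 1e-12))
    ig = 0
    ng = tgrid.size
    # samples exactly at the segment start
    while ig < ng and tgrid[ig] <= t0 + 1e-12:
        out[ig, :] = y
        ig += 1
    nex = 0.0
    while t < t1 - 1e-12:
        if h > t1 - t:
            h = t1 - t
        # Dormand-Prince tableau
        for i in range(m):
            ytmp[i] = y[i] + h * (0.2 * k1[i])
        _rhs(ytmp, s, P, k2)
        for i in range(m):
            ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _rhs(ytmp, s, P, k3)
        for i in range(m):
            ytmp[i] = y[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                                  + 32.0 / 9.0 * k3[i])
        _rhs(ytmp, s, P, k4)
        for i in range(m):
            ytmp[i] = y[i] + h * (19372.0 / 6561.0 * k1[i]
                                  - 25360.0 / 2187.0 * k2[i]
                                  + 64448.0 / 6561.0 * k3[i]
                                  - 212.0 / 729.0 * k4[i])
        _rhs(ytmp, s, P, k5)
        for i in range(m):
            ytmp[i] = y[i] + h * (9017.0 / 3168.0 * k1[i]
                                  - 355.0 / 33.0 * k2[i]
                                  + 46732.0 / 5247.0 * k3[i]
                                  + 49.0 / 176.0 * k4[i]
                                  - 5103.0 / 18656.0 * k5[i])
        _rhs(ytmp, s, P, k6)
        for i in range(m):
            ynew[i] = y[i] + h * (35.0 / 384.0 * k1[i]
                                  + 500.0 / 1113.0 * k3[i]
                                  + 125.0 / 192.0 * k4[i]
                                  - 2187.0 / 6784.0 * k5[i]
                                  + 11.0 / 84.0 * k6[i])
        _rhs(ynew, s, P, k7)
        # embedded error estimate
        err = 0.0
        for i in range(m):
            e = h * (71.0 / 57600.0 * k1[i]
                     - 71.0 / 16695.0 * k3[i]
                     + 71.0 / 1920.0 * k4[i]
                     - 17253.0 / 339200.0 * k5[i]
                     + 22.0 / 525.0 * k6[i]
                     - 1.0 / 40.0 * k7[i])
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            err += (e / sc) ** 2
        err = np.sqrt(err / m)
        if err <= 1.0:
            tnew = t + h
            # dense output: cubic Hermite on (y, k1) -- (ynew, k7)
            while ig < ng and tgrid[ig] <= tnew + 1e-12:
                th = (tgrid[ig] - t) / h
                h00 = (1.0 + 2.0 * th) * (1.0 - th) ** 2
                h10 = th * (1.0 - th) ** 2
                h01 = th * th * (3.0 - 2.0 * th)
                h11 = th * th * (th - 1.0)
                for i in range(m):
                    out[ig, i] = (h00 * y[i] + h10 * h * k1[i]
                                  + h01 * ynew[i] + h11 * h * k7[i])
                ig += 1
            t = tnew
            for i in range(m):
                y[i] = ynew[i]
                k1[i] = k7[i]
            # clamp NMDA into [0, 1]; record the worst excursion
            for j in range(N):
                idx = 2 * N + j
                if y[idx] < 0.0:
                    if -y[idx] > nex:
                        nex = -y[idx]
                    y[idx] = 0.0
                elif y[idx] > 1.0:
                    if y[idx] - 1.0 > nex:
                        nex = y[idx] - 1.0
                    y[idx] = 1.0
            fac = 0.9 * err ** (-0.2) if err > 1e-14 else 5.0
            h *= min(5.0, max(0.2, fac))
        else:
            h *= max(0.2, 0.9 * err ** (-0.2))
            if h < 1e-12 * max(1.0, abs(t)):
                return -1.0, t
    # samples at the segment end (within rounding)
    while ig < ng and tgrid[ig] <= t1 + 1e-9:
        out[ig, :] = y
        ig += 1
    return nex, t1


# ---------------------------------------------------------------------------
# trajectories and simulate()
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Regularly sampled (u, v, n) time courses for all populations."""

    times: np.ndarray            # (S,)
    u: np.ndarray                # (S, N)
    v: np.ndarray                # (S, N)
    n: np.ndarray                # (S, N)
    params: ModelParameters
    protocol: StimulusProtocol

    @property
    def N(self) -> int:
        return self.u.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def final_state(self) -> np.ndarray:
        return np.concatenate([self.u[-1], self.v[-1], self.n[-1]])

    def window(self, t_start: float, t_end: float | None = None) -> "Trajectory":
        mask = self.times >= t_start
        if t_end is not None:
            mask &= self.times <= t_end
        return Trajectory(self.times[mask], self.u[mask], self.v[mask],
                          self.n[mask], self.params, self.protocol)

    def permuted(self, perm: Sequence[int]) -> "Trajectory":
        """Columns reordered so population j takes the place of perm[j]."""
        inv = np.argsort(np.asarray(perm))
        return Trajectory(self.times, self.u[:, inv], self.v[:, inv],
                          self.n[:, inv], self.params, self.protocol)


def simulate(
    params: ModelParameters,
    protocol: StimulusProtocol | None = None,
    t_end: float = 1000.0,
    initial="baseline",
    t_start: float = 0.0,
    output_step: float = OUTPUT_STEP,
    rtol: float = RTOL,
    atol: float = ATOL,
    solver: str = "dopri",
) -> Trajectory:
    """Integrate the network under a stimulus protocol.

    ``initial`` is either the string ``"baseline"`` (all populations at the
    low fixed point; activity then comes only from the pulses, matching the
    loading protocol) or a flat state vector of length 3N.  Integration is
    segmented at every pulse edge so the square wave is exact, and the
    solution is sampled on a fixed ``output_step`` grid.
    """
    if protocol is None:
        protocol = StimulusProtocol()
    N = params.N
    protocol.validate(N)
    if isinstance(initial, str):
        if initial != "baseline":
            raise ValueError(f"unknown initial condition {initial!r}")
        y = baseline_state(params)
    else:
        y = np.array(initial, dtype=float).ravel()
        if y.size != 3 * N:
            raise ValueError(f"initial state must have {3 * N} entries")
        y = y.copy()
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")

    times = t_start + output_step * np.arange(
        int(np.floor((t_end - t_start) / output_step + 1e-9)) + 1)
    out = np.empty((times.size, 3 * N))
    P = params.as_array()

    seg_edges = np.concatenate([[t_start], protocol.edges(t_start, t_end), [t_end]])
    filled = 0
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        s = protocol.drive(0.5 * (a + b), N)
        hi = int(np.searchsorted(times, b + 1e-9))
        tgrid = times[filled:hi]
        if solver == "dopri":
            nex, t_reached = _dopri_segment(y, a, b, s, P, rtol, atol,
                                            tgrid, out[filled:hi])
            if nex < 0:
                raise SimulationError(f"step size collapsed at t = {t_reached:.3f}")
            if nex > N_CLAMP_TOL:
                raise SimulationError(
                    f"NMDA left [0, 1] by {nex:.2e} (> {N_CLAMP_TOL}); "
                    "tighten tolerances")
        elif solver == "lsoda":
            sol = solve_ivp(
                lambda t, yy: _rhs(yy, s, P, np.empty(3 * N)),
                (a, b), y, method="LSODA", rtol=rtol, atol=atol,
                t_eval=tgrid if tgrid.size else None, dense_output=False,
            )
            if not sol.success:
                raise SimulationError(f"LSODA failed in [{a}, {b}]: {sol.message}")
            if tgrid.size:
                out[filled:hi] = sol.y.T
            y = sol.y[:, -1].copy() if sol.y.size else y
            np.clip(y[2 * N:], 0.0, 1.0, out=y[2 * N:])
        else:
            raise ValueError(f"unknown solver {solver!r}")
        filled = hi

    return Trajectory(
        times=times,
        u=out[:, :N].copy(),
        v=out[:, N:2 * N].copy(),
        n=out[:, 2 * N:].copy(),
        params=params,
        protocol=protocol,
    )
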