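"""Weak-coupling phase reduction: limit cycle, adjoint, H functions, basins.

At weak interpopulation coupling each active population stays on the
single-population limit cycle and is described by its phase alone.  The
adjoint (infinitesimal phase response) Z(t) of the cycle, normalised so
that Z.dX/dt = 1, turns the pairwise coupling terms into interaction
functions by averaging over one period:

    H_path(phi) = (c_z/T) * integral Z_w(t) . g_path(X(t), X(t+phi)) dt

where g_path is the first-order effect of the all-to-all mixing through the
firing-rate nonlinearity (the mixing denominator is expanded to first order
in c_z, so the perturbation per partner k is c_z * (alpha_k - alpha_j)).
The phase differences psi_j = theta_j - theta_1 then obey an
(N-1)-dimensional flow whose attractors are the synchronous, splay
(out-of-phase) and mixed-phase configurations; basins are rasterised on the
(psi_2, psi_3) torus for N = 3.

Phase convention: phase 0 at the peak of u; phases are measured in time
units modulo the period T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, root

from .classify import classify_trajectory
from .model import (
    SimulationError,
    baseline_state,
    firing_rate_deriv,
    simulate,
    vector_field,
)
from .params import ModelParameters, StimulusProtocol, StimulusPulse

__all__ = [
    "LimitCycle",
    "Adjoint",
    "PhaseInteraction",
    "compute_limit_cycle",
    "compute_adjoint",
    "compute_H",
    "phase_interaction",
    "phase_flow_attractors",
    "NoOscillationError",
]

#: samples per period for orbit, adjoint and H
SAMPLES = 2048
#: basin raster resolution per torus axis
BASIN_GRID = 101


class NoOscillationError(RuntimeError):
    """No stable single-population oscillation at these parameters."""


def _single(params: ModelParameters) -> ModelParameters:
    return params.with_(N=1) if params.N != 1 else params


# ---------------------------------------------------------------------------
# limit cycle
# ---------------------------------------------------------------------------

@dataclass
class LimitCycle:
    period: float
    orbit: np.ndarray          # (SAMPLES, 3), phase 0 at the u-peak
    params: ModelParameters

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.orbit.shape[0]) * self.period / self.orbit.shape[0]

    def splines(self):
        sp = getattr(self, "_splines", None)
        if sp is None:
            t = np.append(self.times, self.period)
            y = np.vstack([self.orbit, self.orbit[:1]])
            sp = [CubicSpline(t, y[:, i], bc_type="periodic") for i in range(3)]
            self._splines = sp
        return sp

    def state_at(self, phase: float) -> np.ndarray:
        sp = self.splines()
        ph = phase % self.period
        return np.array([s(ph) for s in sp])

    @property
    def closure_residual(self) -> float:
        p = _single(self.params)
        traj = simulate(p, None, t_end=self.period, initial=self.orbit[0],
                        output_step=self.period)
        return float(np.max(np.abs(traj.final_state() - self.orbit[0])))


def _advance(params: ModelParameters, y: np.ndarray, dt: float) -> np.ndarray:
    traj = simulate(params, None, t_end=dt, initial=y, output_step=dt)
    return traj.final_state()


def _next_crossing(params, y, level, t_guess, tol=1e-10):
    """Time of the next upward crossing of u = level, by bisection."""
    # bracket: march in coarse steps until u passes level from below
    t, state = 0.0, y.copy()
    step = t_guess / 40.0
    prev_u = state[0]
    while t < 4 * t_guess:
        nxt = _advance(params, state, step)
        if prev_u < level <= nxt[0]:
            lo, hi = 0.0, step
            base = state
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                um = _advance(params, base, mid)[0] if mid > 0 else base[0]
                if um < level:
                    lo = mid
                else:
                    hi = mid
            return t + hi, _advance(params, base, hi)
        state, prev_u, t = nxt, nxt[0], t + step
    raise NoOscillationError("no section crossing found (state not oscillating)")


def compute_limit_cycle(params: ModelParameters, settle: float = 3000.0) -> LimitCycle:
    """Single-population limit cycle by long-run integration to the
    attractor followed by Poincare-section refinement of the period."""
    p = _single(params)
    proto = StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 100.0),))
    traj = simulate(p, proto, t_end=settle)
    pat = classify_trajectory(traj, window=(settle - 1200.0, settle))
    if pat.label != "SO":
        raise NoOscillationError(
            f"attractor at these parameters classifies as {pat.label!r}, "
            "not a single-population oscillation")
    T0 = pat.period
    y = traj.final_state()
    w = traj.window(settle - 1200.0, settle)
    level = 0.5 * (w.u[:, 0].max() + w.u[:, 0].min())
    # land exactly on the section, then measure one full return
    _, y_sec = _next_crossing(p, y, level, T0)
    T, y_back = _next_crossing(p, y_sec, level, T0)
    # sample one period from the section point
    dt = T / SAMPLES
    tr = simulate(p, None, t_end=T, initial=y_sec, output_step=dt)
    orbit = np.column_stack([tr.u[:SAMPLES, 0], tr.v[:SAMPLES, 0],
                             tr.n[:SAMPLES, 0]])
    # roll so that phase 0 sits at the u-peak
    k = int(np.argmax(orbit[:, 0]))
    orbit = np.roll(orbit, -k, axis=0)
    return LimitCycle(period=float(T), orbit=orbit, params=p)


# ---------------------------------------------------------------------------
# adjoint (phase response)
# ---------------------------------------------------------------------------

def _jacobian(params: ModelParameters, y: np.ndarray) -> np.ndarray:
    """3x3 Jacobian of the single-population vector field."""
    p = params
    u, v, n = y
    xe = p.a_ee * u - p.a_ei * v + p.a_en * n - p.theta_e
    xi = p.a_ie * u - p.a_ii * v + p.a_in * n - p.theta_i
    fe = firing_rate_deriv(xe, p.beta)
    fi = firing_rate_deriv(xi, p.beta)
    up = max(u, 0.0)
    return np.array([
        [-1.0 + fe * p.a_ee, -fe * p.a_ei, fe * p.a_en],
        [fi * p.a_ie / p.tau_i, (-1.0 - fi * p.a_ii) / p.tau_i,
         fi * p.a_in / p.tau_i],
        [p.a_n * p.p * up ** (p.p - 1.0) * (1.0 - n) / p.tau_n,
         0.0, (-1.0 - p.a_n * up ** p.p) / p.tau_n],
    ])


@dataclass
class Adjoint:
    cycle: LimitCycle
    Z: np.ndarray              # (SAMPLES, 3) on the cycle's phase grid

    def splines(self):
        sp = getattr(self, "_splines", None)
        if sp is None:
            T = self.cycle.period
            t = np.append(self.cycle.times, T)
            z = np.vstack([self.Z, self.Z[:1]])
            sp = [CubicSpline(t, z[:, i], bc_type="periodic") for i in range(3)]
            self._splines = sp
        return sp

    def at(self, phase: float) -> np.ndarray:
        sp = self.splines()
        ph = phase % self.cycle.period
        return np.array([s(ph) for s in sp])

    def normalization_residual(self) -> float:
        """max_t |Z(t) . F(X(t)) - 1| on the sample grid."""
        p = self.cycle.params
        F = np.array([vector_field(x, p) for x in self.cycle.orbit])
        return float(np.max(np.abs(np.einsum("ij,ij->i", self.Z, F) - 1.0)))


def compute_adjoint(cycle: LimitCycle, params: ModelParameters | None = None,
                    n_periods: int = 12, tol: float = 1e-8) -> Adjoint:
    """Adjoint Z(t) by backward integration of Z' = -J(t)^T Z.

    Backward time makes the periodic adjoint attracting; integration runs
    over ``n_periods`` periods and the last two returns must agree to
    ``tol`` (relative) or an error carrying the decay diagnostic is raised.
    The result is normalised so Z . X' = 1 (checked at every sample).
    """
    p = _single(params if params is not None else cycle.params)
    T = cycle.period
    # resample the orbit finely: the adjoint's accuracy is limited by the
    # interpolation of the fast spike, not by the ODE tolerance
    fine = 16384
    tr = simulate(p, None, t_end=T, initial=cycle.orbit[0], output_step=T / fine)
    tf = np.append(tr.times[:fine], T)
    yf = np.column_stack([tr.u[:fine, 0], tr.v[:fine, 0], tr.n[:fine, 0]])
    yf = np.vstack([yf, yf[:1]])
    sp = [CubicSpline(tf, yf[:, i], bc_type="periodic") for i in range(3)]

    def orbit_at(t):
        ph = t % T
        return np.array([s(ph) for s in sp])

    def rhs(t, z):
        return -_jacobian(p, orbit_at(t)).T @ z

    z0 = np.array([1.0, 0.0, 0.0])
    sol = solve_ivp(rhs, (n_periods * T, 0.0), z0, method="LSODA",
                    rtol=1e-12, atol=1e-14, dense_output=True)
    if not sol.success:
        raise SimulationError(f"adjoint integration failed: {sol.message}")
    zA = sol.sol(2 * T)
    zB = sol.sol(T)
    drift = np.linalg.norm(zA - zB) / max(np.linalg.norm(zB), 1e-300)
    if drift > 1e-4:
        raise SimulationError(
            f"adjoint failed to converge to a periodic solution "
            f"(relative change per period {drift:.2e})")
    ts = cycle.times
    Z = sol.sol(ts).T
    # enforce Z . F = 1 at every sample: the identity is conserved by the
    # exact adjoint flow, so this only removes slow numerical drift
    F = np.array([vector_field(x, p) for x in cycle.orbit])
    Z = Z / np.einsum("ij,ij->i", Z, F)[:, None]
    return Adjoint(cycle=cycle, Z=Z)


def asymptotic_time_shift(
    params: ModelParameters,
    y_ref: np.ndarray,
    y_pert: np.ndarray,
    t_end: float = 1500.0,
    t_late: float = 1000.0,
) -> float:
    """Asymptotic phase (time) shift between two single-population states.

    Both states are integrated to the common attractor; the shift is the
    mean difference of the late upward mid-level crossing times of u
    (reference minus perturbed, so a positive value means the perturbation
    advanced the phase).  Crossing times are linearly interpolated, which
    resolves shifts far below the output step because the systematic
    interpolation bias is common to both trajectories.
    """
    p = _single(params)
    trA = simulate(p, None, t_end=t_end, initial=np.asarray(y_ref, float))
    trB = simulate(p, None, t_end=t_end, initial=np.asarray(y_pert, float))
    u = trA.u[:, 0]
    level = 0.5 * (u.max() + u.min())

    def crossings(tr):
        uu = tr.u[:, 0]
        idx = np.flatnonzero((uu[:-1] < level) & (uu[1:] >= level))
        tc = tr.times[idx] + tr.dt * (level - uu[idx]) / (uu[idx + 1] - uu[idx])
        return tc[tc > t_late]

    ca, cb = crossings(trA), crossings(trB)
    k = min(ca.size, cb.size)
    if k < 3:
        raise NoOscillationError("too few late cycles to measure a time shift")
    return float(np.mean(ca[:k] - cb[:k]))


# ---------------------------------------------------------------------------
# interaction functions
# ---------------------------------------------------------------------------

def _circular_correlate(w: np.ndarray, a: np.ndarray) -> np.ndarray:
    """c[m] = sum_t w[t] * a[(t+m) % M]."""
    return np.fft.ifft(np.conj(np.fft.fft(w)) * np.fft.fft(a)).real


def compute_H(
    cycle: LimitCycle,
    adjoint: Adjoint,
    pathway: str,
    params: ModelParameters,
) -> np.ndarray:
    """Sampled interaction function H(phi) for one coupling pathway.

    Pathways: "EE" (c_e; the partner's u and n perturb the excitatory
    rate), "EI" (c_ei; the partner's v perturbs the excitatory rate),
    "IE" (c_ie; the partner's u perturbs the inhibitory rate).  A pathway
    whose coupling strength is zero yields the zero function.
    """
    p = _single(params)
    u, v, n = cycle.orbit.T
    M = u.size
    xe = p.a_ee * u - p.a_ei * v + p.a_en * n - p.theta_e
    if pathway == "EE":
        c = p.c_e
        w = adjoint.Z[:, 0] * firing_rate_deriv(xe, p.beta)
        terms = [(p.a_ee, u), (p.a_en, n)]
    elif pathway == "EI":
        c = p.c_ei
        w = adjoint.Z[:, 0] * firing_rate_deriv(xe, p.beta)
        terms = [(-p.a_ei, v)]
    elif pathway == "IE":
        c = p.c_ie
        xi = p.a_ie * u - p.a_ii * v + p.a_in * n - p.theta_i
        w = adjoint.Z[:, 1] * firing_rate_deriv(xi, p.beta) / p.tau_i
        terms = [(p.a_ie, u)]
    else:
        raise ValueError(f"unknown pathway {pathway!r}")
    if c == 0.0:
        return np.zeros(M)
    H = np.zeros(M)
    for coeff, alpha in terms:
        H += coeff * (_circular_correlate(w, alpha) - (w * alpha).sum())
    return c * H / M


@dataclass
class PhaseInteraction:
    """Total pairwise interaction function and the reduced phase flow."""

    cycle: LimitCycle
    phi: np.ndarray
    H: np.ndarray                      # total over pathways
    components: dict = field(default_factory=dict)

    @property
    def period(self) -> float:
        return self.cycle.period

    def spline(self):
        sp = getattr(self, "_spline", None)
        if sp is None:
            T = self.period
            sp = CubicSpline(np.append(self.phi, T), np.append(self.H, self.H[:1]),
                             bc_type="periodic")
            object.__setattr__(self, "_spline", sp)
        return sp

    def h(self, phi):
        return self.spline()(np.mod(phi, self.period))

    def odd_part(self, phi):
        return self.h(-np.asarray(phi)) - self.h(phi)

    def psi_flow(self, psi: np.ndarray) -> np.ndarray:
        """Flow of the phase differences psi_2..psi_N (psi_1 = 0)."""
        psi = np.atleast_1d(np.asarray(psi, dtype=float))
        theta = np.concatenate([[0.0], psi])
        h = self.h
        drift = np.array([
            sum(h(theta[k] - theta[j]) for k in range(theta.size) if k != j)
            for j in range(theta.size)
        ])
        return drift[1:] - drift[0]


def phase_interaction(params: ModelParameters,
                      cycle: LimitCycle | None = None) -> PhaseInteraction:
    """Limit cycle + adjoint + all nonzero coupling pathways."""
    if cycle is None:
        cycle = compute_limit_cycle(params)
    adj = compute_adjoint(cycle, params)
    comps = {pw: compute_H(cycle, adj, pw, params) for pw in ("EE", "EI", "IE")}
    H = sum(comps.values())
    return PhaseInteraction(cycle=cycle, phi=cycle.times, H=H, components=comps)


# ---------------------------------------------------------------------------
# fixed points and basins of the reduced flow
# ---------------------------------------------------------------------------

@dataclass
class PhaseFixedPoint:
    psi: tuple[float, ...]
    stable: bool
    eigenvalues: tuple[complex, ...]
    label: str                 # pattern the configuration represents


def _configuration_label(psi: tuple[float, ...], T: float,
                         tol_frac: float = 0.05) -> str:
    """S / OP / MP label of the phase configuration (0, psi_2, ..)."""
    theta = np.array([0.0, *psi]) % T
    n = theta.size
    tol = tol_frac * T
    groups = []
    used = [False] * n
    for i in range(n):
        if used[i]:
            continue
        g = [i]
        used[i] = True
        for j in range(i + 1, n):
            if not used[j]:
                d = abs((theta[j] - theta[i] + T / 2) % T - T / 2)
                if d < tol:
                    g.append(j)
                    used[j] = True
        groups.append(g)
    k = len(groups)
    if k == 1:
        return "S"
    if k == n:
        return "OP"
    return "MP"


def phase_flow_attractors(
    interaction: PhaseInteraction,
    N: int,
    seed_grid: int = 24,
    basin_grid: int = BASIN_GRID,
    rasterize: bool = True,
):
    """Fixed points (with stability) of the reduced phase-difference flow,
    and for N = 3 a basin raster on the (psi_2, psi_3) torus.

    Returns (fixed_points, basins) where basins is None for N = 2 or when
    ``rasterize`` is false; otherwise an integer array of shape
    (basin_grid, basin_grid) indexing into the stable fixed points.
    """
    if N not in (2, 3):
        raise ValueError("reduced-flow analysis supports N in {2, 3}")
    T = interaction.period
    dim = N - 1
    # scale time so the flow is O(1); direction and attractors are unchanged
    scale = max(np.max(np.abs(interaction.H)), 1e-300)

    def flow(psi):
        return interaction.psi_flow(psi) / scale

    # --- fixed points by dense seeding + root polish
    pts = []
    axes = [np.linspace(0, T, seed_grid, endpoint=False)] * dim
    for seed in np.stack(np.meshgrid(*axes), axis=-1).reshape(-1, dim):
        sol = root(flow, seed, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        psi = tuple(float(x % T) for x in sol.x)
        if any(all(abs((a - b + T / 2) % T - T / 2) < 1e-4 * T
                   for a, b in zip(psi, q.psi)) for q in pts):
            continue
        # classify by the numerically linearised flow
        eps = 1e-6 * T
        J = np.zeros((dim, dim))
        for k in range(dim):
            e = np.zeros(dim)
            e[k] = eps
            J[:, k] = (flow(np.array(psi) + e) - flow(np.array(psi) - e)) / (2 * eps)
        ev = np.linalg.eigvals(J)
        pts.append(PhaseFixedPoint(
            psi=psi, stable=bool(np.all(ev.real < 0)),
            eigenvalues=tuple(ev), label=_configuration_label(psi, T)))
    stable = [q for q in pts if q.stable]
    basins = None
    if dim == 2 and rasterize and stable:
        ax = np.linspace(0, T, basin_grid, endpoint=False)
        P2, P3 = np.meshgrid(ax, ax, indexing="ij")
        psi = np.stack([P2.ravel(), P3.ravel()], axis=-1)
        # dense lookup table; linear interpolation is ample for basins
        tab_x = np.linspace(0, T, 4097)
        tab_y = interaction.spline()(tab_x % T)

        def h(x):
            return np.interp(np.mod(x, T), tab_x, tab_y)

        def vec_flow(ps):
            t2 = ps[:, 0] % T
            t3 = ps[:, 1] % T
            h0_2 = h(-t2) + h(t3 - t2)
            h0_3 = h(-t3) + h(t2 - t3)
            h0_1 = h(t2) + h(t3)
            return np.stack([h0_2 - h0_1, h0_3 - h0_1], axis=-1) / scale

        # Heun steps; the flow is smooth and only the basin label matters
        dt = 0.02 * T
        for _ in range(2000):
            k1 = vec_flow(psi)
            k2 = vec_flow(psi + dt * k1)
            psi = psi + 0.5 * dt * (k1 + k2)
        lab = np.zeros(psi.shape[0], dtype=int)
        targets = np.array([q.psi for q in stable])
        for i in range(psi.shape[0]):
            d = np.abs((psi[i] - targets + T / 2) % T - T / 2)
            lab[i] = int(np.argmin(d.max(axis=1)))
        basins = lab.reshape(basin_grid, basin_grid)
    return pts, basins
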