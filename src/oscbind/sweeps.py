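"""Existence and stability regions of multi-population oscillatory states.

Stability is operationalised as persistence under perturbation in direct
simulation: a state is constructed by its loading protocol (evenly staggered
pulses for out-of-phase states, simultaneous pulses for synchronous ones),
settled, perturbed, and re-classified.  For synchronous states, whose loss
of stability is transverse to the synchronous manifold and can be slow near
a boundary, persistence additionally requires that the across-population
desynchronisation amplitude does not grow: its stroboscopic envelope is fit
with an exponential and the sign of the rate decides.  Boundaries in a
parameter are located by solution-following continuation -- each step seeds
the integrator with the previous converged state -- with bisection at the
loss point.  Near folds the result can depend on the seeding direction,
which is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .classify import ETA, PhasePattern, classify_trajectory
from .model import SimulationError, Trajectory, baseline_state, find_baseline, simulate
from .params import ModelParameters, StimulusProtocol, StimulusPulse

__all__ = [
    "ProbeResult",
    "StabilityInterval",
    "RegionBoundary",
    "probe_state",
    "continuation_scan",
    "trace_region",
    "capacity",
]

#: boundary bisection tolerances by parameter family
BOUNDARY_TOL = {"tau": 0.05, "coupling": 0.002}
#: deterministic perturbation amplitude used by persistence probes
PERTURB = 1e-3

_PERTURB_RNG_SEED = 20181112


def _param_tol(name: str) -> float:
    return BOUNDARY_TOL["tau"] if name.startswith("tau") else BOUNDARY_TOL["coupling"]


def _single_period(params: ModelParameters) -> float | None:
    """Period of the single-oscillator state at these parameters, or None
    if a pulse fails to ignite a persistent oscillation."""
    proto = StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 100.0),))
    try:
        traj = simulate(params, proto, t_end=1500.0)
    except SimulationError:
        return None
    pat = classify_trajectory(traj, window=(800.0, 1500.0))
    if pat.label != "SO" or not np.isfinite(pat.period):
        return None
    return float(pat.period)


def loading_protocol(params: ModelParameters, kind: str, M: int) -> StimulusProtocol | None:
    """Pinned construction protocol for an M-population state.

    OP states are loaded by M short pulses staggered by the single-population
    period divided by M (mirroring sequential loading); S states by M
    simultaneous pulses.  Returns None if no single-population oscillation
    exists to set the stagger.
    """
    if kind == "OP":
        T1 = _single_period(params)
        if T1 is None:
            return None
        if M == 1:
            return StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 300.0),))
        return StimulusProtocol(tuple(
            StimulusPulse(j, 3.0, 8.0, 300.0 + j * T1 / M) for j in range(M)))
    if kind == "S":
        return StimulusProtocol(tuple(
            StimulusPulse(j, 2.0, 20.0, 100.0) for j in range(M)))
    raise ValueError(f"kind must be 'OP' or 'S', got {kind!r}")


def _target_groups(kind: str, M: int) -> tuple[tuple[int, ...], ...]:
    if kind == "OP":
        return tuple((j,) for j in range(M))
    return (tuple(range(M)),)


def _perturbation(n: int, seed: int | None = None) -> np.ndarray:
    rng = np.random.default_rng(_PERTURB_RNG_SEED if seed is None else seed)
    return PERTURB * rng.choice([-1.0, 1.0], size=n)


def _desync_rate(traj: Trajectory, members: range | list[int]) -> float | None:
    """Exponential growth rate (1/ms) of the across-population spread of u,
    sampled stroboscopically at the peaks of the group-mean activity.
    None when the spread is at numerical noise level throughout (clearly
    synchronous) -- callers treat that as decay."""
    mem = list(members)
    um = traj.u[:, mem].mean(axis=1)
    idx, _ = find_peaks(um, prominence=0.5)
    if idx.size < 5:
        return None
    d = traj.u[idx][:, mem].std(axis=1)
    t = traj.times[idx]
    ok = (d > 1e-12) & (d < 0.5)
    if ok.sum() < 5:
        if np.all(d < 1e-8):
            return None
        ok = d > 0
    # late two-thirds: let fast-decaying transverse modes die first
    cut = t[ok][0] + (t[ok][-1] - t[ok][0]) / 3.0
    sel = ok & (traj.times[idx] >= cut)
    if sel.sum() < 4:
        sel = ok
    coef = np.polyfit(t[sel], np.log(d[sel]), 1)
    return float(coef[0])


@dataclass
class ProbeResult:
    persists: bool
    pattern: PhasePattern
    indeterminate: bool = False
    desync_rate: float | None = None
    final_state: np.ndarray | None = None


def probe_state(
    params: ModelParameters,
    kind: str,
    M: int,
    settle: float = 4000.0,
    observe: float = 2000.0,
    seed_state: np.ndarray | None = None,
    eta: float = ETA,
    perturb_seed: int | None = None,
) -> ProbeResult:
    """Does the M-population state of the given kind persist?

    The state is constructed by its loading protocol (or seeded from
    ``seed_state`` during continuation), settled, perturbed by +-1e-3 per
    variable with a fixed sign pattern, and integrated on.  It persists when
    the canonical synchrony partition is unchanged after the perturbation;
    synchronous states must additionally show a non-growing
    desynchronisation envelope.  An unresolved classification is recorded
    as indeterminate and never counted as persisting.
    """
    if M > params.N:
        raise ValueError(f"M = {M} exceeds N = {params.N}")
    target = _target_groups(kind, M)
    u_star, _, _ = find_baseline(params)
    if seed_state is None:
        proto = loading_protocol(params, kind, M)
        if proto is None:
            return ProbeResult(False, PhasePattern(groups=()), indeterminate=False)
        try:
            traj = simulate(params, proto, t_end=proto.last_offset + settle)
        except SimulationError:
            return ProbeResult(False, PhasePattern(groups=()))
        y = traj.final_state()
    else:
        try:
            traj = simulate(params, None, t_end=max(settle / 2, 1500.0),
                            initial=seed_state)
        except SimulationError:
            return ProbeResult(False, PhasePattern(groups=()))
        y = traj.final_state()
    y = y + _perturbation(y.size, perturb_seed)
    try:
        traj = simulate(params, None, t_end=observe, initial=y)
    except SimulationError:
        return ProbeResult(False, PhasePattern(groups=()))
    pat = classify_trajectory(traj, window=(observe / 3.0, observe),
                              u_star=u_star, eta=eta)
    if pat.unresolved:
        return ProbeResult(False, pat, indeterminate=True,
                           final_state=traj.final_state())
    ok = pat.groups == target
    rate = None
    if ok and kind == "S" and M >= 2:
        rate = _desync_rate(traj, range(M))
        if rate is not None and rate > 0.0:
            ok = False
    return ProbeResult(ok, pat, desync_rate=rate, final_state=traj.final_state())


@dataclass
class StabilityInterval:
    """Parameter interval over which an M-population state persists."""

    parameter: str
    kind: str
    M: int
    lower: float | None
    upper: float | None
    tol: float
    lower_successor: str | None = None   # label of the state found below
    upper_successor: str | None = None   # label of the state found above
    seeding: str = "inside-out"
    #: False when the state never persisted anywhere in the scanned range;
    #: a None bound on a found interval means the state persists through
    #: that end of the range
    found: bool = True

    @property
    def empty(self) -> bool:
        return not self.found

    def contains(self, x: float) -> bool:
        return (not self.empty and (self.lower is None or x >= self.lower)
                and (self.upper is None or x <= self.upper))


def _march(params, kind, M, name, start_val, start_state, limit, step0, tol,
           settle, observe, perturb_seed=None):
    """March the parameter from a persisting start towards ``limit``;
    bisect the loss point.  Returns (bound, successor_label) where bound is
    None if the state persists through the limit."""
    direction = 1.0 if limit > start_val else -1.0
    val, state = start_val, start_state
    step = step0
    bad_val, bad_label = None, None
    while True:
        nxt = val + direction * step
        if (nxt - limit) * direction >= 0:
            nxt = limit
        r = probe_state(params.with_(**{name: nxt}), kind, M,
                        settle=settle, observe=observe, seed_state=state,
                        perturb_seed=perturb_seed)
        if r.persists:
            val, state = nxt, r.final_state
            if nxt == limit:
                return None, None
        else:
            bad_val, bad_label = nxt, r.pattern.label
            break
    # bisect between val (persists, with seed state) and bad_val
    while abs(bad_val - val) > tol:
        mid = 0.5 * (val + bad_val)
        r = probe_state(params.with_(**{name: mid}), kind, M,
                        settle=settle, observe=observe, seed_state=state,
                        perturb_seed=perturb_seed)
        if r.persists:
            val, state = mid, r.final_state
        else:
            bad_val, bad_label = mid, r.pattern.label
    return 0.5 * (val + bad_val), bad_label


def continuation_scan(
    params: ModelParameters,
    kind: str,
    M: int,
    parameter: str,
    prange: tuple[float, float],
    step0: float | None = None,
    tol: float | None = None,
    settle: float = 2500.0,
    observe: float = 2500.0,
    perturb_seed: int | None = None,
) -> StabilityInterval:
    """Persistence interval of the M-state in one parameter.

    Starts from the current parameter value (which must lie in ``prange``),
    verifies persistence there, then marches outward in both directions with
    solution-following restarts, bisecting each boundary to ``tol``.  A
    bound equal to None means the state persists through that end of the
    range.  If the state does not persist at the start the interval is
    returned empty rather than raising.
    """
    lo, hi = prange
    x0 = getattr(params, parameter)
    if not (lo <= x0 <= hi):
        raise ValueError(f"current {parameter} = {x0} outside range {prange}")
    if tol is None:
        tol = _param_tol(parameter)
    if step0 is None:
        step0 = max(8 * tol, (hi - lo) / 25.0)
    r0 = probe_state(params, kind, M, settle=4000.0, observe=observe,
                     perturb_seed=perturb_seed)
    if not r0.persists:
        return StabilityInterval(parameter, kind, M, None, None, tol,
                                 found=False)
    up, up_lab = _march(params, kind, M, parameter, x0, r0.final_state, hi,
                        step0, tol, settle, observe, perturb_seed)
    dn, dn_lab = _march(params, kind, M, parameter, x0, r0.final_state, lo,
                        step0, tol, settle, observe, perturb_seed)
    return StabilityInterval(parameter, kind, M, lower=dn, upper=up, tol=tol,
                             lower_successor=dn_lab, upper_successor=up_lab)


@dataclass
class RegionBoundary:
    """Boundary of an M-state existence region in a parameter plane."""

    kind: str
    M: int
    x_parameter: str
    y_parameter: str
    x_values: np.ndarray
    intervals: list[StabilityInterval]

    def lower_curve(self) -> list[tuple[float, float]]:
        return [(float(x), iv.lower) for x, iv in zip(self.x_values, self.intervals)
                if not iv.empty and iv.lower is not None]

    def upper_curve(self) -> list[tuple[float, float]]:
        return [(float(x), iv.upper) for x, iv in zip(self.x_values, self.intervals)
                if not iv.empty and iv.upper is not None]


def trace_region(
    params: ModelParameters,
    kind: str,
    M: int,
    x_parameter: str,
    y_parameter: str,
    x_values,
    y_range: tuple[float, float],
    **scan_kw,
) -> RegionBoundary:
    """Run a continuation scan in ``y_parameter`` at each ``x_parameter``
    grid value, assembling an existence-region boundary."""
    x_values = np.asarray(x_values, dtype=float)
    intervals = []
    for x in x_values:
        p = params.with_(**{x_parameter: float(x)})
        y0 = getattr(p, y_parameter)
        lo, hi = y_range
        if not (lo <= y0 <= hi):
            p = p.with_(**{y_parameter: 0.5 * (lo + hi)})
        intervals.append(continuation_scan(p, kind, M, y_parameter, y_range,
                                           **scan_kw))
    return RegionBoundary(kind, M, x_parameter, y_parameter, x_values, intervals)


def capacity(
    params: ModelParameters,
    eta: float = ETA,
    max_m: int | None = None,
    perturb_seed: int | None = None,
) -> tuple[int, int]:
    """(measured capacity, theoretical ceiling).

    The measured capacity is the largest M for which the M-OP state
    persists, probing M = 1 upward.  The ceiling floor(T/eta) is the number
    of peaks separated by the synchrony tolerance that fit in one period of
    the capacity state.
    """
    if max_m is None:
        max_m = params.N
    best, best_T = 0, None
    for M in range(1, max_m + 1):
        r = probe_state(params, "OP", M, perturb_seed=perturb_seed)
        if not r.persists:
            break
        best, best_T = M, r.pattern.period
    if best == 0 or best_T is None or not np.isfinite(best_T):
        return 0, 0
    return best, int(np.floor(best_T / eta))
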