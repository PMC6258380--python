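"""Oscillation summaries and phase-pattern classification.

A settled trajectory is reduced per population to peak times, period T,
active-phase duration T_a (time with u above the baseline fixed point u*),
quiescent-phase duration T_q = T - T_a, and an activity class.  Active
populations are then partitioned into synchrony groups: two populations are
synchronous when their cyclic peak-time offsets agree within the synchrony
tolerance eta (default 5 ms, inside the 6-10 ms windows over which cortical
neurons have been observed to phase-lock).  The resulting pattern carries the
label grammar used throughout: SO (single oscillator), o_jk / O (out-of-phase
diad / triad), s_jk / S (synchronous diad / triad), and MP partitions such as
(12)(3) for mixed-phase states.  Population indices in labels are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .model import Trajectory, find_baseline

__all__ = [
    "OscillationSummary",
    "PhasePattern",
    "summarize_oscillations",
    "classify_pattern",
    "classify_trajectory",
    "frequencies",
    "InsufficientDataError",
    "UndefinedFrequencyError",
]

#: synchrony tolerance in ms (config knob; below the 6 ms robust-window grain)
ETA = 5.0
#: a population is active when its mean peak u exceeds u* + ACTIVE_DELTA
ACTIVE_DELTA = 1.0
#: peak-interval dispersion (std/mean) bound for a stationary oscillation
STATIONARY_DISPERSION = 0.02
#: settling time discarded after the last stimulus offset before classifying
SETTLE = 500.0


class InsufficientDataError(ValueError):
    """Classification window too short for the oscillation present."""


class UndefinedFrequencyError(ValueError):
    """Frequency requested for a pattern with no active populations."""


@dataclass
class OscillationSummary:
    """Per-population cycle statistics over a stationary window."""

    population: int
    peak_times: np.ndarray
    period: float          # mean peak-to-peak interval (nan if < 2 peaks)
    t_active: float        # mean time per cycle with u > u*
    t_quiet: float         # mean time per cycle with u <= u*
    amplitude: float       # mean peak height
    activity_class: str    # "quiescent" | "low_amplitude" | "active"
    dispersion: float      # std/mean of peak intervals

    @property
    def active(self) -> bool:
        return self.activity_class == "active"

    @property
    def stationary(self) -> bool:
        return self.active and self.dispersion < STATIONARY_DISPERSION


def _refine_peak(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Quadratic interpolation of a grid local maximum."""
    if i == 0 or i == len(y) - 1:
        return float(t[i])
    d = (y[i - 1] - 2.0 * y[i] + y[i + 1])
    if d >= 0:
        return float(t[i])
    return float(t[i] + 0.5 * (y[i - 1] - y[i + 1]) / d * (t[1] - t[0]))


def summarize_oscillations(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    u_star: float | None = None,
    active_delta: float = ACTIVE_DELTA,
) -> list[OscillationSummary]:
    """Reduce each population's u time course to oscillation statistics.

    ``window`` defaults to (last stimulus offset + SETTLE, end of trajectory)
    so transients are excluded.  T_a counts time above ``u_star`` with linear
    interpolation at threshold crossings, averaged over the complete cycles
    between the first and last detected peak.
    """
    if u_star is None:
        u_star, _, _ = find_baseline(traj.params)
    if window is None:
        window = (traj.protocol.last_offset + SETTLE, float(traj.times[-1]))
    w = traj.window(*window)
    if w.times.size < 10:
        raise InsufficientDataError(
            f"window {window} contains only {w.times.size} samples")
    t = w.times
    dt = w.dt
    out: list[OscillationSummary] = []
    thresh = u_star + active_delta
    for j in range(w.N):
        u = w.u[:, j]
        idx, _ = find_peaks(u, prominence=0.05)
        peaks = np.array([_refine_peak(t, u, i) for i in idx])
        heights = u[idx]
        if idx.size >= 2:
            ivals = np.diff(peaks)
            period = float(ivals.mean())
            disp = float(ivals.std() / period) if period > 0 else np.inf
        else:
            period, disp = float("nan"), float("inf")
        if idx.size >= 2 and heights.mean() > thresh:
            cls = "active"
            # complete cycles between first and last peak
            lo, hi = idx[0], idx[-1]
            seg = u[lo:hi + 1]
            above = seg > u_star
            frac = float(above.mean())
            # refine with crossing interpolation
            cross = np.flatnonzero(np.diff(above.astype(int)))
            corr = 0.0
            for c in cross:
                y0, y1 = seg[c], seg[c + 1]
                th = (u_star - y0) / (y1 - y0)
                corr += (0.5 - th) if y1 > y0 else (th - 0.5)
            frac += corr / max(len(seg) - 1, 1)
            ncyc = idx.size - 1
            span = peaks[-1] - peaks[0]
            t_active = frac * span / ncyc
            t_quiet = span / ncyc - t_active
            if w.times[-1] - w.times[0] < 3 * period:
                raise InsufficientDataError(
                    f"window shorter than 3 periods ({period:.1f} ms) for "
                    f"population {j + 1}")
        elif idx.size >= 2 and (u.max() - u.min()) > 0.25:
            # genuine small oscillation around the low state; quiescent
            # populations pick up a ripple of order the baseline rate
            # (~0.05-0.1) through the coupled inhibition, which does not count
            cls = "low_amplitude"
            t_active = t_quiet = float("nan")
        else:
            cls = "quiescent"
            period = float("nan")
            t_active = t_quiet = float("nan")
            peaks = np.array([])
            disp = float("inf")
        out.append(OscillationSummary(
            population=j, peak_times=peaks, period=period,
            t_active=t_active, t_quiet=t_quiet,
            amplitude=float(heights.mean()) if idx.size else 0.0,
            activity_class=cls, dispersion=disp,
        ))
    return out


# ---------------------------------------------------------------------------
# phase patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhasePattern:
    """Partition of the active populations into synchrony groups.

    ``groups`` holds 0-based population indices, canonicalised: members
    sorted within each group, groups sorted by smallest member.
    ``cyclic_order`` lists the groups (as indices into ``groups``) in the
    order they fire within one network period, started at the group holding
    the smallest active population.  ``label`` follows the field grammar
    with 1-based indices: SO, o_12, s_12, O, S, MP(12)(3), ...
    """

    groups: tuple[tuple[int, ...], ...]
    cyclic_order: tuple[int, ...] = ()
    period: float = float("nan")
    unresolved: bool = False

    @property
    def active_populations(self) -> tuple[int, ...]:
        return tuple(sorted(j for g in self.groups for j in g))

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def partition(self) -> str:
        return "".join(
            "(" + "".join(str(j + 1) for j in g) + ")" for g in self.groups)

    @property
    def label(self) -> str:
        if self.unresolved:
            return "unresolved"
        k = len(self.active_populations)
        if k == 0:
            return "baseline"
        if k == 1:
            return "SO"
        sizes = sorted(len(g) for g in self.groups)
        if len(self.groups) == 1:           # fully synchronous
            if k == 2:
                return "s_" + "".join(str(j + 1) for j in self.groups[0])
            return "S"
        if sizes[-1] == 1:                  # fully out-of-phase
            if k == 2:
                return "o_" + "".join(str(j + 1) for j in self.active_populations)
            if k == 3:
                return "O"
            return "o_" + "".join(str(j + 1) for j in self.active_populations)
        return "MP" + self.partition

    def permuted(self, perm: Sequence[int]) -> "PhasePattern":
        """Pattern after relabeling population j -> perm[j]."""
        new = [tuple(sorted(int(perm[j]) for j in g)) for g in self.groups]
        order = list(self.cyclic_order)
        pairs = sorted(range(len(new)), key=lambda i: new[i])
        remap = {old: new_i for new_i, old in enumerate(pairs)}
        groups = tuple(new[i] for i in pairs)
        cyc = tuple(remap[i] for i in order)
        cyc = _canonical_cycle(groups, cyc)
        return PhasePattern(groups, cyc, self.period, self.unresolved)

    def same_partition(self, other: "PhasePattern") -> bool:
        return self.groups == other.groups and self.unresolved == other.unresolved


def _canonical_cycle(groups, order):
    """Rotate the cyclic order to start at the group with the smallest
    member (labels are invariant under rotation)."""
    if not order:
        return tuple(order)
    start = min(range(len(groups)), key=lambda i: groups[i])
    order = list(order)
    k = order.index(start)
    return tuple(order[k:] + order[:k])


def _circular_offset(a: np.ndarray, b: np.ndarray, T: float) -> float:
    """Median circular peak-time offset of population b relative to a."""
    ds = []
    for tb in b:
        k = np.argmin(np.abs(a - tb))
        d = (tb - a[k] + T / 2.0) % T - T / 2.0
        ds.append(d)
    return float(np.median(ds))


def classify_pattern(
    summaries: list[OscillationSummary],
    eta: float = ETA,
    period_tol: float = 0.02,
) -> PhasePattern:
    """Group active populations by peak-time synchrony.

    Two active populations are grouped when the magnitude of their median
    circular peak-time offset is within ``eta``; grouping is the transitive
    closure.  If any between-group offset then fails to exceed ``eta`` (ties
    at the tolerance included), the result is flagged unresolved rather than
    silently forced to S or OP.  All active populations must be stationary
    and share one period to within ``period_tol``.
    """
    act = [s for s in summaries if s.active]
    if not act:
        return PhasePattern(groups=())
    if len(act) == 1:
        return PhasePattern(groups=((act[0].population,),),
                            cyclic_order=(0,), period=act[0].period)
    periods = np.array([s.period for s in act])
    T = float(periods.mean())
    if any(not s.stationary for s in act) or np.ptp(periods) / T > period_tol:
        return PhasePattern(
            groups=tuple((s.population,) for s in act), unresolved=True,
            period=T)
    k = len(act)
    off = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = _circular_offset(act[i].peak_times, act[j].peak_times, T)
            off[i, j] = off[j, i] = abs(d)
    # union-find transitive closure of |offset| <= eta
    parent = list(range(k))

    def root(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tie_tol = 1e-6
    for i in range(k):
        for j in range(i + 1, k):
            if off[i, j] <= eta - tie_tol:
                parent[root(i)] = root(j)
    groups_map: dict[int, list[int]] = {}
    for i in range(k):
        groups_map.setdefault(root(i), []).append(i)
    members = list(groups_map.values())
    # between-group separation must exceed eta (ties -> unresolved)
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            for i in members[a]:
                for j in members[b]:
                    if off[i, j] <= eta + tie_tol:
                        return PhasePattern(
                            groups=tuple(
                                tuple(sorted(act[i].population for i in m))
                                for m in sorted(members, key=lambda m: min(m))),
                            unresolved=True, period=T)
    groups = tuple(sorted(
        (tuple(sorted(act[i].population for i in m)) for m in members)))
    # cyclic order by phase of each group's first member relative to group 0
    ref_i = next(i for i in range(k) if act[i].population == groups[0][0])
    ref = act[ref_i].peak_times
    phases = []
    for g in groups:
        i = next(i for i in range(k) if act[i].population == g[0])
        phases.append(_circular_offset(ref, act[i].peak_times, T) % T)
    order = tuple(int(i) for i in np.argsort(phases))
    return PhasePattern(groups=groups, cyclic_order=_canonical_cycle(groups, order),
                        period=T)


def classify_trajectory(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    u_star: float | None = None,
    eta: float = ETA,
    active_delta: float = ACTIVE_DELTA,
) -> PhasePattern:
    """summarize_oscillations followed by classify_pattern."""
    summaries = summarize_oscillations(traj, window=window, u_star=u_star,
                                       active_delta=active_delta)
    return classify_pattern(summaries, eta=eta)


def frequencies(pattern: PhasePattern, T: float | None = None) -> tuple[float, float]:
    """(population frequency, interpopulation frequency) in Hz.

    The interpopulation frequency -- the rate at which *some* group of the
    cycle peaks -- is the population frequency multiplied by the number of
    mutually out-of-phase groups.
    """
    if T is None:
        T = pattern.period
    if not pattern.groups or not np.isfinite(T) or T <= 0:
        raise UndefinedFrequencyError("no active oscillation to measure")
    pop = 1000.0 / T
    return pop, pop * pattern.n_groups
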