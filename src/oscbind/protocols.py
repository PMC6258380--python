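"""Stimulus protocol construction, onset scans, and switching thresholds.

Because the outcome of stimulating an oscillating network depends on the
phase at which the pulse arrives, operations are characterised by scanning
the pulse onset across one network period and keeping only outcomes that
are robust over a contiguous onset window of at least 6 ms -- the smallest
interval of time cortical neurons phase-locking within a gamma cycle could
plausibly resolve.  The same machinery locates, by bisection, the minimal
pulse amplitude that switches which of two competing populations is active.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import Trajectory, baseline_state, find_baseline, simulate
from .params import ModelParameters, StimulusProtocol, StimulusPulse, preset
from .classify import (
    ACTIVE_DELTA,
    ETA,
    SETTLE,
    PhasePattern,
    classify_trajectory,
)

__all__ = [
    "OnsetScanResult",
    "onset_scan",
    "find_switching_amplitude",
    "scenario_library",
    "settled_state",
    "ProtocolError",
    "ROBUST_WINDOW",
]

#: minimal onset-window length (ms) for an outcome to count as robust
ROBUST_WINDOW = 6.0
#: onset grid step (ms), finer than the robustness grain
ONSET_STEP = 1.0

#: pinned single-pulse classes, (amplitude, width), calibrated once by onset
#: scans at the default parameter set:
#:   weak        -- subthreshold; never changes the pattern
#:   ignite      -- activates a quiescent population without quenching
#:   load        -- short pulse used for evenly staggered out-of-phase loading
#:   stagger     -- moderate pulse interleaving a new item into the cycle
#:   bind        -- re-times an active population onto a partner (o -> s,
#:                  s + new -> S); windows are narrow (~6-7 ms)
#:   wts         -- winner-take-some: quenches some active populations
#:   wta         -- winner-take-all: same amplitude as wts but much wider;
#:                  the stimulated population ends as the only active one
PULSE_CLASSES: dict[str, tuple[float, float]] = {
    "weak": (1.0, 10.0),
    "ignite": (2.0, 20.0),
    "load": (3.0, 8.0),
    "stagger": (3.5, 30.0),
    "bind": (12.0, 40.0),
    "wts": (30.0, 50.0),
    "wta": (30.0, 200.0),
}


class ProtocolError(RuntimeError):
    """Background protocol failed to produce the required stationary state."""


def settled_state(
    params: ModelParameters,
    background: StimulusProtocol,
    settle: float = SETTLE,
    expect: str | None = None,
    **classify_kw,
) -> tuple[np.ndarray, PhasePattern]:
    """Run the background protocol past its settling window and return the
    final state together with its stationary classification."""
    t_end = background.last_offset + settle + 700.0
    traj = simulate(params, background, t_end=t_end)
    pat = classify_trajectory(traj, **classify_kw)
    if pat.unresolved:
        raise ProtocolError(
            f"background protocol is not stationary (pattern unresolved)")
    if expect is not None and pat.label != expect:
        raise ProtocolError(
            f"background protocol settled to {pat.label!r}, expected {expect!r}")
    return traj.final_state(), pat


@dataclass
class OnsetScanResult:
    """Outcome of sweeping a pulse's onset across a range of phases."""

    pulse: tuple[float, float]              # (amplitude, width)
    target: int
    onsets: np.ndarray                      # onset times scanned
    patterns: list[PhasePattern]            # resultant pattern per onset
    robust_threshold: float = ROBUST_WINDOW
    circular: bool = True                   # scan range covers one period

    def _runs(self) -> list[tuple[int, int]]:
        key = lambda p: (p.groups, p.cyclic_order, p.unresolved)
        runs = []
        i, n = 0, len(self.onsets)
        while i < n:
            j = i
            while j + 1 < n and key(self.patterns[j + 1]) == key(self.patterns[i]):
                j += 1
            runs.append((i, j))
            i = j + 1
        # a scan over one full period is circular: merge wrap-around runs
        if self.circular and len(runs) > 1:
            (i0, j0), (i1, j1) = runs[0], runs[-1]
            if key(self.patterns[i0]) == key(self.patterns[i1]):
                runs[0] = (i1 - len(self.onsets), j0)
                runs.pop()
        return runs

    @property
    def robust_windows(self) -> list[tuple[float, float, PhasePattern]]:
        """Maximal contiguous onset intervals (>= threshold) with one
        resultant pattern (identity: synchrony partition + cyclic order).
        A wrapped window is reported with a negative start."""
        step = float(self.onsets[1] - self.onsets[0]) if len(self.onsets) > 1 else 0.0
        span_total = float(self.onsets[-1] - self.onsets[0])
        wins = []
        for i, j in self._runs():
            t0 = float(self.onsets[i]) if i >= 0 else float(
                self.onsets[i] - span_total - step)
            t1 = float(self.onsets[j])
            if (t1 - t0 >= self.robust_threshold - 1e-9
                    and not self.patterns[j].unresolved):
                wins.append((t0, t1, self.patterns[j]))
        return wins

    def outcomes(self) -> dict[str, float]:
        """Map label -> total robust onset time yielding it."""
        out: dict[str, float] = {}
        for a, b, pat in self.robust_windows:
            out[pat.label] = out.get(pat.label, 0.0) + (b - a)
        return out


def onset_scan(
    params: ModelParameters,
    background: StimulusProtocol,
    pulse: tuple[float, float],
    target: int,
    onset_range: tuple[float, float] | None = None,
    grid_step: float = ONSET_STEP,
    settle: float = SETTLE,
    observe: float = 700.0,
    eta: float = ETA,
) -> OnsetScanResult:
    """Classify the settled outcome of one extra pulse for each onset.

    The background protocol is integrated once to a stationary state; each
    scanned onset then continues from that state, so the scan cost is one
    short simulation per grid point.  ``onset_range`` defaults to one network
    period of the background pattern (one period covers all phases).
    """
    y0, bg_pat = settled_state(params, background, settle=settle, eta=eta)
    if onset_range is None:
        T = bg_pat.period if np.isfinite(bg_pat.period) else 50.0
        onset_range = (0.0, float(np.ceil(T)))
    onsets = np.arange(onset_range[0], onset_range[1] + 1e-9, grid_step)
    amp, width = pulse
    patterns = []
    u_star, _, _ = find_baseline(params)
    for t0 in onsets:
        proto = StimulusProtocol((StimulusPulse(target, amp, width, float(t0)),))
        traj = simulate(params, proto, t_end=float(t0) + width + settle + observe,
                        initial=y0)
        patterns.append(classify_trajectory(
            traj, window=(t0 + width + settle, traj.times[-1]),
            u_star=u_star, eta=eta))
    return OnsetScanResult(pulse=pulse, target=target, onsets=onsets,
                           patterns=patterns)


# ---------------------------------------------------------------------------
# switching-amplitude bisection (two-population competition)
# ---------------------------------------------------------------------------

def _persistently_active(traj: Trajectory, u_star: float,
                         delta: float = ACTIVE_DELTA) -> np.ndarray:
    """Boolean per population: mean u over the final 300 ms exceeds
    u* + delta.  Covers both oscillatory and steady up-state activity."""
    m = traj.times >= traj.times[-1] - 300.0
    return traj.u[m].mean(axis=0) > u_star + delta


def find_switching_amplitude(
    params: ModelParameters,
    width: float = 50.0,
    source: int = 0,
    target: int = 1,
    bracket: tuple[float, float] = (0.25, 64.0),
    rtol: float = 1e-2,
    settle: float = 800.0,
    ignite: tuple[float, float] = PULSE_CLASSES["ignite"],
) -> float:
    """Minimal amplitude of a single square pulse to ``target`` that switches
    which population is persistently active.

    The source population is first activated and allowed to settle (to its
    oscillation or, at strong mutual inhibition, its steady up state).  An
    amplitude ``A`` "switches" when, after settling, the target is
    persistently active and the source has returned to baseline.  The
    threshold is bisected to relative tolerance ``rtol``; if no interpopulation
    inhibition is present the source can never be quenched and ``inf`` is
    returned.
    """
    if params.c_ei == 0.0 and params.c_ie == 0.0:
        return float("inf")
    u_star, _, _ = find_baseline(params)
    amp0, w0 = ignite
    bg = StimulusProtocol((StimulusPulse(source, amp0, w0, 100.0),))
    traj = simulate(params, bg, t_end=100.0 + w0 + settle + 400.0)
    act = _persistently_active(traj, u_star)
    if not act[source]:
        raise ProtocolError("source population failed to activate")
    y0 = traj.final_state()

    def switched(A: float) -> bool:
        proto = StimulusProtocol((StimulusPulse(target, A, width, 50.0),))
        tr = simulate(params, proto, t_end=50.0 + width + settle + 400.0,
                      initial=y0)
        a = _persistently_active(tr, u_star)
        return bool(a[target] and not a[source])

    lo, hi = bracket
    s_lo, s_hi = switched(lo), switched(hi)
    if s_lo or not s_hi:
        raise ProtocolError(
            f"bracket {bracket} does not straddle the switching threshold "
            f"(switched(lo)={s_lo}, switched(hi)={s_hi})")
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if switched(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


# ---------------------------------------------------------------------------
# scenario library -- pinned, deterministic stimulus scripts
# ---------------------------------------------------------------------------

def _p(target, amp, width, onset):
    return StimulusPulse(target, amp, width, onset)


def _seq(*pulses) -> StimulusProtocol:
    return StimulusProtocol(tuple(pulses))


#: single-population period at the default parameter set (ms), used for
#: the evenly staggered loading stagger
T_SINGLE = 49.88

#: expected settled pattern label of each scenario, and the measured onset
#: window (ms) over which the pinned outcome is robust; windows below 6 ms
#: reflect intrinsically phase-sensitive operations
SCENARIO_EXPECT: dict[str, tuple[str, float]] = {
    "fig2A_op2": ("o_12", 40.0),
    "fig2B_op3": ("O", 7.0),
    "fig2C_op3": ("O", 17.0),
    "fig2DE_wts": ("o_23", 22.0),
    "fig2F_wta": ("SO", 50.0),
    "fig4A_s_simultaneous": ("s_12", 50.0),
    "fig4B_s_from_op": ("s_12", 6.0),
    "fig4C_s_sequential": ("s_12", 4.0),
    "fig5A_capacity_forgetting": ("O", 1.0),
    "fig5C_mp_pairs": ("MP(12)(34)", 10.0),
    "fig8A_feature_bind": ("S", 6.0),
    "fig8B_feature_unbind": ("o_12", 16.0),
    "fig9_variable_binding": ("MP(12)(3)", 8.0),
}


def scenario_library(params: ModelParameters | None = None) -> dict[str, StimulusProtocol]:
    """Named, version-pinned stimulus scripts reproducing the canonical
    dynamic regimes: out-of-phase loading (with both activation orderings of
    a third item), winner-take-some and winner-take-all interference,
    synchronous binding by simultaneous and by sequential stimuli,
    mixed-phase formation, forgetting at capacity, and the feature/variable
    binding demonstrations.

    Onsets were pinned once by onset scans at the default parameter set
    (single-population period 49.9 ms).  ``SCENARIO_EXPECT`` records each
    script's settled pattern and the measured robust onset window; most
    admit the 6 ms robustness criterion, while the sequential-binding and
    forgetting-at-capacity operations are intrinsically phase-sensitive
    and sit on narrower windows.
    """
    ig_a, ig_w = PULSE_CLASSES["ignite"]     # (2, 20)
    ld_a, ld_w = PULSE_CLASSES["load"]       # (3, 8)
    sg_a, sg_w = PULSE_CLASSES["stagger"]    # (3.5, 30)
    bd_a, bd_w = PULSE_CLASSES["bind"]       # (12, 40)
    ws_a, ws_w = PULSE_CLASSES["wts"]        # (30, 50)
    wa_a, wa_w = PULSE_CLASSES["wta"]        # (30, 200)
    third = T_SINGLE / 3.0
    # backgrounds (settled 1200 ms after the last pulse offset)
    op2 = (_p(0, ig_a, ig_w, 100.0), _p(1, ig_a, ig_w, 625.0))   # -> o_12 @1845
    s2 = (_p(0, ig_a, ig_w, 100.0), _p(1, ig_a, ig_w, 100.0))    # -> s_12 @1320
    op3 = (_p(0, ld_a, ld_w, 300.0), _p(1, ld_a, ld_w, 300.0 + third),
           _p(2, ld_a, ld_w, 300.0 + 2 * third))                 # -> O @1541.25
    lib = {
        # Two-item loading: second pulse lands mid-cycle -> o_12
        "fig2A_op2": _seq(*op2),
        # Third item interleaved; onset picks the activation ordering
        "fig2B_op3": _seq(*op2, _p(2, sg_a, sg_w, 1845.0 + 3.0)),
        "fig2C_op3": _seq(*op2, _p(2, sg_a, sg_w, 1845.0 + 25.0)),
        # Winner-take-some: strong pulse quenches one of the two items
        "fig2DE_wts": _seq(*op2, _p(2, ws_a, ws_w, 1845.0 + 20.0)),
        # Winner-take-all: same amplitude, four times the width
        "fig2F_wta": _seq(*op2, _p(2, wa_a, wa_w, 1845.0 + 20.0)),
        # Binding by simultaneous stimulation -> s_12
        "fig4A_s_simultaneous": _seq(*s2),
        # Restimulating one member of an OP pair re-times it -> s_12
        "fig4B_s_from_op": _seq(*op2, _p(0, bd_a, bd_w, 1845.0 + 31.0)),
        # A small pulse near the upstroke of a running oscillation binds
        "fig4C_s_sequential": _seq(_p(0, ig_a, ig_w, 100.0),
                                   _p(1, ig_a, ig_w, 1320.0 + 27.0)),
        # At capacity (3 OP), a modest 4th stimulus quenches one original
        # item; the network stays at 3 OP with a different membership
        "fig5A_capacity_forgetting": _seq(
            *op3, _p(3, 2.8, 20.0, 1541.25 + 5.0)),
        # Stimulating a quiescent population at an MP state produces two
        # synchronous pairs oscillating out of phase
        "fig5C_mp_pairs": _seq(
            *s2, _p(2, ig_a, ig_w, 1326.0),
            _p(3, ig_a, ig_w, 2546.0 + 35.0)),
        # Feature binding: a new feature joins a bound pair -> S
        "fig8A_feature_bind": _seq(*s2, _p(2, bd_a, bd_w, 1320.0 + 38.0)),
        # Feature unbinding: a bound pair is split into distinct items
        "fig8B_feature_unbind": _seq(*s2, _p(0, ig_a, ig_w, 1320.0 + 8.0)),
        # Variable binding chain: two distinct items are first bound into
        # one object, then a new item is loaded as a distinct memorandum
        "fig9_variable_binding": _seq(
            *op2, _p(0, bd_a, bd_w, 1845.0 + 31.0),
            _p(2, ig_a, ig_w, 3116.0 + 6.0)),
    }
    return lib


def run_scenario(
    name: str,
    params: ModelParameters | None = None,
    t_end: float | None = None,
) -> tuple[Trajectory, PhasePattern]:
    """Simulate a named scenario and classify its settled outcome."""
    if params is None:
        params = preset("paper-default")
    lib = scenario_library(params)
    try:
        proto = lib[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(lib)}") from None
    if t_end is None:
        t_end = proto.last_offset + SETTLE + 700.0
    traj = simulate(params, proto, t_end=t_end)
    return traj, classify_trajectory(traj)
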