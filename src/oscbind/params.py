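"""Model parameters and stimulus protocols.

The network consists of ``N`` all-to-all coupled populations ("triplets"),
each carrying a fast excitatory (AMPA) synaptic activity ``u``, an inhibitory
(GABA) activity ``v`` and a slow excitatory (NMDA) activity ``n``.  Time is
rescaled so that the fast excitatory timescale is 1; one model time unit is
interpreted as 1 ms throughout.

Stimuli are square pulses added inside the firing-rate nonlinearity of the
``u`` equation of a selected population; they are the only way activity is
loaded into the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "StimulusPulse",
    "StimulusProtocol",
    "preset",
    "PRESETS",
]


class ParameterError(ValueError):
    """Raised when a model or stimulus parameter violates its constraints."""


@dataclass(frozen=True)
class ModelParameters:
    """Immutable record of all model constants.

    Couplings prefixed ``a_`` act within one population; ``c_e`` (excitatory),
    ``c_ei`` (inhibitory) and ``c_ie`` (E-to-I, 0 by default) act between
    populations through the normalised all-to-all mixing rule.
    """

    N: int = 5
    tau_i: float = 12.0
    tau_n: float = 144.0
    c_e: float = 0.001
    c_ei: float = 0.03
    c_ie: float = 0.0
    a_ee: float = 14.0
    a_ei: float = 10.0
    a_en: float = 4.0
    a_ie: float = 20.0
    a_ii: float = 8.0
    a_in: float = 0.1
    theta_e: float = 6.0
    theta_i: float = 5.0
    a_n: float = 2.0
    p: float = 2.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise ParameterError(f"N must be an integer >= 1, got {self.N}")
        object.__setattr__(self, "N", int(self.N))
        for name in ("c_e", "c_ei", "c_ie", "a_ee", "a_ei", "a_en",
                     "a_ie", "a_ii", "a_in"):
            if getattr(self, name) < 0:
                raise ParameterError(f"coupling {name} must be >= 0")
        if self.a_n <= 0:
            raise ParameterError("a_n must be > 0")
        if self.p <= 0:
            raise ParameterError("p must be > 0")
        if self.beta <= 0:
            raise ParameterError("beta must be > 0")
        if self.tau_i <= 0 or self.tau_n <= 0:
            raise ParameterError("timescales must be > 0")
        if not (self.tau_n > self.tau_i > 1.0):
            warnings.warn(
                "outside the default regime tau_n > tau_i > 1; oscillatory "
                "persistence is not guaranteed",
                stacklevel=2,
            )

    def with_(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def as_array(self) -> np.ndarray:
        """Pack the scalar constants into the flat array the kernels use."""
        return np.array(
            [self.N, self.tau_i, self.tau_n, self.c_e, self.c_ei, self.c_ie,
             self.a_ee, self.a_ei, self.a_en, self.a_ie, self.a_ii, self.a_in,
             self.theta_e, self.theta_i, self.a_n, self.p, self.beta],
            dtype=np.float64,
        )

    def to_dict(self) -> dict:
        return {
            "N": self.N, "tau_i": self.tau_i, "tau_n": self.tau_n,
            "c_e": self.c_e, "c_ei": self.c_ei, "c_ie": self.c_ie,
            "a_ee": self.a_ee, "a_ei": self.a_ei, "a_en": self.a_en,
            "a_ie": self.a_ie, "a_ii": self.a_ii, "a_in": self.a_in,
            "theta_e": self.theta_e, "theta_i": self.theta_i,
            "a_n": self.a_n, "p": self.p, "beta": self.beta,
        }


#: Named parameter sets.  "paper-default" is the published default regime:
#: tristable between a low fixed point, a small oscillation around it, and the
#: large-amplitude oscillation used to represent an item held in memory.
PRESETS: dict[str, ModelParameters] = {
    "paper-default": ModelParameters(),
}


def preset(name: str, **overrides) -> ModelParameters:
    """Look up a named parameter set, optionally overriding fields."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return base.with_(**overrides) if overrides else base


@dataclass(frozen=True)
class StimulusPulse:
    """One square pulse: amplitude ``A`` on [onset, onset + width) added to
    the firing-rate argument of the target population's ``u`` equation."""

    target: int
    amplitude: float
    width: float
    onset: float

    def __post_init__(self) -> None:
        if self.target < 0:
            raise ParameterError("target population index must be >= 0")
        if self.amplitude < 0:
            raise ParameterError("pulse amplitude must be >= 0")
        if self.width <= 0:
            raise ParameterError("pulse width must be > 0")

    @property
    def offset(self) -> float:
        return self.onset + self.width


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered collection of square pulses defining s_j(t).

    Per-population drive is the sum of that population's active pulses, so
    s_j(t) is piecewise constant with finitely many jumps.
    """

    pulses: tuple[StimulusPulse, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pulses", tuple(self.pulses))

    @classmethod
    def from_pulses(cls, pulses: Iterable[StimulusPulse | tuple]) -> "StimulusProtocol":
        out = []
        for p in pulses:
            if not isinstance(p, StimulusPulse):
                p = StimulusPulse(*p)
            out.append(p)
        return cls(tuple(out))

    def validate(self, N: int) -> None:
        for p in self.pulses:
            if p.target >= N:
                raise ParameterError(
                    f"pulse targets population {p.target} but N = {N}"
                )

    @property
    def last_offset(self) -> float:
        return max((p.offset for p in self.pulses), default=0.0)

    def edges(self, t0: float, t1: float) -> np.ndarray:
        """Sorted unique pulse edge times strictly inside (t0, t1)."""
        ts = set()
        for p in self.pulses:
            for t in (p.onset, p.offset):
                if t0 < t < t1:
                    ts.add(float(t))
        return np.array(sorted(ts))

    def drive(self, t: float, N: int) -> np.ndarray:
        """s(t) as a length-N vector (right-continuous at edges)."""
        s = np.zeros(N)
        for p in self.pulses:
            if p.onset <= t < p.offset:
                s[p.target] += p.amplitude
        return s

    def shifted(self, dt: float) -> "StimulusProtocol":
        return StimulusProtocol(tuple(
            StimulusPulse(p.target, p.amplitude, p.width, p.onset + dt)
            for p in self.pulses
        ))

    def permuted(self, perm: Sequence[int]) -> "StimulusProtocol":
        """Relabel targets: population j becomes perm[j]."""
        return StimulusProtocol(tuple(
            StimulusPulse(int(perm[p.target]), p.amplitude, p.width, p.onset)
            for p in self.pulses
        ))

    def __add__(self, other: "StimulusProtocol") -> "StimulusProtocol":
        return StimulusProtocol(self.pulses + other.pulses)
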