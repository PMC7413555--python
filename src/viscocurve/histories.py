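"""Displacement-controlled indentation ramps with a single contact maximum.

Two ideal piezo trajectories are supported:

* triangular -- constant-speed approach and retraction,
  ``delta(t) = v t`` up to ``t_m`` then ``v (2 t_m - t)``, with
  ``v = delta_max / t_m``;
* sinusoidal -- ``delta(t) = A sin(omega t)`` with amplitude
  ``A = delta_max`` and ``omega = pi / (2 t_m)``, so the maximum
  contact radius is reached at a quarter period; the same sine is
  continued past ``t_m`` for the retraction.

Both are normalised families: ``delta(t) / delta_max`` depends on
``t / t_m`` only, which is why force curves for a linear material can
be presented in normalised coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["IndentationHistory", "make_history", "depth_and_rate"]

_KINDS = ("triangular", "sinusoidal")


@dataclass(frozen=True)
class IndentationHistory:
    kind: str
    delta_max: float  # maximum depth [m]
    t_m: float  # time of maximum contact radius [s]

    @property
    def v(self) -> float:
        """Approach speed [m/s] (triangular ramp)."""
        return self.delta_max / self.t_m

    @property
    def A(self) -> float:
        """Amplitude [m] (sinusoidal ramp); equals delta_max."""
        return self.delta_max

    @property
    def omega(self) -> float:
        """Angular frequency [rad/s] (sinusoidal ramp): pi / (2 t_m)."""
        return math.pi / (2.0 * self.t_m)

    def depth(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "triangular":
            return self.v * np.where(t <= self.t_m, t, 2.0 * self.t_m - t)
        return self.A * np.sin(self.omega * t)

    def rate(self, t, phase: str | None = None):
        """d(delta)/dt; at the triangular turning point the one-sided
        limit is selected by ``phase`` ('approach' -> +v, 'retract' -> -v)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "triangular":
            if phase == "approach":
                on_approach = t <= self.t_m
            elif phase == "retract":
                on_approach = t < self.t_m
            else:
                on_approach = t <= self.t_m  # causal (left-limit) default at t_m
            return self.v * np.where(on_approach, 1.0, -1.0)
        return self.A * self.omega * np.cos(self.omega * t)


def make_history(kind: str, delta_max: float, t_m: float) -> IndentationHistory:
    """Build a single-maximum ramp from its kind, depth [m] and ``t_m`` [s]."""
    if kind not in _KINDS:
        raise ValueError(f"unknown ramp kind {kind!r}; choose from {_KINDS}")
    if not (delta_max > 0 and t_m > 0):
        raise ValueError(f"delta_max and t_m must be positive, got {delta_max}, {t_m}")
    return IndentationHistory(kind, float(delta_max), float(t_m))


def depth_and_rate(history: IndentationHistory, t, phase: str | None = None):
    """Evaluate ``(delta(t), d(delta)/dt)`` on arbitrary non-negative times."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return history.depth(t), history.rate(t, phase=phase)
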