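"""Force curves for displacement-controlled viscoelastic indentation.

The approach force follows the Lee-Radok hereditary integral: the
elastic modulus in the Hertz law is replaced by a convolution of the
relaxation modulus with the rate of ``delta(t)^n``,

    F_appr(t) = C_geom * int_0^t E(t - xi) d(delta^n)/dxi dxi .

Once the contact radius shrinks (retraction), that expression loses
validity and Ting's construction applies: the force becomes the same
convolution truncated at the auxiliary time ``t1(t)`` -- the
approach-phase instant with the same contact radius as the current
retraction instant -- where ``t1(t)`` is the root of

    int_{t1(t)}^{t} E(t - xi) d(delta)/dxi dxi = 0 .

Contact is lost (detachment) at the first time this equation has no
root in ``(0, t_m]``; the force is identically zero afterwards and the
probe-sample contact time is ``t_ind = t_detach``, with
``t_m < t_ind <= 2 t_m``.

Numerics
--------
Product integration on a uniform grid: within each step the rate of
``delta^n`` is replaced by its exact interval mean while the kernel is
integrated exactly through the model's closed-form running integral
``int E_reg`` (so integrable ``t^-alpha`` singularities cost nothing).
A Dirac term ``eta * delta_D`` in the kernel contributes
``eta * d(delta^n)/dt`` at the current time with full weight (causal
limit) -- this reproduces the contact jump of a Kelvin-Voigt solid
under a flat punch and the force drop at the triangular turning point.
``t1`` is found per sample by bracketed bisection (absolute tolerance
``dt/100``), warm-started from the previous sample since ``t1`` is
non-increasing.  For Mittag-Leffler kernels the running integral is
tabulated once and interpolated monotonically in log-log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator

from .histories import IndentationHistory, make_history
from .models import RelaxationModel, build_model
from .probes import ProbeGeometry

__all__ = [
    "ForceCurve",
    "approach_force",
    "t1_function",
    "retraction_force",
    "simulate_curve",
    "lee_radok_curve",
    "analytic_curve",
]

_T1_BISECT_FRACTION = 0.01  # absolute t1 tolerance, as a fraction of dt


# ---------------------------------------------------------------------------
# force curve container
# ---------------------------------------------------------------------------


@dataclass
class ForceCurve:
    """Sampled (t, delta, F) indentation cycle with phase segmentation.

    ``F`` is clamped at zero beyond detachment; ``t1`` holds the Ting
    auxiliary map on retraction samples (NaN on approach samples).
    ``t_ind`` is the probe-sample contact time, equal to ``t_detach``.
    """

    t: np.ndarray
    delta: np.ndarray
    F: np.ndarray
    phase: np.ndarray  # 'approach' / 'retract' per sample
    t_m: float
    t_detach: float
    t1: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def t_ind(self) -> float:
        return self.t_detach

    @property
    def is_approach(self) -> np.ndarray:
        return self.phase == "approach"

    @property
    def delta_max(self) -> float:
        return float(np.max(self.delta))

    def normalized(self):
        """(delta / delta_max, F / F_max) views for shape comparison."""
        fmax = np.max(self.F)
        return self.delta / self.delta_max, self.F / (fmax if fmax > 0 else 1.0)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.t, "indentation_m": self.delta, "force_N": self.F, "phase": self.phase}
        )


# ---------------------------------------------------------------------------
# kernel plumbing
# ---------------------------------------------------------------------------


class _CumKernel:
    """Vectorised ``int_0^u E_reg`` with log-log interpolation for ML kernels."""

    def __init__(self, model: RelaxationModel, u_max: float, n_nodes: int = 480):
        self._model = model
        if model.has_ml:
            u_lo = u_max * 1e-8
            nodes = np.geomspace(u_lo, u_max * 1.0000001, n_nodes)
            vals = np.asarray(model.cumulative(nodes), dtype=float)
            logs = np.log(vals)
            self._interp = PchipInterpolator(np.log(nodes), logs, extrapolate=False)
            self._u_lo = u_lo
            # power-law continuation below the tabulated range
            self._p_lo = (logs[1] - logs[0]) / (np.log(nodes[1]) - np.log(nodes[0]))
            self._c_lo = vals[0]
            self._exact = False
        else:
            self._exact = True

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        if self._exact:
            return self._model.cumulative(u)
        scalar = u.ndim == 0
        u = np.atleast_1d(u)
        out = np.zeros_like(u)
        small = (u > 0) & (u < self._u_lo)
        big = u >= self._u_lo
        if np.any(small):
            out[small] = self._c_lo * (u[small] / self._u_lo) ** self._p_lo
        if np.any(big):
            out[big] = np.exp(self._interp(np.log(u[big])))
        return out[0] if scalar else out


def _g_rate_at(probe: ProbeGeometry, history: IndentationHistory, t, phase):
    """Analytic d(delta^n)/dt = n delta^(n-1) d(delta)/dt."""
    d = history.depth(t)
    r = history.rate(t, phase=phase)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = probe.n * np.power(d, probe.n - 1.0) * r
    return np.where(np.asarray(d) > 0, out, 0.0 if probe.n != 1.0 else r)


def _segment_means(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.diff(values) / np.diff(grid)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def approach_force(
    model: RelaxationModel,
    history: IndentationHistory,
    probe: ProbeGeometry,
    t_grid: np.ndarray,
    f_bec: Callable | None = None,
    _kernel: _CumKernel | None = None,
) -> np.ndarray:
    """Lee-Radok approach force on an ascending grid within [0, t_m].

    ``f_bec`` is an optional bottom-effect correction: a function of the
    depth multiplying the integrand (default 1, appropriate for samples
    much thicker than the contact size).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly ascending")
    if t_grid[0] != 0.0:
        raise ValueError("approach grid must start at initial contact (t = 0)")
    if t_grid[-1] > history.t_m * (1 + 1e-12):
        raise ValueError("approach grid extends past t_m")
    kern = _kernel if _kernel is not None else _CumKernel(model, float(t_grid[-1]))
    g = history.depth(t_grid) ** probe.n
    gdot = _segment_means(g, t_grid)
    if f_bec is not None:
        mid = 0.5 * (t_grid[:-1] + t_grid[1:])
        gdot = gdot * np.asarray(f_bec(history.depth(mid)), dtype=float)
    n = t_grid.size
    F = np.empty(n)
    start = 0
    if t_grid[0] == 0.0:
        F[0] = 0.0
        start = 1
    for k in range(start, n):
        w = kern(t_grid[k] - t_grid[: k + 1])  # descending distances
        F[k] = np.dot(gdot[:k], w[:k] - w[1 : k + 1])
    delta_part = model.delta_coeff * _g_rate_at(probe, history, t_grid, "approach")
    if f_bec is not None:
        delta_part = delta_part * np.asarray(f_bec(history.depth(t_grid)), dtype=float)
    return probe.C_geom * F + probe.C_geom * delta_part


def t1_function(
    model: RelaxationModel,
    history: IndentationHistory,
    retraction_times: np.ndarray,
    n_approach: int | None = None,
    _kernel: _CumKernel | None = None,
):
    """Solve the contact-radius matching equation for each retraction time.

    Returns ``(t1, t_detach)``: the auxiliary times (0 where detached)
    and the detachment time, linearly interpolated between the last
    attached and first detached samples (``2 t_m`` if contact persists
    through the whole ramp).
    """
    t_ret = np.asarray(retraction_times, dtype=float)
    t_m = history.t_m
    if np.any(t_ret <= t_m) or np.any(t_ret > 2 * t_m * (1 + 1e-12)):
        raise ValueError("retraction times must lie in (t_m, 2*t_m]")
    n_app = n_approach if n_approach is not None else max(200, t_ret.size)
    t_app = np.linspace(0.0, t_m, n_app + 1)
    dt = t_m / n_app
    kern = _kernel if _kernel is not None else _CumKernel(model, 2.0 * t_m)
    d_app = history.depth(t_app)
    ddot_app = _segment_means(d_app, t_app)  # exact interval means of the rate
    grid_ret = np.concatenate(([t_m], t_ret))
    d_ret = history.depth(grid_ret)
    ddot_ret = _segment_means(d_ret, grid_ret)
    tol = dt * _T1_BISECT_FRACTION
    t1 = np.zeros(t_ret.size)
    t_detach = 2.0 * t_m
    prev = t_m
    detached = False
    g0_prev = None
    for k, t in enumerate(t_ret):
        if detached:
            t1[k:] = 0.0
            break
        w_app = kern(t - t_app)  # length n_app+1, descending in index
        seg_w = w_app[:-1] - w_app[1:]
        contrib = ddot_app * seg_w
        tail = np.concatenate((np.cumsum(contrib[::-1])[::-1], [0.0]))  # tail[j] = sum_{i>=j}
        w_ret = kern(t - grid_ret[: k + 2])
        R = float(np.dot(ddot_ret[: k + 1], w_ret[:-1] - w_ret[1:]))
        R += model.delta_coeff * float(history.rate(t, phase="retract"))

        def G(x: float) -> float:
            j = min(int(x / dt), n_app - 1)
            hi = t_app[j + 1]
            part = 0.0
            if hi - x > 1e-13 * dt:
                mean = (d_app[j + 1] - float(history.depth(x))) / (hi - x)
                part = mean * (float(kern(t - x)) - w_app[j + 1])
            return part + tail[j + 1] + R

        g_full = G(0.0)
        if g_full <= 0.0:
            # no root: contact lost between the previous sample and t
            if k == 0 or g0_prev is None or g0_prev <= 0:
                t_detach = t_m if k == 0 else float(t_ret[k - 1])
            else:
                t_prev = t_m if k == 0 else float(t_ret[k - 1])
                t_detach = t_prev + (t - t_prev) * g0_prev / (g0_prev - g_full)
            t1[k:] = 0.0
            detached = True
            continue
        g0_prev = g_full
        lo, hi = 0.0, min(prev, t_m)
        g_hi = G(hi)
        if g_hi > 0.0:
            hi = t_m  # warm-start bracket failed; widen to the full phase
            g_hi = G(hi)
            if g_hi > 0.0:
                raise RuntimeError("t1 bracketing failed: G(t_m) > 0")
        g_lo = g_full if lo == 0.0 else G(lo)
        while hi - lo > tol:
            midp = 0.5 * (lo + hi)
            g_mid = G(midp)
            if g_mid > 0.0:
                lo, g_lo = midp, g_mid
            else:
                hi, g_hi = midp, g_mid
        # one false-position step sharpens the bracketed root by ~3 digits
        if g_lo > 0.0 > g_hi:
            t1[k] = lo + g_lo * (hi - lo) / (g_lo - g_hi)
        else:
            t1[k] = 0.5 * (lo + hi)
        prev = t1[k]
    return t1, float(t_detach)


def retraction_force(
    model: RelaxationModel,
    history: IndentationHistory,
    probe: ProbeGeometry,
    t_grid: np.ndarray,
    t1_map: np.ndarray,
    f_bec: Callable | None = None,
    n_approach: int | None = None,
    _kernel: _CumKernel | None = None,
) -> np.ndarray:
    """Ting retraction force: the approach convolution truncated at t1(t)."""
    t_ret = np.asarray(t_grid, dtype=float)
    t1_map = np.asarray(t1_map, dtype=float)
    t_m = history.t_m
    n_app = n_approach if n_approach is not None else max(200, t_ret.size)
    t_app = np.linspace(0.0, t_m, n_app + 1)
    dt = t_m / n_app
    kern = _kernel if _kernel is not None else _CumKernel(model, 2.0 * t_m)
    g_app = history.depth(t_app) ** probe.n
    gdot_app = _segment_means(g_app, t_app)
    if f_bec is not None:
        mid = 0.5 * (t_app[:-1] + t_app[1:])
        gdot_app = gdot_app * np.asarray(f_bec(history.depth(mid)), dtype=float)
    F = np.zeros(t_ret.size)
    for k, (t, x) in enumerate(zip(t_ret, t1_map)):
        if x <= 0.0:
            continue
        j = min(int(x / dt), n_app - 1)
        w_app = kern(t - t_app[: j + 2])
        full = float(np.dot(gdot_app[:j], w_app[:j] - w_app[1 : j + 1]))
        lo = t_app[j]
        part = 0.0
        if x - lo > 1e-13 * dt:
            gx = float(history.depth(x)) ** probe.n
            mean = (gx - g_app[j]) / (x - lo)
            if f_bec is not None:
                mean *= float(f_bec(history.depth(0.5 * (lo + x))))
            part = mean * (w_app[j] - float(kern(t - x)))
        F[k] = probe.C_geom * (full + part)
    return np.maximum(F, 0.0)


def simulate_curve(
    model: RelaxationModel,
    history: IndentationHistory,
    probe: ProbeGeometry,
    n_steps: int = 1000,
    f_bec: Callable | None = None,
) -> ForceCurve:
    """Simulate a full approach-retraction force curve.

    Uniform grid of ``n_steps`` intervals per phase (default 1000).
    The force is clamped at zero beyond detachment and the realized
    contact time ``t_detach`` is recorded as ``t_ind``.
    """
    if n_steps < 100:
        raise ValueError("n_steps must be >= 100")
    t_m = history.t_m
    probe.check_depth(history.delta_max)
    kern = _CumKernel(model, 2.0 * t_m)
    t_app = np.linspace(0.0, t_m, n_steps + 1)
    t_ret = np.linspace(t_m, 2.0 * t_m, n_steps + 1)[1:]
    F_app = approach_force(model, history, probe, t_app, f_bec=f_bec, _kernel=kern)
    t1, t_detach = t1_function(model, history, t_ret, n_approach=n_steps, _kernel=kern)
    F_ret = retraction_force(
        model, history, probe, t_ret, t1, f_bec=f_bec, n_approach=n_steps, _kernel=kern
    )
    F_ret[t_ret >= t_detach] = 0.0
    t = np.concatenate((t_app, t_ret))
    delta = history.depth(t)
    F = np.concatenate((np.maximum(F_app, 0.0), F_ret))
    phase = np.concatenate((np.full(t_app.size, "approach"), np.full(t_ret.size, "retract")))
    t1_full = np.concatenate((np.full(t_app.size, np.nan), t1))
    meta = {
        "model": model.name,
        "params": dict(model.params),
        "delta_coeff": model.delta_coeff,
        "probe": {"shape": probe.shape, "dimension": probe.dimension, "n": probe.n,
                  "C_geom": probe.C_geom, "nu": probe.nu,
                  "nu_divisor_applied": probe.nu_divisor_applied},
        "ramp": {"kind": history.kind, "delta_max": history.delta_max, "t_m": history.t_m},
        "n_steps": n_steps,
        "t_detach": t_detach,
        "t_ind": t_detach,
    }
    return ForceCurve(t, delta, F, phase, t_m, t_detach, t1_full, meta)


def lee_radok_curve(
    model: RelaxationModel,
    history: IndentationHistory,
    probe: ProbeGeometry,
    n_steps: int = 1000,
    clamp: bool = False,
) -> ForceCurve:
    """Continue the Lee-Radok convolution through the retraction phase.

    Valid only while the contact radius is non-decreasing; for the
    cylindrical punch (constant contact radius) it coincides with the
    Ting solution on both phases.  Returned unclamped by default so the
    (possibly negative) continuation can be inspected.
    """
    if n_steps < 100:
        raise ValueError("n_steps must be >= 100")
    t_m = history.t_m
    t = np.linspace(0.0, 2.0 * t_m, 2 * n_steps + 1)
    kern = _CumKernel(model, 2.0 * t_m)
    g = history.depth(t) ** probe.n
    gdot = _segment_means(g, t)
    n = t.size
    F = np.empty(n)
    F[0] = 0.0
    for k in range(1, n):
        w = kern(t[k] - t[: k + 1])
        F[k] = np.dot(gdot[:k], w[:k] - w[1 : k + 1])
    phase_flag = np.where(t <= t_m, "approach", "retract")
    rate_term = model.delta_coeff * np.where(
        t <= t_m,
        _g_rate_at(probe, history, t, "approach"),
        _g_rate_at(probe, history, t, "retract"),
    )
    F = probe.C_geom * (F + rate_term)
    if clamp:
        F = np.maximum(F, 0.0)
    meta = {"model": model.name, "solution": "lee_radok", "n_steps": n_steps}
    return ForceCurve(t, history.depth(t), F, phase_flag, t_m, 2.0 * t_m,
                      np.full(n, np.nan), meta)


# ---------------------------------------------------------------------------
# closed-form oracle curves
# ---------------------------------------------------------------------------


def analytic_curve(
    case: str,
    params: dict,
    history: IndentationHistory,
    probe: ProbeGeometry,
    t_grid: np.ndarray,
) -> ForceCurve:
    """Closed-form force histories for the analytically solvable cases.

    Supported: ``spring`` (both ramps, all probes), ``dashpot`` (both
    ramps, all probes), ``kelvin_voigt`` (triangular, all probes),
    ``maxwell`` (triangular; cylinder and cone, where the convolution
    is elementary).  These serve as independent oracles for the
    numerical solver.
    """
    t = np.asarray(t_grid, dtype=float)
    t_m = history.t_m
    C, n = probe.C_geom, probe.n
    app = t <= t_m
    d = history.depth(t)
    if case == "spring":
        E = float(params["E"])
        F = C * E * np.where(d > 0, d, 0.0) ** n
        if history.kind == "triangular":
            t1 = np.where(app, np.nan, 2.0 * t_m - t)
        else:
            t1 = np.where(app, np.nan, math.pi / history.omega - t)
        return ForceCurve(t, d, F, _phase_of(t, t_m), t_m, 2.0 * t_m, t1,
                          {"model": "spring", "solution": "analytic"})
    if case == "dashpot":
        eta = float(params["eta"])
        rate = history.rate(t, phase="approach")
        F = np.where(app, C * eta * n * np.where(d > 0, d, 0.0) ** (n - 1.0) * rate, 0.0)
        if n == 1.0:
            F = np.where(app, C * eta * rate, 0.0)
        return ForceCurve(t, d, F, _phase_of(t, t_m), t_m, t_m,
                          np.where(app, np.nan, 0.0),
                          {"model": "dashpot", "solution": "analytic"})
    if case == "kelvin_voigt":
        if history.kind != "triangular":
            raise ValueError("analytic Kelvin-Voigt curve requires the triangular ramp")
        E_inf, eta = float(params["E_inf"]), float(params["eta"])
        v = history.v
        tau_kv = eta / E_inf
        dn = np.where(d > 0, d, 0.0) ** n
        dn1 = np.where(d > 0, d, 0.0) ** (n - 1.0) if n != 1.0 else np.ones_like(d)
        F_app = C * (E_inf * dn + eta * n * dn1 * v)
        t1 = np.clip(2.0 * t_m - t - tau_kv, 0.0, None)
        t_det = max(t_m, 2.0 * t_m - tau_kv)
        F_ret = C * E_inf * (v * t1) ** n
        F = np.where(app, F_app, np.where(t < t_det, F_ret, 0.0))
        return ForceCurve(t, d, F, _phase_of(t, t_m), t_m, t_det,
                          np.where(app, np.nan, t1),
                          {"model": "kelvin_voigt", "solution": "analytic"})
    if case == "maxwell":
        if history.kind != "triangular":
            raise ValueError("analytic Maxwell curve requires the triangular ramp")
        if probe.shape not in ("cylinder", "cone"):
            raise ValueError("analytic Maxwell curve supports cylinder and cone probes")
        E0 = float(params["E0"])
        tau = float(params["tau"]) if "tau" in params else float(params["eta"]) / E0
        v = history.v
        # t1: exp(-(t - t1)/tau) = 2 exp(-(t - t_m)/tau) - 1
        with np.errstate(invalid="ignore"):
            arg = 2.0 * np.exp(-(t - t_m) / tau) - 1.0
            t1 = np.where(arg > 0, t + tau * np.log(np.maximum(arg, 1e-300)), 0.0)
        t1 = np.clip(t1, 0.0, t_m)
        # tau*log(2*exp(t_m/tau) - 1) rewritten to avoid overflow
        t_det = min(2.0 * t_m, t_m + tau * math.log(2.0 - math.exp(-t_m / tau)))
        if probe.shape == "cylinder":
            F_app = C * E0 * v * tau * (-np.expm1(-t / tau))
            F_ret = C * E0 * v * tau * np.exp(-t / tau) * np.expm1(t1 / tau)
        else:  # cone
            F_app = 2.0 * C * E0 * v**2 * tau * (t + tau * np.expm1(-t / tau))
            F_ret = (
                2.0 * C * E0 * v**2 * tau
                * np.exp(-t / tau) * (np.exp(t1 / tau) * (t1 - tau) + tau)
            )
        F = np.where(app, F_app, np.where((t < t_det) & (t1 > 0), F_ret, 0.0))
        return ForceCurve(t, d, F, _phase_of(t, t_m), t_m, float(t_det),
                          np.where(app, np.nan, t1),
                          {"model": "maxwell", "solution": "analytic"})
    raise ValueError(f"no closed-form oracle for case {case!r}")


def _phase_of(t, t_m):
    return np.where(t <= t_m, "approach", "retract")
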