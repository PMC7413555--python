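"""Force-curve metrics and their dependence on the indentation time.

Three scalar features summarise how far a force-indentation cycle
deviates from the elastic (Hertzian) response:

* **apparent Young's modulus (YM)** -- the modulus obtained by forcing
  the elastic law ``F = C_geom * YM * delta^n`` (exponent fixed by the
  probe) onto the approach segment; rate-dependent for any
  viscoelastic material;
* **curve exponent** -- the exponent of a free power-law fit
  ``F = A * delta^m`` to the approach segment; equals the Hertzian
  ``n`` for elastic behaviour and drops by up to one (by ``alpha`` for
  a springpot) when relaxation is strong;
* **normalized hysteresis area (NHA)** -- the loop area between
  approach and retraction divided by the area under the approach, i.e.
  the fraction of the input work dissipated in the cycle; 0 for a
  spring, 1 for a dashpot.

Sweeping these metrics over the indentation time ``t_ind`` (the inverse
of the indentation rate) produces the characteristic fingerprints by
which relaxation models can be told apart, and two diagnostics connect
them back to the relaxation function: the apparent YM tracks the time
average ``<E>`` of ``E(t)`` over the first quarter cycle, and the NHA
tracks minus twice the logarithmic slope of ``<E>``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .histories import make_history
from .models import RelaxationModel, log_slope_time_average, time_averaged_modulus
from .probes import ProbeGeometry
from .ting import ForceCurve, simulate_curve

__all__ = [
    "CurveMetrics",
    "SweepResult",
    "hertz_fit",
    "exponent_fit",
    "nha",
    "analyze_curve",
    "sweep_indentation_time",
    "eq_average_check",
    "nha_slope_check",
    "add_noise",
]

logger = logging.getLogger(__name__)


@dataclass
class CurveMetrics:
    """Scalar metrics for one force curve."""

    apparent_YM: float  # [Pa]
    NHA: float | None  # [0, 1], None when retraction data are absent
    exponent: float  # unitless
    exponent_amplitude: float = math.nan  # prefactor of the free power-law fit [N]
    hertz_residual: float = math.nan  # rms of (F - fit)/max(F), fixed-exponent fit
    exponent_residual: float = math.nan  # same for the free-exponent fit


@dataclass
class SweepResult:
    """Metrics versus (normalized) indentation time for one model/probe/ramp."""

    t_ind: np.ndarray  # nominal indentation-cycle time grid [s]
    t_norm: np.ndarray  # t_ind / char_time [unitless]
    metrics: list  # CurveMetrics or None per grid point
    t_contact: np.ndarray  # realized probe-sample contact times [s]
    model_name: str = ""
    normalize_by: str | None = None
    norm_value: float = math.nan
    metadata: dict = field(default_factory=dict)

    @property
    def YM(self) -> np.ndarray:
        return np.array([m.apparent_YM if m else np.nan for m in self.metrics])

    @property
    def YM_norm(self) -> np.ndarray:
        return self.YM / self.norm_value if self.norm_value == self.norm_value else self.YM

    @property
    def NHA(self) -> np.ndarray:
        return np.array([m.NHA if m and m.NHA is not None else np.nan for m in self.metrics])

    @property
    def exponent(self) -> np.ndarray:
        return np.array([m.exponent if m else np.nan for m in self.metrics])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_ind_s": self.t_ind,
                "t_norm": self.t_norm,
                "YM_Pa": self.YM,
                "YM_norm": self.YM_norm,
                "NHA": self.NHA,
                "exponent": self.exponent,
            }
        )


# ---------------------------------------------------------------------------
# single-curve metrics
# ---------------------------------------------------------------------------


def _approach_data(curve: ForceCurve):
    m = curve.is_approach & (curve.delta > 0)
    return curve.delta[m], curve.F[m]


def hertz_fit(curve: ForceCurve, probe: ProbeGeometry) -> float:
    """Apparent Young's modulus from the fixed-exponent Hertzian fit.

    Only the approach segment enters the fit (the quarter-cycle time
    average ``<E>`` is the matching theoretical quantity).  With the
    exponent fixed the least-squares problem is linear:
    ``YM = sum(F * delta^n) / (C_geom * sum(delta^(2n)))``.
    """
    d, F = _approach_data(curve)
    if d.size < 20:
        raise ValueError("need at least 20 approach samples with delta > 0")
    dn = d**probe.n
    denom = float(np.dot(dn, dn))
    if denom == 0.0 or not np.any(F > 0):
        raise ValueError("degenerate approach segment (zero force or depth)")
    return float(np.dot(F, dn)) / (probe.C_geom * denom)


def exponent_fit(curve: ForceCurve, initial_exponent: float | None = None):
    """Free power-law fit ``F = A * delta^m`` of the approach segment.

    Samples shallower than 1% of the maximum depth are excluded (the
    fit is unstable against contact-point noise there).  Returns
    ``(m, A, rms_residual)``; the fit runs in normalized coordinates
    for conditioning and is initialized at the Hertz-like solution.
    """
    d, F = _approach_data(curve)
    dmax = float(np.max(curve.delta))
    keep = d >= 0.01 * dmax
    d, F = d[keep], F[keep]
    if d.size < 5 or not np.any(F > 0):
        raise ValueError("degenerate approach segment for the exponent fit")
    fmax = float(np.max(F))
    x, y = d / dmax, F / fmax
    n0 = initial_exponent if initial_exponent is not None else 1.5
    popt, _ = curve_fit(
        lambda xx, a, mm: a * xx**mm, x, y, p0=(1.0, n0), maxfev=5000
    )
    a, mexp = float(popt[0]), float(popt[1])
    resid = float(np.sqrt(np.mean((a * x**mexp - y) ** 2)))
    return mexp, a * fmax / dmax**mexp, resid


def nha(curve: ForceCurve) -> float:
    """Normalized hysteresis area of the cycle in (delta, F) space.

    Trapezoidal areas; the retraction force is zero beyond detachment,
    so the open part of the loop contributes nothing.  The result is
    clipped to [0, 1] (clipping beyond numerical jitter is logged).
    """
    app = curve.is_approach
    if not np.any(~app):
        raise ValueError("curve has no retraction phase")
    d_a, F_a = curve.delta[app], curve.F[app]
    a_app = float(np.trapezoid(F_a, d_a))
    if a_app <= 0.0:
        raise ValueError("zero area under the approach curve")
    # close the retraction path at the apex; the force there is the
    # retraction-side limit (it jumps down for delta-term kernels), so
    # extrapolate the first two retraction samples linearly in time
    t_r, d_r, F_r = curve.t[~app], curve.delta[~app], curve.F[~app]
    if t_r.size >= 2 and t_r[1] > t_r[0]:
        slope = (F_r[1] - F_r[0]) / (t_r[1] - t_r[0])
        f_apex = max(0.0, F_r[0] - slope * (t_r[0] - curve.t_m))
    else:
        f_apex = F_r[0]
    d_r = np.concatenate(([max(d_a[-1], d_r[0])], d_r))
    F_r = np.concatenate(([f_apex], F_r))
    a_ret = -float(np.trapezoid(F_r, d_r))  # delta decreases along retraction
    val = (a_app - a_ret) / a_app
    if val < -1e-6 or val > 1.0 + 1e-6:
        logger.warning("NHA %.3g outside [0, 1]; clipping", val)
    return float(np.clip(val, 0.0, 1.0))


def analyze_curve(curve: ForceCurve, probe: ProbeGeometry) -> CurveMetrics:
    """All three metrics for one curve (NHA None if no retraction data)."""
    ym = hertz_fit(curve, probe)
    d, F = _approach_data(curve)
    dn = d**probe.n
    hertz_resid = float(np.sqrt(np.mean((probe.C_geom * ym * dn - F) ** 2)) / np.max(F))
    mexp, amp, exp_resid = exponent_fit(curve, initial_exponent=probe.n)
    try:
        area = nha(curve)
    except ValueError:
        area = None
    return CurveMetrics(ym, area, mexp, amp, hertz_resid, exp_resid)


# ---------------------------------------------------------------------------
# indentation-time sweeps and diagnostics
# ---------------------------------------------------------------------------

_NORM_CHOICES = (None, "E0", "E_inf", "E0_minus_Einf")


def sweep_indentation_time(
    model: RelaxationModel,
    probe: ProbeGeometry,
    ramp_kind: str,
    t_grid: np.ndarray,
    delta_max: float = 100e-9,
    n_steps: int = 400,
    normalize: str | None = None,
) -> SweepResult:
    """Simulate and analyze one curve per indentation time.

    ``t_grid`` sets the nominal (full-cycle) indentation time of each
    simulation, ``t_m = t_ind / 2``; the realized contact time (which
    is shorter whenever the probe detaches early) is recorded per
    point.  ``normalize`` selects the modulus used for the normalized
    YM axis ('E0', 'E_inf', 'E0_minus_Einf' or None), matching the
    different conventions used for different models.  Failures at
    individual grid points are logged and left as gaps, not raised.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 3:
        raise ValueError("t_grid needs at least 3 points")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if normalize not in _NORM_CHOICES:
        raise ValueError(f"normalize must be one of {_NORM_CHOICES}")
    if normalize == "E0":
        norm_value = model.E0
    elif normalize == "E_inf":
        norm_value = model.E_inf
    elif normalize == "E0_minus_Einf":
        norm_value = model.E0 - model.E_inf
    else:
        norm_value = math.nan
    if normalize and not (norm_value and math.isfinite(norm_value)):
        raise ValueError(f"normalization modulus {normalize} is not finite for {model.name}")
    metrics: list = []
    t_contact = np.empty(t_grid.size)
    for i, t_ind in enumerate(t_grid):
        try:
            hist = make_history(ramp_kind, delta_max, t_ind / 2.0)
            curve = simulate_curve(model, hist, probe, n_steps=n_steps)
            metrics.append(analyze_curve(curve, probe))
            t_contact[i] = curve.t_detach
        except Exception:  # per-point failures are data gaps, not fatal
            logger.exception("sweep point t_ind = %g s failed", t_ind)
            metrics.append(None)
            t_contact[i] = math.nan
    tau = model.char_time
    t_norm = t_grid / tau if tau else t_grid.copy()
    return SweepResult(
        t_grid, t_norm, metrics, t_contact, model.name, normalize, norm_value,
        {"probe": probe.shape, "ramp": ramp_kind, "delta_max": delta_max, "n_steps": n_steps},
    )


def eq_average_check(model: RelaxationModel, sweep: SweepResult) -> np.ndarray:
    """Relative deviation of the apparent YM from the quarter-cycle average.

    ``|YM(t_ind) - <E>(t_ind)| / <E>(t_ind)`` per sweep point, where
    ``<E>`` averages the relaxation function from 0 to ``t_ind / 4``.
    """
    avg = np.array([time_averaged_modulus(model, t) for t in sweep.t_ind])
    return np.abs(sweep.YM - avg) / avg


def nha_slope_check(model: RelaxationModel, sweep: SweepResult) -> np.ndarray:
    """Pairs (NHA, -2 * d ln<E>/d ln t) per sweep point.

    Minus twice the log-log slope of the time-averaged relaxation
    function approximates the NHA: a flat (elastic) region gives 0,
    the steepest slope (dashpot, slope 1) gives 1.
    """
    doubled = np.array([-2.0 * log_slope_time_average(model, t) for t in sweep.t_ind])
    return np.column_stack((sweep.NHA, doubled))


def add_noise(curve: ForceCurve, force_noise_sd: float, seed: int) -> ForceCurve:
    """Gaussian force noise (synthetic-measurement fixture), reproducible by seed."""
    if force_noise_sd < 0:
        raise ValueError("force_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    noisy = curve.F + (rng.standard_normal(curve.F.size) * force_noise_sd if force_noise_sd else 0.0)
    meta = dict(curve.metadata)
    meta["noise"] = {"sd_N": force_noise_sd, "seed": seed}
    return ForceCurve(
        curve.t.copy(), curve.delta.copy(), noisy, curve.phase.copy(),
        curve.t_m, curve.t_detach, curve.t1.copy(), meta,
    )
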