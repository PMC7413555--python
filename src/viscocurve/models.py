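"""Linear viscoelastic relaxation functions: classical and fractional.

A material is described by its Young's relaxation modulus ``E(t)``, the
stress response to a unit step strain.  Every catalogued model is stored
as a regular (time-dependent) part plus the coefficient of a Dirac-delta
term ``eta * delta_D(t)`` contributed by a free dashpot in parallel; the
delta term is handled analytically by the contact solver, never sampled.

The regular part is a sum of primitive terms -- constant, exponential
(Maxwell arm), power law (springpot) and Mittag-Leffler (springpot
networks in series) -- each of which knows its own exact running
integral ``int_0^u E_reg(s) ds``.  Those closed-form cumulative kernels
are what make product integration of the singular hereditary integrals
cheap and accurate.

Catalogue (parameter names follow the conventions of the AFM
viscoelasticity literature; moduli in Pa, viscosities in Pa s, times in
s, fractional exponents unitless):

====================================  =============================================
name                                  relaxation function E(t)
====================================  =============================================
spring                                E
dashpot                               eta * delta_D(t)
kelvin_voigt                          E_inf + eta * delta_D(t)
maxwell                               E0 * exp(-t/tau)
sls                                   (E0 - E_inf) exp(-t/tau) + E_inf
gen_maxwell                           sum_i E_si exp(-t/tau_i) + E_inf
springpot                             E_alpha1 * t^-alpha
fractional_kv                         E_alpha1 * t^-alpha + E_inf
springpot_spring_series               E0 * ML_a[-(E0/E_alpha1) t^a]
springpot_dashpot_parallel            E_alpha1 * t^-alpha + eta * delta_D(t)
springpot_dashpot_series              see two_springpots_series with alpha = 1
two_springpots_parallel               E_alpha1 t^-alpha + E_beta1 t^-beta
two_springpots_series                 ML-kernel power law, beta < alpha
fractional_sls                        (E0-E_inf) ML_a[-(t/tau)^a] + E_inf
fractional_sls_dashpot                springpot_dashpot_series + E_inf
====================================  =============================================

The springpot uses the ``E_alpha1`` parameterisation: the modulus value
of ``E(t)`` at t = 1 s, with time treated as numerically unitless
seconds (reference time fixed at 1 s).  ``rescale_springpot_modulus``
converts between reference times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import nnls

from .mittag import mittag_leffler

__all__ = [
    "RelaxationModel",
    "MODEL_NAMES",
    "build_model",
    "eval_relaxation",
    "time_averaged_modulus",
    "log_slope_time_average",
    "prony_approximation",
    "rescale_springpot_modulus",
]


# ---------------------------------------------------------------------------
# primitive terms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Const:
    E: float

    def value(self, u):
        return np.full_like(u, self.E, dtype=float)

    def cumulative(self, u):
        return self.E * u

    e0 = property(lambda self: self.E)
    e_inf = property(lambda self: self.E)


@dataclass(frozen=True)
class _Exp:
    E: float
    tau: float

    def value(self, u):
        return self.E * np.exp(-u / self.tau)

    def cumulative(self, u):
        return -self.E * self.tau * np.expm1(-u / self.tau)

    e0 = property(lambda self: self.E)
    e_inf = property(lambda self: 0.0)


@dataclass(frozen=True)
class _Power:
    E: float
    alpha: float  # 0 < alpha < 1; E * u^-alpha

    def value(self, u):
        return self.E * u ** (-self.alpha)

    def cumulative(self, u):
        return self.E * u ** (1.0 - self.alpha) / (1.0 - self.alpha)

    e0 = property(lambda self: math.inf)
    e_inf = property(lambda self: 0.0)


@dataclass(frozen=True)
class _MLTerm:
    """pref * u^(mu-1) * E_[a,mu](-c u^a); cumulative pref * u^mu * E_[a,mu+1](-c u^a)."""

    pref: float
    a: float
    mu: float  # 0 < mu <= 1 in the catalogue
    c: float

    def value(self, u):
        u = np.asarray(u, dtype=float)
        return self.pref * u ** (self.mu - 1.0) * mittag_leffler(self.a, -self.c * u**self.a, self.mu)

    def cumulative(self, u):
        u = np.asarray(u, dtype=float)
        return self.pref * u**self.mu * mittag_leffler(self.a, -self.c * u**self.a, self.mu + 1.0)

    @property
    def e0(self):
        if self.mu < 1.0:
            return math.inf
        return self.pref  # mu == 1: E_[a,1](0) = 1

    e_inf = property(lambda self: 0.0)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class RelaxationModel:
    """A relaxation function split into regular terms and a Dirac-delta part.

    Attributes
    ----------
    name : str
        Catalogue name.
    params : dict
        The canonical parameters the model was built from.
    delta_coeff : float
        Coefficient of ``eta * delta_D(t)`` [Pa s]; zero unless a free
        dashpot sits in parallel.
    E0, E_inf : float
        Instantaneous and long-term moduli; ``E0`` may be ``inf`` for
        springpot-containing models whose modulus diverges at t -> 0.
    char_time : float or None
        The model's primary characteristic time [s] (None for spring
        and dashpot, 1 s reference for the bare springpot).
    char_times : dict
        All named characteristic times (e.g. SLS has both ``tau_rel``
        and ``tau_creep``).
    """

    name: str
    params: dict
    terms: tuple
    delta_coeff: float = 0.0
    char_time: float | None = None
    char_times: dict = field(default_factory=dict)
    fit_info: dict | None = None

    @property
    def E0(self) -> float:
        if self.delta_coeff > 0.0:
            return math.inf
        if not self.terms:
            return 0.0
        return sum(t.e0 for t in self.terms)

    @property
    def E_inf(self) -> float:
        return sum((t.e_inf for t in self.terms), 0.0)

    @property
    def has_ml(self) -> bool:
        return any(isinstance(t, _MLTerm) for t in self.terms)

    def evaluate(self, t):
        """Regular part ``E_reg(t)`` [Pa] for strictly positive times."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape if t.ndim else ())
        for term in self.terms:
            out = out + term.value(t)
        return out

    def cumulative(self, u):
        """Exact running integral ``int_0^u E_reg(s) ds`` [Pa s] for u >= 0."""
        u = np.asarray(u, dtype=float)
        out = np.zeros(u.shape if u.ndim else ())
        for term in self.terms:
            out = out + np.where(u > 0, term.cumulative(np.maximum(u, 1e-300)), 0.0)
        return out


MODEL_NAMES = (
    "spring",
    "dashpot",
    "kelvin_voigt",
    "maxwell",
    "sls",
    "gen_maxwell",
    "springpot",
    "fractional_kv",
    "springpot_spring_series",
    "springpot_dashpot_parallel",
    "springpot_dashpot_series",
    "two_springpots_parallel",
    "two_springpots_series",
    "fractional_sls",
    "fractional_sls_dashpot",
)


def _need(params: dict, *keys: str) -> list[float]:
    missing = [k for k in keys if k not in params]
    if missing:
        raise ValueError(f"missing parameter(s) {missing} (have {sorted(params)})")
    return [float(params[k]) for k in keys]


def _positive(**kv):
    for k, v in kv.items():
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"parameter {k} must be positive and finite, got {v}")


def _frac_exponent(name: str, v: float, *, allow_zero=False, allow_one=False):
    lo_ok = v > 0 or (allow_zero and v == 0)
    hi_ok = v < 1 or (allow_one and v == 1)
    if not (lo_ok and hi_ok):
        lo = "[0" if allow_zero else "(0"
        hi = "1]" if allow_one else "1)"
        raise ValueError(f"exponent {name} must lie in {lo}, {hi}, got {v}")


def build_model(name: str, params: dict) -> RelaxationModel:
    """Construct a catalogued relaxation model from named parameters.

    ``params`` uses the canonical names from the module docstring.  For
    exponential models either the characteristic time (``tau``) or the
    dashpot viscosity (``eta``) may be given; for ML-kernel models
    either the springpot modulus (``E_alpha1``) or the transition time
    (``tau``).

    Raises
    ------
    ValueError
        Unknown model name, missing parameter, out-of-range parameter,
        or ``beta >= alpha`` for the two-springpot models.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; known models: {', '.join(MODEL_NAMES)}")
    p = {k: float(v) for k, v in params.items()} if params else {}
    builder = _BUILDERS[name]
    return builder(p)


def _build_spring(p):
    (E,) = _need(p, "E") if "E" in p else _need(p, "E0") if "E0" in p else _need(p, "E_inf")
    _positive(E=E)
    return RelaxationModel("spring", {"E": E}, (_Const(E),))


def _build_dashpot(p):
    (eta,) = _need(p, "eta")
    _positive(eta=eta)
    return RelaxationModel("dashpot", {"eta": eta}, (), delta_coeff=eta)


def _build_kelvin_voigt(p):
    E_inf, eta = _need(p, "E_inf", "eta")
    _positive(E_inf=E_inf, eta=eta)
    tau = eta / E_inf
    return RelaxationModel(
        "kelvin_voigt", {"E_inf": E_inf, "eta": eta}, (_Const(E_inf),),
        delta_coeff=eta, char_time=tau, char_times={"tau_KV": tau},
    )


def _build_maxwell(p):
    (E0,) = _need(p, "E0")
    _positive(E0=E0)
    if "tau" in p:
        tau = float(p["tau"])
        eta = tau * E0
    else:
        (eta,) = _need(p, "eta")
        tau = eta / E0
    _positive(tau=tau)
    return RelaxationModel(
        "maxwell", {"E0": E0, "eta": eta}, (_Exp(E0, tau),),
        char_time=tau, char_times={"tau_MW": tau},
    )


def _build_sls(p):
    E0, E_inf = _need(p, "E0", "E_inf")
    _positive(E0=E0, E_inf=E_inf)
    if E0 <= E_inf:
        raise ValueError(f"SLS requires E0 > E_inf, got E0={E0}, E_inf={E_inf}")
    if "tau" in p:
        tau = float(p["tau"])
        eta = tau * (E0 - E_inf)
    else:
        (eta,) = _need(p, "eta")
        tau = eta / (E0 - E_inf)
    _positive(tau=tau)
    tau_creep = E0 * eta / (E_inf * (E0 - E_inf))
    return RelaxationModel(
        "sls", {"E0": E0, "E_inf": E_inf, "eta": eta},
        (_Exp(E0 - E_inf, tau), _Const(E_inf)),
        char_time=tau, char_times={"tau_rel": tau, "tau_creep": tau_creep},
    )


def _build_gen_maxwell(p):
    # accept either explicit lists or the E_s1/tau1, E_s2/tau2, ..., E_inf naming;
    # a trailing E_s<k> without tau<k> is the long-term spring
    if "E_terms" in p or "tau_terms" in p:
        raise ValueError("pass gen_maxwell arms as E_s1/tau1, E_s2/tau2, ... plus E_inf")
    arms = []
    i = 1
    while f"E_s{i}" in p and f"tau{i}" in p:
        arms.append((float(p[f"E_s{i}"]), float(p[f"tau{i}"])))
        i += 1
    if f"E_s{i}" in p and "E_inf" not in p:
        E_inf = float(p[f"E_s{i}"])
    else:
        E_inf = float(p.get("E_inf", 0.0))
    if not arms:
        raise ValueError("gen_maxwell needs at least one (E_s<i>, tau<i>) arm")
    terms = []
    canon = {}
    for j, (E, tau) in enumerate(arms, start=1):
        _positive(**{f"E_s{j}": E, f"tau{j}": tau})
        terms.append(_Exp(E, tau))
        canon[f"E_s{j}"] = E
        canon[f"tau{j}"] = tau
    if E_inf < 0:
        raise ValueError("E_inf must be non-negative")
    if E_inf > 0:
        terms.append(_Const(E_inf))
    canon["E_inf"] = E_inf
    taus = sorted(t for _, t in arms)
    return RelaxationModel(
        "gen_maxwell", canon, tuple(terms),
        char_time=taus[0], char_times={f"tau{j+1}": t for j, t in enumerate(taus)},
    )


def _build_springpot(p):
    E_a1, alpha = _need(p, "E_alpha1", "alpha")
    _positive(E_alpha1=E_a1)
    _frac_exponent("alpha", alpha)
    return RelaxationModel(
        "springpot", {"E_alpha1": E_a1, "alpha": alpha}, (_Power(E_a1, alpha),),
        char_time=1.0, char_times={"tau_ref": 1.0},
    )


def _build_fractional_kv(p):
    E_a1, alpha, E_inf = _need(p, "E_alpha1", "alpha", "E_inf")
    _positive(E_alpha1=E_a1, E_inf=E_inf)
    _frac_exponent("alpha", alpha)
    tau = (E_a1 / E_inf) ** (1.0 / alpha)
    return RelaxationModel(
        "fractional_kv", {"E_alpha1": E_a1, "alpha": alpha, "E_inf": E_inf},
        (_Power(E_a1, alpha), _Const(E_inf)),
        char_time=tau, char_times={"tau": tau},
    )


def _build_springpot_spring_series(p):
    E0, alpha = _need(p, "E0", "alpha")
    _positive(E0=E0)
    _frac_exponent("alpha", alpha, allow_one=True)
    if "E_alpha1" in p:
        E_a1 = float(p["E_alpha1"])
        _positive(E_alpha1=E_a1)
        tau = (E_a1 / E0) ** (1.0 / alpha)
    else:
        (tau,) = _need(p, "tau")
        _positive(tau=tau)
        E_a1 = E0 * tau**alpha
    term = _MLTerm(pref=E0, a=alpha, mu=1.0, c=E0 / E_a1)
    return RelaxationModel(
        "springpot_spring_series", {"E0": E0, "alpha": alpha, "E_alpha1": E_a1},
        (term,), char_time=tau, char_times={"tau": tau},
    )


def _build_springpot_dashpot_parallel(p):
    E_a1, alpha, eta = _need(p, "E_alpha1", "alpha", "eta")
    _positive(E_alpha1=E_a1, eta=eta)
    _frac_exponent("alpha", alpha)
    # dashpot = springpot with exponent 1, "modulus" eta: parallel transition time
    tau = (eta / E_a1) ** (1.0 / (1.0 - alpha))
    return RelaxationModel(
        "springpot_dashpot_parallel", {"E_alpha1": E_a1, "alpha": alpha, "eta": eta},
        (_Power(E_a1, alpha),), delta_coeff=eta,
        char_time=tau, char_times={"tau": tau},
    )


def _springpot_dashpot_series_term(E_b1, beta, eta):
    if beta == 0.0:
        # reduces to the Maxwell kernel E_b1 * exp(-t / (eta/E_b1))
        return _Exp(E_b1, eta / E_b1)
    pref = eta ** (beta / (beta - 1.0)) * E_b1 ** (1.0 / (1.0 - beta))
    return _MLTerm(pref=pref, a=1.0 - beta, mu=1.0 - beta, c=E_b1 / eta)


def _build_springpot_dashpot_series(p):
    E_b1, beta, eta = _need(p, "E_beta1", "beta", "eta")
    _positive(E_beta1=E_b1, eta=eta)
    _frac_exponent("beta", beta, allow_zero=True)
    tau = (eta / E_b1) ** (1.0 / (1.0 - beta))
    return RelaxationModel(
        "springpot_dashpot_series", {"E_beta1": E_b1, "beta": beta, "eta": eta},
        (_springpot_dashpot_series_term(E_b1, beta, eta),),
        char_time=tau, char_times={"tau": tau},
    )


def _check_beta_lt_alpha(alpha, beta):
    if beta >= alpha:
        raise ValueError(f"two-springpot models require beta < alpha, got alpha={alpha}, beta={beta}")


def _build_two_springpots_parallel(p):
    E_a1, alpha, E_b1, beta = _need(p, "E_alpha1", "alpha", "E_beta1", "beta")
    _positive(E_alpha1=E_a1, E_beta1=E_b1)
    _frac_exponent("alpha", alpha)
    _frac_exponent("beta", beta, allow_zero=True)
    _check_beta_lt_alpha(alpha, beta)
    tau = (E_a1 / E_b1) ** (1.0 / (alpha - beta))
    term_b = _Const(E_b1) if beta == 0.0 else _Power(E_b1, beta)
    return RelaxationModel(
        "two_springpots_parallel",
        {"E_alpha1": E_a1, "alpha": alpha, "E_beta1": E_b1, "beta": beta},
        (_Power(E_a1, alpha), term_b),
        char_time=tau, char_times={"tau_parallel": tau},
    )


def _build_two_springpots_series(p):
    E_a1, alpha, E_b1, beta = _need(p, "E_alpha1", "alpha", "E_beta1", "beta")
    _positive(E_alpha1=E_a1, E_beta1=E_b1)
    _frac_exponent("alpha", alpha, allow_one=True)
    _frac_exponent("beta", beta, allow_zero=True)
    _check_beta_lt_alpha(alpha, beta)
    if beta == 0.0:
        # springpot + spring in series: ML_alpha kernel with E0 = E_beta1
        term = _MLTerm(pref=E_b1, a=alpha, mu=1.0, c=E_b1 / E_a1)
    else:
        pref = E_a1 ** (beta / (beta - alpha)) * E_b1 ** (alpha / (alpha - beta))
        term = _MLTerm(pref=pref, a=alpha - beta, mu=1.0 - beta, c=E_b1 / E_a1)
    tau = ((1.0 - alpha) * E_a1 / E_b1) ** (1.0 / (alpha - beta)) if alpha < 1.0 else (
        (E_a1 / E_b1) ** (1.0 / (1.0 - beta))
    )
    return RelaxationModel(
        "two_springpots_series",
        {"E_alpha1": E_a1, "alpha": alpha, "E_beta1": E_b1, "beta": beta},
        (term,), char_time=tau, char_times={"tau_serial": tau},
    )


def _build_fractional_sls(p):
    E0, E_inf, alpha = _need(p, "E0", "E_inf", "alpha")
    _positive(E0=E0, E_inf=E_inf)
    _frac_exponent("alpha", alpha, allow_one=True)
    if E0 <= E_inf:
        raise ValueError(f"fractional SLS requires E0 > E_inf, got E0={E0}, E_inf={E_inf}")
    E_s = E0 - E_inf
    if "E_alpha1" in p:
        E_a1 = float(p["E_alpha1"])
        _positive(E_alpha1=E_a1)
        tau = (E_a1 / E_s) ** (1.0 / alpha)
    else:
        (tau,) = _need(p, "tau")
        _positive(tau=tau)
        E_a1 = E_s * tau**alpha
    term = _MLTerm(pref=E_s, a=alpha, mu=1.0, c=E_s / E_a1)
    return RelaxationModel(
        "fractional_sls", {"E0": E0, "E_inf": E_inf, "alpha": alpha, "E_alpha1": E_a1},
        (term, _Const(E_inf)),
        char_time=tau, char_times={"tau_fSLS": tau},
    )


def _build_fractional_sls_dashpot(p):
    E_b1, beta, eta, E_inf = _need(p, "E_beta1", "beta", "eta", "E_inf")
    _positive(E_beta1=E_b1, eta=eta, E_inf=E_inf)
    _frac_exponent("beta", beta, allow_zero=True)
    tau = (eta / E_b1) ** (1.0 / (1.0 - beta))
    return RelaxationModel(
        "fractional_sls_dashpot",
        {"E_beta1": E_b1, "beta": beta, "eta": eta, "E_inf": E_inf},
        (_springpot_dashpot_series_term(E_b1, beta, eta), _Const(E_inf)),
        char_time=tau, char_times={"tau": tau},
    )


_BUILDERS: dict[str, Callable[[dict], RelaxationModel]] = {
    "spring": _build_spring,
    "dashpot": _build_dashpot,
    "kelvin_voigt": _build_kelvin_voigt,
    "maxwell": _build_maxwell,
    "sls": _build_sls,
    "gen_maxwell": _build_gen_maxwell,
    "springpot": _build_springpot,
    "fractional_kv": _build_fractional_kv,
    "springpot_spring_series": _build_springpot_spring_series,
    "springpot_dashpot_parallel": _build_springpot_dashpot_parallel,
    "springpot_dashpot_series": _build_springpot_dashpot_series,
    "two_springpots_parallel": _build_two_springpots_parallel,
    "two_springpots_series": _build_two_springpots_series,
    "fractional_sls": _build_fractional_sls,
    "fractional_sls_dashpot": _build_fractional_sls_dashpot,
}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def eval_relaxation(model: RelaxationModel, t):
    """Regular part of the relaxation modulus at strictly positive times.

    The Dirac-delta contribution (``model.delta_coeff``) is *not*
    included; the contact solver accounts for it analytically.
    """
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("t must be strictly positive and finite")
    return model.evaluate(t)


def time_averaged_modulus(model: RelaxationModel, t_ind: float) -> float:
    """Time average of E(t) over the first quarter of the indentation cycle.

    ``<E> = (1 / (t_ind/4)) * int_0^(t_ind/4) E(t) dt``, the quantity
    the apparent Young's modulus tracks.  The delta term contributes
    ``delta_coeff / (t_ind/4)``; the regular part is integrated in
    closed form (every catalogued term has an exact running integral,
    including the integrable ``t^-alpha`` endpoint singularity).
    """
    if not t_ind > 0:
        raise ValueError("t_ind must be positive")
    T = t_ind / 4.0
    return float((model.cumulative(T) + model.delta_coeff) / T)


def log_slope_time_average(model: RelaxationModel, t_ind: float) -> float:
    """Logarithmic slope ``d ln<E> / d ln t_ind`` at ``t_ind``.

    Central finite difference with step ratio 1.05; non-positive for
    every catalogued model (the time average inherits monotonicity).
    """
    r = 1.05
    hi = math.log(time_averaged_modulus(model, t_ind * r))
    lo = math.log(time_averaged_modulus(model, t_ind / r))
    return (hi - lo) / (2.0 * math.log(r))


def prony_approximation(model: RelaxationModel, n_terms: int, t_range: tuple[float, float]) -> RelaxationModel:
    """Least-squares Prony (generalized Maxwell) fit of the regular part.

    ``n_terms`` relaxation times are log-spaced over ``t_range`` and the
    arm moduli (plus a long-term spring) are fitted by non-negative
    least squares to ``E_reg`` on a 200-point log-time grid, weighted
    for relative error.  The returned model is a ``gen_maxwell`` whose
    ``fit_info`` records the achieved maximum relative error.

    Useful for exporting power-law kernels to tools that only accept a
    sum of exponentials (e.g. FEM packages).
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    t_lo, t_hi = float(t_range[0]), float(t_range[1])
    if not (0 < t_lo < t_hi):
        raise ValueError("t_range must satisfy 0 < t_lo < t_hi")
    taus = np.logspace(math.log10(t_lo), math.log10(t_hi), n_terms)
    grid = np.logspace(math.log10(t_lo), math.log10(t_hi), 200)
    target = model.evaluate(grid)
    if np.any(~np.isfinite(target)) or np.any(target <= 0):
        raise ValueError("model must be finite and positive on t_range")
    w = 1.0 / target  # relative-error weighting
    A = np.empty((grid.size, n_terms + 1))
    A[:, :n_terms] = np.exp(-grid[:, None] / taus[None, :])
    A[:, n_terms] = 1.0  # long-term spring
    coeffs, _ = nnls(A * w[:, None], target * w)
    fitted = A @ coeffs
    max_rel_err = float(np.max(np.abs(fitted - target) / target))
    params = {}
    j = 0
    for E, tau in zip(coeffs[:n_terms], taus):
        j += 1
        params[f"E_s{j}"] = max(E, 1e-300)  # keep arm count stable
        params[f"tau{j}"] = tau
    params["E_inf"] = coeffs[n_terms]
    out = build_model("gen_maxwell", params)
    out.fit_info = {"max_rel_error": max_rel_err, "taus": taus.tolist(), "coeffs": coeffs.tolist()}
    return out


def rescale_springpot_modulus(E_ref: float, alpha: float, tau_from: float, tau_to: float) -> float:
    """Convert a springpot modulus between reference times.

    The springpot kernel ``E(t) = E_ref * (t/tau_ref)^-alpha`` is
    invariant under ``E_ref -> E_ref * (tau_to/tau_from)^-alpha``.
    """
    return E_ref * (tau_to / tau_from) ** (-alpha)
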