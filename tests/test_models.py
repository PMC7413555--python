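"""Relaxation-function catalogue: construction, evaluation, reductions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from viscocurve import (
    MODEL_NAMES,
    build_model,
    eval_relaxation,
    log_slope_time_average,
    prony_approximation,
    time_averaged_modulus,
)

TGRID = np.logspace(-4, 3, 40)


def _example_model(name):
    """An admissible parameter set for every catalogue entry."""
    return {
        "spring": {"E": 1000.0},
        "dashpot": {"eta": 10.0},
        "kelvin_voigt": {"E_inf": 1000.0, "eta": 10.0},
        "maxwell": {"E0": 1000.0, "tau": 0.1},
        "sls": {"E0": 1000.0, "E_inf": 300.0, "tau": 0.01},
        "gen_maxwell": {"E_s1": 500.0, "tau1": 0.01, "E_s2": 100.0, "tau2": 1.0, "E_s3": 10.0},
        "springpot": {"E_alpha1": 1000.0, "alpha": 0.5},
        "fractional_kv": {"E_alpha1": 1000.0, "alpha": 0.2, "E_inf": 600.0},
        "springpot_spring_series": {"E0": 1000.0, "alpha": 0.4, "E_alpha1": 1000.0},
        "springpot_dashpot_parallel": {"E_alpha1": 1000.0, "alpha": 0.5, "eta": 1000.0},
        "springpot_dashpot_series": {"E_beta1": 1000.0, "beta": 0.3, "eta": 1e4},
        "two_springpots_parallel": {"E_alpha1": 1.0, "alpha": 0.7, "E_beta1": 1.0, "beta": 0.2},
        "two_springpots_series": {"E_alpha1": 1.0, "alpha": 0.7, "E_beta1": 1.0, "beta": 0.2},
        "fractional_sls": {"E0": 1000.0, "E_inf": 300.0, "alpha": 0.5, "tau": 0.01},
        "fractional_sls_dashpot": {"E_beta1": 1000.0, "beta": 0.3, "eta": 10.0, "E_inf": 300.0},
    }[name]


class TestConstruction:
    def test_characteristic_times(self):
        # tau_KV = eta / E_inf
        kv = build_model("kelvin_voigt", {"E_inf": 1000.0, "eta": 10.0})
        assert kv.char_time == pytest.approx(0.01)
        # tau_MW = eta / E0
        mw = build_model("maxwell", {"E0": 1000.0, "eta": 100.0})
        assert mw.char_time == pytest.approx(0.1)
        # tau_rel = eta/(E0 - E_inf): eta = 7 gives 0.01 for E0=1000, E_inf=300
        sls = build_model("sls", {"E0": 1000.0, "E_inf": 300.0, "eta": 7.0})
        assert sls.char_times["tau_rel"] == pytest.approx(0.01)
        assert sls.char_times["tau_creep"] == pytest.approx(1000.0 * 7.0 / (300.0 * 700.0))
        # fractional KV: (E_alpha1 / E_inf)^(1/alpha)
        fkv = build_model("fractional_kv", {"E_alpha1": 1000.0, "alpha": 0.2, "E_inf": 600.0})
        assert fkv.char_time == pytest.approx((1000.0 / 600.0) ** 5.0)
        # fractional SLS: (E_alpha1 / (E0-E_inf))^(1/alpha)
        fsls = build_model(
            "fractional_sls", {"E0": 1000.0, "E_inf": 300.0, "alpha": 0.5, "E_alpha1": 700.0}
        )
        assert fsls.char_time == pytest.approx(1.0)
        # two springpots, parallel and serial transition times
        par = build_model(
            "two_springpots_parallel",
            {"E_alpha1": 8.0, "alpha": 0.6, "E_beta1": 1.0, "beta": 0.1},
        )
        assert par.char_time == pytest.approx(8.0 ** (1.0 / 0.5))
        ser = build_model(
            "two_springpots_series",
            {"E_alpha1": 8.0, "alpha": 0.6, "E_beta1": 1.0, "beta": 0.1},
        )
        assert ser.char_time == pytest.approx((0.4 * 8.0) ** 2.0)

    def test_limiting_moduli(self):
        sls = build_model("sls", _example_model("sls"))
        assert sls.E0 == pytest.approx(1000.0)
        assert sls.E_inf == pytest.approx(300.0)
        assert math.isinf(build_model("springpot", _example_model("springpot")).E0)
        assert math.isinf(build_model("kelvin_voigt", _example_model("kelvin_voigt")).E0)
        gm = build_model("gen_maxwell", _example_model("gen_maxwell"))
        assert gm.E0 == pytest.approx(610.0)
        assert gm.E_inf == pytest.approx(10.0)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            build_model("not_a_model", {})
        with pytest.raises(ValueError):
            build_model("maxwell", {"E0": 1000.0})  # no time scale
        with pytest.raises(ValueError):
            build_model("spring", {"E": -5.0})
        with pytest.raises(ValueError):
            build_model("springpot", {"E_alpha1": 1000.0, "alpha": 1.2})
        # beta >= alpha is inadmissible for two-springpot networks
        with pytest.raises(ValueError):
            build_model(
                "two_springpots_parallel",
                {"E_alpha1": 1.0, "alpha": 0.3, "E_beta1": 1.0, "beta": 0.5},
            )
        with pytest.raises(ValueError):
            build_model("sls", {"E0": 300.0, "E_inf": 1000.0, "tau": 0.1})


class TestEvaluation:
    def test_pointwise_examples(self):
        spring = build_model("spring", {"E": 1000.0})
        assert eval_relaxation(spring, [1e-3, 1.0, 50.0]) == pytest.approx([1000.0] * 3)
        mw = build_model("maxwell", {"E0": 1000.0, "tau": 1.0})
        assert eval_relaxation(mw, 1.0) == pytest.approx(1000.0 * math.exp(-1.0))
        sp = build_model("springpot", {"E_alpha1": 1000.0, "alpha": 0.5})
        assert eval_relaxation(sp, 4.0) == pytest.approx(500.0)

    def test_rejects_nonpositive_times(self):
        m = build_model("spring", {"E": 1.0})
        with pytest.raises(ValueError):
            eval_relaxation(m, [0.0, 1.0])
        with pytest.raises(ValueError):
            eval_relaxation(m, -1.0)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_nonincreasing_everywhere(self, name):
        m = build_model(name, _example_model(name))
        vals = m.evaluate(TGRID)
        assert np.all(vals >= 0)
        assert np.all(np.diff(vals) <= 1e-12 * vals[0] if vals[0] > 0 else True)

    @given(
        alpha=st.floats(0.05, 0.95),
        e_ratio=st.floats(0.01, 0.99),
        tau=st.floats(1e-3, 1e2),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fractional_sls_monotone_for_random_parameters(self, alpha, e_ratio, tau):
        m = build_model(
            "fractional_sls",
            {"E0": 1000.0, "E_inf": 1000.0 * e_ratio, "alpha": alpha, "tau": tau},
        )
        vals = m.evaluate(np.logspace(-3, 3, 25))
        assert np.all(np.diff(vals) <= 1e-9 * vals[0])
        assert np.all(vals >= 0)


class TestReductions:
    """Fractional models collapse onto classical ones at boundary exponents."""

    def _rel_diff(self, a, b):
        va, vb = a.evaluate(TGRID), b.evaluate(TGRID)
        keep = np.abs(vb) > 1e-290  # both vanish identically below underflow
        assert np.all(np.abs(va[~keep]) <= 1e-290)
        return np.max(np.abs(va[keep] - vb[keep]) / np.abs(vb[keep]))

    def test_serial_springpots_alpha_one_is_springpot_dashpot_series(self):
        two = build_model(
            "two_springpots_series",
            {"E_alpha1": 1e4, "alpha": 1.0, "E_beta1": 1000.0, "beta": 0.3},
        )
        sd = build_model(
            "springpot_dashpot_series", {"E_beta1": 1000.0, "beta": 0.3, "eta": 1e4}
        )
        assert self._rel_diff(two, sd) < 1e-6

    def test_serial_springpots_beta_zero_is_springpot_spring_series(self):
        two = build_model(
            "two_springpots_series",
            {"E_alpha1": 2000.0, "alpha": 0.4, "E_beta1": 1000.0, "beta": 0.0},
        )
        ss = build_model(
            "springpot_spring_series", {"E0": 1000.0, "alpha": 0.4, "E_alpha1": 2000.0}
        )
        assert self._rel_diff(two, ss) < 1e-6

    def test_fractional_sls_dashpot_beta_zero_is_sls(self):
        fsd = build_model(
            "fractional_sls_dashpot",
            {"E_beta1": 700.0, "beta": 0.0, "eta": 7.0, "E_inf": 300.0},
        )
        sls = build_model("sls", {"E0": 1000.0, "E_inf": 300.0, "eta": 7.0})
        assert self._rel_diff(fsd, sls) < 1e-6

    def test_fractional_sls_alpha_one_is_sls(self):
        # exponential limit of the Mittag-Leffler kernel (independent code path)
        fsls = build_model(
            "fractional_sls", {"E0": 1000.0, "E_inf": 300.0, "alpha": 1.0, "tau": 0.01}
        )
        sls = build_model("sls", {"E0": 1000.0, "E_inf": 300.0, "tau": 0.01})
        assert self._rel_diff(fsls, sls) < 1e-6

    def test_springpot_spring_series_alpha_one_is_maxwell(self):
        ss = build_model("springpot_spring_series", {"E0": 1000.0, "alpha": 1.0, "tau": 0.05})
        mw = build_model("maxwell", {"E0": 1000.0, "tau": 0.05})
        assert self._rel_diff(ss, mw) < 1e-6


class TestTimeAverage:
    def test_matches_closed_forms(self):
        # spring: average of a constant
        spring = build_model("spring", {"E": 1000.0})
        assert time_averaged_modulus(spring, 3.7) == pytest.approx(1000.0, rel=1e-12)
        # maxwell, t_ind = 4 s, tau = 1 s: E0 (1 - e^-1)
        mw = build_model("maxwell", {"E0": 1000.0, "tau": 1.0})
        assert time_averaged_modulus(mw, 4.0) == pytest.approx(
            1000.0 * (1.0 - math.exp(-1.0)), rel=1e-9
        )
        # springpot: E_alpha1 (t_ind/4)^-alpha / (1 - alpha)
        sp = build_model("springpot", {"E_alpha1": 1000.0, "alpha": 0.3})
        for t_ind in (0.013, 4.0, 210.0):
            expect = 1000.0 * (t_ind / 4.0) ** -0.3 / 0.7
            assert time_averaged_modulus(sp, t_ind) == pytest.approx(expect, rel=1e-9)

    @pytest.mark.parametrize("name", ["sls", "fractional_sls", "springpot_dashpot_series"])
    def test_matches_adaptive_quadrature(self, name):
        """Independent route: direct quadrature of the evaluated kernel."""
        m = build_model(name, _example_model(name))
        T = 0.02
        ref, _ = quad(lambda s: float(m.evaluate(s)), 0.0, T, limit=300, points=[T * 1e-6])
        assert time_averaged_modulus(m, 4 * T) == pytest.approx(ref / T, rel=1e-5)

    def test_delta_term_contribution(self):
        # KV average = E_inf + eta / (t_ind/4)
        kv = build_model("kelvin_voigt", {"E_inf": 1000.0, "eta": 10.0})
        assert time_averaged_modulus(kv, 0.4) == pytest.approx(1000.0 + 10.0 / 0.1, rel=1e-12)

    def test_log_slope(self):
        spring = build_model("spring", {"E": 1000.0})
        assert log_slope_time_average(spring, 1.0) == pytest.approx(0.0, abs=1e-12)
        sp = build_model("springpot", {"E_alpha1": 1000.0, "alpha": 0.3})
        assert log_slope_time_average(sp, 7.3) == pytest.approx(-0.3, abs=1e-9)
        # SLS far below the relaxation time: instantaneous plateau, slope ~ 0
        sls = build_model("sls", _example_model("sls"))
        assert abs(log_slope_time_average(sls, 1e-5 * 0.01)) < 1e-3


class TestProny:
    def test_recovers_gen_maxwell_exactly(self):
        gm = build_model(
            "gen_maxwell",
            {"E_s1": 500.0, "tau1": 0.01, "E_s2": 100.0, "tau2": 1.0, "E_inf": 10.0},
        )
        fit = prony_approximation(gm, 6, (1e-3, 1e2))  # 0.01 and 1.0 are grid nodes
        assert fit.name == "gen_maxwell"
        assert fit.fit_info["max_rel_error"] < 1e-6

    def test_six_terms_fit_power_law_within_five_percent(self):
        sp = build_model("springpot", {"E_alpha1": 1000.0, "alpha": 0.2})
        fit = prony_approximation(sp, 6, (1e-3, 1e3))
        assert fit.fit_info["max_rel_error"] < 0.05
        grid = np.logspace(-3, 3, 50)
        assert np.max(np.abs(fit.evaluate(grid) - sp.evaluate(grid)) / sp.evaluate(grid)) < 0.05

    def test_invalid_inputs(self):
        sp = build_model("springpot", {"E_alpha1": 1000.0, "alpha": 0.2})
        with pytest.raises(ValueError):
            prony_approximation(sp, 0, (1e-3, 1e3))
        with pytest.raises(ValueError):
            prony_approximation(sp, 6, (1.0, 0.1))
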