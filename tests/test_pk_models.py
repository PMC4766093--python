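"""Forward tracer-kinetic models: closed forms, nested identities, and
agreement with an independent ODE integrator."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from littdce.curves import ConcentrationCurve
from littdce.pk_models import (
    CTUParams,
    ExtToftsParams,
    ToftsParams,
    TwoCXMParams,
    _twocxm_values,
    convolve_exponential,
    ctu_forward,
    ext_tofts_forward,
    forward_model,
    tofts_forward,
    twocxm_forward,
)


def constant_aif(value=1.0, t_max=6.0, n=37):
    t = np.linspace(0.0, t_max, n)
    return ConcentrationCurve(t, np.full(n, value))


# ---------------------------------------------------------------------------
# exponential convolution kernel
# ---------------------------------------------------------------------------


class TestConvolveExponential:
    def test_rate_zero_reduces_to_cumulative_integral(self):
        aif = constant_aif(1.0, 2.0, 21)
        out = convolve_exponential(aif, 0.0)
        assert np.allclose(out, aif.times, atol=1e-12)

    def test_zero_aif_gives_zeros(self):
        t = np.linspace(0, 6, 37)
        out = convolve_exponential(ConcentrationCurve(t, np.zeros(37)), 1.3)
        assert np.all(out == 0.0)

    @pytest.mark.parametrize("rate", [0.05, 0.7, 3.0, 8.0])
    def test_matches_dense_trapezoid_quadrature(self, rate):
        # rates within the oracle's own validity: the dt=1e-3 trapezoid
        # reference itself degrades as O((rate*dt)^2)
        # knots on multiples of 0.01 so the dense dt=1e-3 grid hits them
        rng = np.random.default_rng(3)
        t = np.arange(0, 6.01, 0.25)
        c = np.abs(rng.normal(1.0, 0.5, len(t)))
        aif = ConcentrationCurve(t, c)
        out = convolve_exponential(aif, rate)

        dense_t = np.arange(0.0, 6.0 + 1e-12, 1e-3)
        dense_c = np.interp(dense_t, t, c)
        for k in (4, 12, 24):
            m = dense_t <= t[k] + 1e-12
            ref = np.trapezoid(
                dense_c[m] * np.exp(-rate * (t[k] - dense_t[m])), dense_t[m]
            )
            assert out[k] == pytest.approx(ref, rel=1e-4)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            convolve_exponential(constant_aif(), -0.1)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationCurve(np.array([0.0]), np.array([1.0]))


# ---------------------------------------------------------------------------
# standard Tofts model
# ---------------------------------------------------------------------------


class TestTofts:
    def test_constant_input_closed_form(self):
        # C_t(t) = A v_e (1 - exp(-K^trans t / v_e)) for a step input
        aif = constant_aif(1.0, 6.0, 361)
        p = ToftsParams(0.22, 0.3)
        ct = tofts_forward(p, aif)
        expected = 0.3 * (1.0 - np.exp(-(0.22 / 0.3) * aif.times))
        assert np.allclose(ct.values[1:], expected[1:], rtol=1e-6)
        i = np.argmin(np.abs(aif.times - 1.0))
        assert ct.values[i] == pytest.approx(0.1559, abs=5e-5)

    def test_zero_ktrans_gives_zero_curve(self, aif):
        ct = tofts_forward(ToftsParams(0.0, 0.4), aif)
        assert np.all(ct.values == 0.0)

    def test_ve_zero_with_transfer_rejected(self):
        with pytest.raises(ValueError):
            ToftsParams(0.3, 0.0)

    def test_impulse_response_area_equals_ve(self):
        # ∫ K^trans exp(-K^trans t/v_e) dt = v_e; approximate the impulse
        # with a narrow triangle of unit area
        kt, ve = 0.5, 0.25
        width = 1e-3
        t_max = 25.0 * ve / kt
        t = np.unique(np.concatenate([
            [0.0, width / 2, width],
            np.linspace(width, t_max, 4000),
        ]))
        c = np.where(t <= width, 2.0 / width * (1 - np.abs(2 * t / width - 1)), 0.0)
        ct = tofts_forward(ToftsParams(kt, ve), ConcentrationCurve(t, c))
        auc = np.trapezoid(ct.values, t)
        assert auc == pytest.approx(ve, rel=1e-4)


# ---------------------------------------------------------------------------
# nested-model identities
# ---------------------------------------------------------------------------


class TestNestedIdentities:
    def test_ext_tofts_vp_zero_equals_tofts(self, aif):
        e = ext_tofts_forward(ExtToftsParams(0.4, 0.3, 0.0), aif)
        t = tofts_forward(ToftsParams(0.4, 0.3), aif)
        assert np.allclose(e.values, t.values, atol=1e-10)

    def test_ext_tofts_zero_transfer_is_scaled_aif(self, aif):
        e = ext_tofts_forward(ExtToftsParams(0.0, 0.3, 0.05), aif)
        assert np.allclose(e.values, 0.05 * aif.values, atol=1e-12)

    def test_ext_tofts_decomposition(self, aif):
        e = ext_tofts_forward(ExtToftsParams(0.3, 0.25, 0.08), aif)
        t = tofts_forward(ToftsParams(0.3, 0.25), aif)
        assert np.allclose(e.values, t.values + 0.08 * aif.values, atol=1e-12)

    def test_ctu_ps_zero_is_plasma_compartment(self, aif):
        fp, vp = 0.8, 0.06
        c = ctu_forward(CTUParams(fp, 0.0, vp), aif)
        plasma = fp * convolve_exponential(aif, fp / vp)
        assert np.allclose(c.values, plasma, atol=1e-12)

    def test_twocxm_ps_zero_is_plasma_compartment(self, aif):
        fp, vp = 0.8, 0.06
        c = twocxm_forward(TwoCXMParams(fp, 0.0, vp, 0.3), aif)
        plasma = fp * convolve_exponential(aif, fp / vp)
        assert np.allclose(c.values, plasma, atol=1e-9)

    def test_twocxm_high_flow_limit_is_ext_tofts(self, aif):
        ps, vp, ve = 0.3, 0.05, 0.4
        m2 = twocxm_forward(TwoCXMParams(1000.0, ps, vp, ve), aif)
        me = ext_tofts_forward(ExtToftsParams(ps, ve, vp), aif)
        rel = np.max(np.abs(m2.values - me.values)) / np.max(np.abs(me.values))
        assert rel < 1e-2

    def test_ctu_is_no_backflux_limit_of_twocxm(self, aif):
        # v_e -> infinity kills backflux; exercised through the internal
        # evaluator because the public parameter type bounds v_e <= 1
        fp, ps, vp = 0.8, 0.4, 0.06
        c = ctu_forward(CTUParams(fp, ps, vp), aif).values
        big = _twocxm_values(fp, ps, vp, 5e3, aif.times, aif.values)[0]
        assert np.max(np.abs(c - big)) / np.max(np.abs(c)) < 1e-3


# ---------------------------------------------------------------------------
# ODE-integrator oracle
# ---------------------------------------------------------------------------


def _ode_reference(model_id, theta, aif):
    ca = interp1d(aif.times, aif.values, bounds_error=False, fill_value=0.0)
    if model_id == "tofts":
        kt, ve = theta

        def f(t, y):
            return [kt * ca(t) - (kt / ve) * y[0]]

        sol = solve_ivp(f, (0, aif.times[-1]), [0.0], t_eval=aif.times,
                        rtol=1e-10, atol=1e-13, max_step=0.02)
        return sol.y[0]
    if model_id == "ext_tofts":
        kt, ve, vp = theta
        return _ode_reference("tofts", (kt, ve), aif) + vp * aif.values
    if model_id == "ctu":
        fp, ps, vp = theta

        def f(t, y):
            cp, qe = y
            return [(fp * (ca(t) - cp) - ps * cp) / vp, ps * cp]

        sol = solve_ivp(f, (0, aif.times[-1]), [0.0, 0.0], t_eval=aif.times,
                        rtol=1e-10, atol=1e-13, max_step=0.02)
        return vp * sol.y[0] + sol.y[1]
    if model_id == "twocxm":
        fp, ps, vp, ve = theta

        def f(t, y):
            cp, ce = y
            return [
                (fp * (ca(t) - cp) + ps * (ce - cp)) / vp,
                ps * (cp - ce) / ve,
            ]

        sol = solve_ivp(f, (0, aif.times[-1]), [0.0, 0.0], t_eval=aif.times,
                        rtol=1e-10, atol=1e-13, max_step=0.02)
        return vp * sol.y[0] + ve * sol.y[1]
    raise ValueError(model_id)


def _random_params(model_id, rng):
    if model_id == "tofts":
        return ToftsParams(rng.uniform(0.05, 2.0), rng.uniform(0.1, 0.8))
    if model_id == "ext_tofts":
        ve = rng.uniform(0.1, 0.7)
        return ExtToftsParams(rng.uniform(0.05, 2.0), ve, rng.uniform(0.0, 0.2))
    if model_id == "ctu":
        return CTUParams(rng.uniform(0.2, 2.0), rng.uniform(0.0, 1.0),
                         rng.uniform(0.02, 0.2))
    ve = rng.uniform(0.1, 0.6)
    return TwoCXMParams(rng.uniform(0.2, 2.0), rng.uniform(0.02, 1.0),
                        rng.uniform(0.02, 0.2), ve)


@pytest.mark.parametrize("model_id", ["tofts", "ext_tofts", "ctu", "twocxm"])
def test_forward_models_match_ode_oracle(model_id, aif):
    rng = np.random.default_rng(42)
    for _ in range(20):
        params = _random_params(model_id, rng)
        theta = tuple(getattr(params, f) for f in params.__dataclass_fields__)
        ours = forward_model(model_id, params, aif).values
        ref = _ode_reference(model_id, theta, aif)
        scale = np.max(np.abs(ref))
        assert np.max(np.abs(ours - ref)) / scale < 1e-4


# ---------------------------------------------------------------------------
# shared properties
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("model_id", ["tofts", "ext_tofts", "ctu", "twocxm"])
def test_linearity_in_input(model_id, aif):
    rng = np.random.default_rng(9)
    params = _random_params(model_id, rng)
    scaled = ConcentrationCurve(aif.times, 2.5 * aif.values)
    base = forward_model(model_id, params, aif).values
    out = forward_model(model_id, params, scaled).values
    assert np.allclose(out, 2.5 * base, rtol=1e-12, atol=1e-12)


@pytest.mark.parametrize("model_id", ["tofts", "ext_tofts", "ctu", "twocxm"])
def test_output_zero_while_aif_zero(model_id, t_minutes):
    rng = np.random.default_rng(11)
    params = _random_params(model_id, rng)
    vals = np.where(t_minutes >= 2.0, 1.0, 0.0)  # input arrives at t=2
    aif = ConcentrationCurve(t_minutes, vals)
    out = forward_model(model_id, params, aif).values
    assert np.all(out[t_minutes < 2.0] == 0.0)


def test_parameter_validation():
    with pytest.raises(ValueError):
        ToftsParams(-0.1, 0.3)
    with pytest.raises(ValueError):
        ToftsParams(7.0, 0.3)  # above the prior support
    with pytest.raises(ValueError):
        ExtToftsParams(0.2, 0.8, 0.3)  # ve + vp > 1
    with pytest.raises(ValueError):
        CTUParams(0.0, 0.1, 0.05)
    with pytest.raises(ValueError):
        TwoCXMParams(1.0, 0.1, 0.6, 0.6)  # vp + ve > 1
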