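"""Forward tracer-kinetic models for DCE-MRI.

Four standard compartment models map an arterial input function (AIF,
plasma concentration C_a in mM vs. minutes) and kinetic parameters to a
tissue concentration curve C_t:

* standard Tofts: C_t(t) = K^trans ∫ C_a(τ) exp(−(K^trans/v_e)(t−τ)) dτ
* extended Tofts: adds a vascular term v_p·C_a(t)
* compartment tissue-uptake (CTU): plasma flow F_p, irreversible
  extraction PS into the interstitium (no backflux)
* two-compartment exchange (2CXM): bidirectional exchange, a
  bi-exponential impulse response

All four are linear time-invariant in C_a, so every forward evaluation
reduces to weighted sums of exponential convolutions with the AIF.  The
convolution kernel is exact for a piecewise-linear AIF (recursive
closed form per sampling interval), which stays accurate at the coarse
10 s frame spacing of a clinical dynamic series where naive trapezoid
rules do not.

Parameter units follow the DCE literature: K^trans and PS in 1/min,
F_p in mL plasma/min/mL tissue, v_e and v_p dimensionless fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .curves import ConcentrationCurve

__all__ = [
    "ToftsParams",
    "ExtToftsParams",
    "CTUParams",
    "TwoCXMParams",
    "ModelSpec",
    "MODEL_SPECS",
    "convolve_exponential",
    "tofts_forward",
    "ext_tofts_forward",
    "ctu_forward",
    "twocxm_forward",
    "forward_model",
    "forward_model_matrix",
]

# Prior support for K^trans is 0–6.0 1/min and 0–1 for v_e; vascular and
# flow parameters use physiologic defaults (configurable in PriorSpec).
KTRANS_MAX = 6.0


@dataclass(frozen=True)
class ToftsParams:
    """Standard Tofts model: transfer constant and interstitial fraction."""

    ktrans: float  # 1/min
    ve: float  # fraction

    def __post_init__(self) -> None:
        if not 0.0 <= self.ktrans <= KTRANS_MAX:
            raise ValueError(f"ktrans {self.ktrans} outside [0, {KTRANS_MAX}] 1/min")
        if not 0.0 < self.ve <= 1.0:
            raise ValueError(f"ve {self.ve} outside (0, 1]")


@dataclass(frozen=True)
class ExtToftsParams:
    """Extended Tofts model: Tofts plus a plasma volume fraction v_p."""

    ktrans: float
    ve: float
    vp: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ktrans <= KTRANS_MAX:
            raise ValueError(f"ktrans {self.ktrans} outside [0, {KTRANS_MAX}] 1/min")
        if not 0.0 < self.ve <= 1.0:
            raise ValueError(f"ve {self.ve} outside (0, 1]")
        if not 0.0 <= self.vp <= 1.0:
            raise ValueError(f"vp {self.vp} outside [0, 1]")
        if self.ve + self.vp > 1.0 + 1e-12:
            raise ValueError("ve + vp exceeds 1")


@dataclass(frozen=True)
class CTUParams:
    """Compartment tissue-uptake model: irreversible two-compartment uptake."""

    fp: float  # mL plasma / min / mL tissue
    ps: float  # 1/min
    vp: float  # fraction

    def __post_init__(self) -> None:
        if not self.fp > 0:
            raise ValueError("fp must be positive")
        if self.ps < 0:
            raise ValueError("ps must be non-negative")
        if not 0.0 < self.vp <= 1.0:
            raise ValueError(f"vp {self.vp} outside (0, 1]")


@dataclass(frozen=True)
class TwoCXMParams:
    """Two-compartment exchange model (plasma <-> interstitium)."""

    fp: float
    ps: float
    vp: float
    ve: float

    def __post_init__(self) -> None:
        if not self.fp > 0:
            raise ValueError("fp must be positive")
        if self.ps < 0:
            raise ValueError("ps must be non-negative")
        if not self.vp > 0:
            raise ValueError("vp must be positive")
        if not self.ve > 0:
            raise ValueError("ve must be positive")
        if self.vp + self.ve > 1.0 + 1e-12:
            raise ValueError("vp + ve exceeds 1")


@dataclass(frozen=True)
class ModelSpec:
    """Identity, parameter names and default uniform prior bounds of a model."""

    model_id: str
    param_names: Tuple[str, ...]
    default_bounds: Dict[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        if set(self.param_names) != set(self.default_bounds):
            raise ValueError("bounds must cover exactly the model parameters")
        for name, (lo, hi) in self.default_bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite and ordered")


# Physiologic default prior boxes.  K^trans and v_e bounds follow the
# study priors; v_p, F_p, PS use conventional physiologic ranges.
MODEL_SPECS: Dict[str, ModelSpec] = {
    "tofts": ModelSpec(
        "tofts", ("ktrans", "ve"), {"ktrans": (0.0, 6.0), "ve": (0.0, 1.0)}
    ),
    "ext_tofts": ModelSpec(
        "ext_tofts",
        ("ktrans", "ve", "vp"),
        {"ktrans": (0.0, 6.0), "ve": (0.0, 1.0), "vp": (0.0, 1.0)},
    ),
    "ctu": ModelSpec(
        "ctu",
        ("fp", "ps", "vp"),
        {"fp": (0.0, 10.0), "ps": (0.0, 6.0), "vp": (0.0, 1.0)},
    ),
    "twocxm": ModelSpec(
        "twocxm",
        ("fp", "ps", "vp", "ve"),
        {"fp": (0.0, 10.0), "ps": (0.0, 6.0), "vp": (0.0, 1.0), "ve": (0.0, 1.0)},
    ),
}


def _exp_conv(times: np.ndarray, values: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """∫₀^t C(τ)·exp(−rate·(t−τ)) dτ on the sample grid, exact for
    piecewise-linear C.

    ``rates`` is a 1-D array of m non-negative rates; returns shape (m, n).
    The per-interval closed form is accumulated recursively, which is
    unconditionally stable (the carry factor exp(−r·Δt) ≤ 1).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(values, dtype=float)
    r = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(r < 0):
        raise ValueError("rate must be non-negative")
    n = len(t)
    dt = np.diff(t)  # (n-1,)
    slope = np.diff(c) / dt

    x = r[:, None] * dt[None, :]  # (m, n-1)
    E = np.exp(-x)
    rsafe = np.where(r == 0.0, 1.0, r)[:, None]
    small = x < 1e-5
    # f1 = ∫₀^Δ e^{−r(Δ−u)} du ; f2 = ∫₀^Δ u e^{−r(Δ−u)} du = (Δ − f1)/r.
    # Series branches avoid 0/0 and catastrophic cancellation at small rΔ.
    f1_exact = (1.0 - E) / rsafe
    f1 = np.where(small, dt * (1.0 - x / 2.0 + x**2 / 6.0 - x**3 / 24.0), f1_exact)
    f2 = np.where(
        small,
        dt**2 * (0.5 - x / 6.0 + x**2 / 24.0 - x**3 / 120.0),
        (dt - f1_exact) / rsafe,
    )

    g = c[:-1][None, :] * f1 + slope[None, :] * f2  # (m, n-1)
    m = len(r)
    out = np.zeros((m, n))
    if m * (n - 1) ** 2 <= 4_000_000:
        # unrolled recursion: out[k+1] = Σ_{j<=k} g_j exp(-r (t_{k+1}-t_{j+1}));
        # one masked matrix product instead of a per-interval Python loop
        delta = t[1:, None] - t[None, 1:]  # (n-1, n-1)
        keep = delta >= 0.0
        kern = np.exp(-r[:, None, None] * np.where(keep, delta, 0.0)[None, :, :])
        kern *= keep[None, :, :]
        out[:, 1:] = np.einsum("mj,mkj->mk", g, kern)
    else:
        acc = np.zeros(m)
        for k in range(n - 1):
            acc = acc * E[:, k] + g[:, k]
            out[:, k + 1] = acc
    return out


def convolve_exponential(aif: ConcentrationCurve, rate: float) -> np.ndarray:
    """Convolution of the AIF with exp(−rate·t), evaluated on the AIF grid.

    Exact for a piecewise-linear AIF.  ``rate`` is in 1/min and must be
    non-negative; ``rate == 0`` reduces to the running integral of the AIF.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return _exp_conv(aif.times, aif.values, np.array([rate]))[0]


def _tofts_values(
    ktrans: np.ndarray, ve: np.ndarray, times: np.ndarray, aif_values: np.ndarray
) -> np.ndarray:
    """Vectorised Tofts forward: rows of (ktrans, ve) -> (m, n) curves."""
    kt = np.atleast_1d(np.asarray(ktrans, dtype=float))
    v = np.atleast_1d(np.asarray(ve, dtype=float))
    if np.any((v <= 0) & (kt > 0)):
        raise ValueError("ve must be positive when ktrans > 0")
    rates = np.where(kt > 0, kt / np.where(v <= 0, 1.0, v), 0.0)
    conv = _exp_conv(times, aif_values, rates)
    return kt[:, None] * conv


def tofts_forward(params: ToftsParams, aif: ConcentrationCurve) -> ConcentrationCurve:
    """Standard Tofts tissue curve on the AIF time grid."""
    vals = _tofts_values(
        np.array([params.ktrans]), np.array([params.ve]), aif.times, aif.values
    )[0]
    return ConcentrationCurve(aif.times, vals)


def ext_tofts_forward(
    params: ExtToftsParams, aif: ConcentrationCurve
) -> ConcentrationCurve:
    """Extended Tofts: Tofts interstitial term plus v_p·C_a."""
    vals = _tofts_values(
        np.array([params.ktrans]), np.array([params.ve]), aif.times, aif.values
    )[0]
    return ConcentrationCurve(aif.times, vals + params.vp * aif.values)


def _ctu_values(
    fp: np.ndarray, ps: np.ndarray, vp: np.ndarray,
    times: np.ndarray, aif_values: np.ndarray,
) -> np.ndarray:
    """Vectorised CTU forward.

    Impulse response F_p[(1−E)e^{−t/Tp} + E], with plasma mean transit
    time Tp = v_p/(F_p+PS) and extraction fraction E = PS/(F_p+PS); the
    constant tail makes the uptake irreversible.
    """
    fp = np.atleast_1d(np.asarray(fp, dtype=float))
    ps = np.atleast_1d(np.asarray(ps, dtype=float))
    vp = np.atleast_1d(np.asarray(vp, dtype=float))
    if np.any(fp <= 0):
        raise ValueError("fp must be positive")
    tp_rate = (fp + ps) / vp
    extraction = ps / (fp + ps)
    conv_fast = _exp_conv(times, aif_values, tp_rate)
    cum = _exp_conv(times, aif_values, np.array([0.0]))[0]
    return fp[:, None] * (
        (1.0 - extraction)[:, None] * conv_fast + extraction[:, None] * cum[None, :]
    )


def ctu_forward(params: CTUParams, aif: ConcentrationCurve) -> ConcentrationCurve:
    """Compartment tissue-uptake tissue curve."""
    vals = _ctu_values(
        params.fp, params.ps, params.vp, aif.times, aif.values
    )[0]
    return ConcentrationCurve(aif.times, vals)


def _twocxm_weights(
    fp: np.ndarray, ps: np.ndarray, vp: np.ndarray, ve: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bi-exponential impulse-response decomposition of the 2CXM.

    Returns (K_plus, K_minus, w_plus, w_minus) such that the impulse
    response is w₊e^{−K₊t} + w₋e^{−K₋t}.  Derived from the eigen-system
    of the coupled plasma/interstitium mass balance; the discriminant is
    (a−c)² + 4bc ≥ 0 with a=(F_p+PS)/v_p, b=PS/v_p, c=PS/v_e, so the two
    rates coincide only in the unreachable limit PS=0 with F_p/v_p=0.
    """
    a = (fp + ps) / vp
    b = ps / vp
    c = ps / ve
    disc = np.sqrt(np.maximum((a - c) ** 2 + 4.0 * b * c, 0.0))
    k_plus = 0.5 * (a + c + disc)
    k_minus = 0.5 * (a + c - disc)
    k_minus = np.maximum(k_minus, 0.0)  # guard FP roundoff
    gap = np.maximum(k_plus - k_minus, 1e-12 * np.maximum(k_plus, 1.0))
    s = fp / vp
    w_plus = s * (vp * (k_plus - c) - ve * c) / gap
    w_minus = s * (vp * (c - k_minus) + ve * c) / gap
    return k_plus, k_minus, w_plus, w_minus


def _twocxm_values(
    fp: np.ndarray, ps: np.ndarray, vp: np.ndarray, ve: np.ndarray,
    times: np.ndarray, aif_values: np.ndarray,
) -> np.ndarray:
    fp = np.atleast_1d(np.asarray(fp, dtype=float))
    ps = np.atleast_1d(np.asarray(ps, dtype=float))
    vp = np.atleast_1d(np.asarray(vp, dtype=float))
    ve = np.atleast_1d(np.asarray(ve, dtype=float))
    if np.any(fp <= 0):
        raise ValueError("fp must be positive")
    k_plus, k_minus, w_plus, w_minus = _twocxm_weights(fp, ps, vp, ve)
    conv_plus = _exp_conv(times, aif_values, k_plus)
    conv_minus = _exp_conv(times, aif_values, k_minus)
    return w_plus[:, None] * conv_plus + w_minus[:, None] * conv_minus


def twocxm_forward(
    params: TwoCXMParams, aif: ConcentrationCurve
) -> ConcentrationCurve:
    """Two-compartment exchange tissue curve."""
    vals = _twocxm_values(
        params.fp, params.ps, params.vp, params.ve, aif.times, aif.values
    )[0]
    return ConcentrationCurve(aif.times, vals)


_PARAM_CLASSES = {
    "tofts": ToftsParams,
    "ext_tofts": ExtToftsParams,
    "ctu": CTUParams,
    "twocxm": TwoCXMParams,
}


def forward_model(model_id: str, params, aif: ConcentrationCurve) -> ConcentrationCurve:
    """Dispatch a forward evaluation by model id."""
    if model_id == "tofts":
        return tofts_forward(params, aif)
    if model_id == "ext_tofts":
        return ext_tofts_forward(params, aif)
    if model_id == "ctu":
        return ctu_forward(params, aif)
    if model_id == "twocxm":
        return twocxm_forward(params, aif)
    raise ValueError(f"unknown model id {model_id!r}")


def forward_model_matrix(
    model_id: str, theta: np.ndarray, times: np.ndarray, aif_values: np.ndarray
) -> np.ndarray:
    """Evaluate a model for many parameter rows at once.

    ``theta`` has shape (m, k) with columns ordered as in
    ``MODEL_SPECS[model_id].param_names``; returns (m, n) tissue curves.
    Rows are assumed to lie in the valid parameter domain (samplers
    enforce bounds before calling); v_e ≤ 0 rows raise.
    """
    th = np.atleast_2d(np.asarray(theta, dtype=float))
    if model_id == "tofts":
        return _tofts_values(th[:, 0], th[:, 1], times, aif_values)
    if model_id == "ext_tofts":
        base = _tofts_values(th[:, 0], th[:, 1], times, aif_values)
        return base + th[:, 2][:, None] * aif_values[None, :]
    if model_id == "ctu":
        return _ctu_values(th[:, 0], th[:, 1], th[:, 2], times, aif_values)
    if model_id == "twocxm":
        return _twocxm_values(
            th[:, 0], th[:, 1], th[:, 2], th[:, 3], times, aif_values
        )
    raise ValueError(f"unknown model id {model_id!r}")
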