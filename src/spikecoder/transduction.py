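"""Sensor front end: photodiode + load resistor mapping illuminance to V_PSV.

A photovoltaic-mode circuit: the photodiode (current source in parallel with
an ideal diode) drives a load resistor R_L, and the voltage developed across
R_L is the presynaptic voltage fed to the encoder. The operating point solves

    responsivity * p_led - i_dark * (exp(v / (n * v_t)) - 1) = v / r_load.

Illuminance ``p_led`` is treated as an arbitrary linear unit; the default
parameters are illustrative, chosen so that a three-decade illuminance sweep
covers the 0-5 V stimulus window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["PhotodiodeParams", "pd_current", "illuminance_to_vpsv", "default_photodiode"]


@dataclass(frozen=True)
class PhotodiodeParams:
    responsivity: float   # amperes per illuminance unit
    i_dark: float         # reverse saturation current (A)
    n_ideality: float
    v_thermal: float      # volts
    r_load: float         # ohms

    def __post_init__(self):
        vals = (self.responsivity, self.i_dark, self.n_ideality, self.v_thermal, self.r_load)
        if any(not (v > 0) for v in vals):
            raise ValueError("all photodiode parameters must be positive")


def default_photodiode() -> PhotodiodeParams:
    return PhotodiodeParams(
        responsivity=1e-8,
        i_dark=1e-12,
        n_ideality=2.0,
        v_thermal=0.6,
        r_load=1e7,
    )


def pd_current(v_pd, p_led, params: PhotodiodeParams):
    """Photodiode terminal current: photocurrent minus forward diode current.

    Strictly decreasing in ``v_pd`` and strictly increasing in ``p_led``.
    """
    v_pd = np.asarray(v_pd, dtype=float)
    p_led = np.asarray(p_led, dtype=float)
    if not (np.all(np.isfinite(v_pd)) and np.all(np.isfinite(p_led))):
        raise ValueError("inputs must be finite")
    out = params.responsivity * p_led - params.i_dark * (
        np.expm1(v_pd / (params.n_ideality * params.v_thermal))
    )
    if out.ndim == 0:
        return float(out)
    return out


def _vpsv_scalar(p: float, params: PhotodiodeParams) -> float:
    if p == 0.0:
        return 0.0
    # upper bound: min(open-circuit voltage, load-line voltage), plus slack
    v_oc = params.n_ideality * params.v_thermal * math.log1p(
        params.responsivity * p / params.i_dark
    )
    v_lin = params.responsivity * p * params.r_load
    hi = min(v_oc, v_lin) * (1 + 1e-9) + 1e-15
    f = lambda v: pd_current(v, p, params) - v / params.r_load
    if f(hi) >= 0:
        return hi
    return brentq(f, 0.0, hi, xtol=1e-12, rtol=8.9e-16)


def illuminance_to_vpsv(p_led, params: PhotodiodeParams):
    """Operating-point voltage across the load for illuminance ``p_led``.

    Solves the load line by bracketed root finding (tolerance < 1e-9 V);
    nonnegative, nondecreasing in illuminance, bounded by the open-circuit
    voltage. Rejects negative illuminance.
    """
    p_arr = np.asarray(p_led, dtype=float)
    if not np.all(np.isfinite(p_arr)):
        raise ValueError("illuminance must be finite")
    if np.any(p_arr < 0):
        raise ValueError("illuminance must be nonnegative")
    out = np.vectorize(lambda p: _vpsv_scalar(float(p), params))(p_arr)
    if out.ndim == 0:
        return float(out)
    return out.astype(float)
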