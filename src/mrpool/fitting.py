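"""Quantitative parameter estimation from simulated images.

Implements the estimation side of the four study pipelines:
multi-component T2 / myelin-water-fraction fitting (with or without an
exchange-aware forward model), actual-flip-angle (AFI) B1 inversion,
macromolecular-proton-fraction mapping from MT-weighted variable-flip
SPGR data, Z-spectrum asymmetry, and the magnetization transfer ratio,
plus small reporting utilities (local-polynomial smoothing and
Bland-Altman limits of agreement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from . import engine
from .tissue import TissueModel, preset_model

__all__ = [
    "EchoTrain",
    "ZSpectrum",
    "TwoPoolT2Fit",
    "fit_two_pool_t2",
    "fit_afi",
    "fit_mcri",
    "cest_asymmetry",
    "mtr",
    "local_polynomial_smooth",
    "bland_altman",
]


@dataclass(frozen=True)
class EchoTrain:
    """Echo times (s, strictly increasing) and magnitudes."""

    times: np.ndarray
    magnitudes: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if np.any(m < 0):
            raise ValueError("echo magnitudes must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "magnitudes", m)


@dataclass(frozen=True)
class ZSpectrum:
    """Normalized signal S(offset)/S0 versus saturation offset (ppm)."""

    offsets_ppm: np.ndarray
    signals: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "offsets_ppm",
                           np.asarray(self.offsets_ppm, dtype=float))
        object.__setattr__(self, "signals",
                           np.asarray(self.signals, dtype=float))

    def value_at(self, delta_ppm: float) -> float:
        i = np.where(np.isclose(self.offsets_ppm, delta_ppm))[0]
        if len(i) == 0:
            raise KeyError(f"offset {delta_ppm} ppm not in spectrum")
        return float(self.signals[i[0]])


@dataclass
class TwoPoolT2Fit:
    mwf: float
    t2_short: float
    t2_long: float
    k: float
    residual: float
    converged: bool
    message: str = ""


def _biexp(t, a1, r1, a2, r2):
    return a1 * np.exp(-r1 * t) + a2 * np.exp(-r2 * t)


def _loglinear_init(t, y, split_t2: float):
    """Initial guess: log-linear fit of the late echoes for the slow
    component, then of the residual early echoes for the fast one."""
    late = t > split_t2
    if late.sum() < 2 or (~late).sum() < 2:
        late = t > np.median(t)
    p_slow = np.polyfit(t[late], np.log(np.clip(y[late], 1e-12, None)), 1)
    a2, r2 = math.exp(p_slow[1]), max(-p_slow[0], 1e-3)
    resid = y - a2 * np.exp(-r2 * t)
    early = ~late
    pos = resid[early] > 1e-12
    if pos.sum() >= 2:
        p_fast = np.polyfit(t[early][pos], np.log(resid[early][pos]), 1)
        a1, r1 = math.exp(p_fast[1]), max(-p_fast[0], r2 * 2)
    else:
        a1, r1 = max(y[0] - a2, 1e-3), r2 * 5
    return a1, r1, a2, r2


def fit_two_pool_t2(train: EchoTrain, exchange="none",
                    t2_bounds=((0.005, 0.040), (0.040, 0.300)),
                    t1s=(0.5, 1.0), seed: int = 0) -> TwoPoolT2Fit:
    """Fit a two-pool model to a multi-echo T2 decay.

    ``exchange``:
      * ``"none"`` -- biexponential (the simplified non-exchanging
        model); parameters (amplitudes, two T2s).
      * ``("fixed", K)`` -- exchange-aware forward model (ideal CPMG
        echo train of the two-pool exchange system) with the rate held
        at K s^-1.
      * ``"free"`` -- same forward model with K as a free parameter.

    Returns MWF = short-T2 amplitude / total.  Initialization is a
    log-linear split at the geometric mean of the T2 bounds; on
    non-convergence three seeded multi-starts are attempted.
    """
    if len(train.times) < 8:
        raise ValueError("need at least 8 echoes")
    t, y = train.times, train.magnitudes
    split = math.sqrt(t2_bounds[0][1] * t2_bounds[1][0])
    a1, r1, a2, r2 = _loglinear_init(t, y, split)
    total0 = max(a1 + a2, 1e-9)

    mode = exchange if isinstance(exchange, str) else exchange[0]
    k_fixed = 0.0 if mode != "fixed" else float(exchange[1])

    def forward(p):
        if mode == "none":
            a1, t2s, a2, t2l = p
            return _biexp(t, a1, 1.0 / t2s, a2, 1.0 / t2l)
        amp, f, t2s, t2l = p[:4]
        k = p[4] if mode == "free" else k_fixed
        model = preset_model("mwf_two_pool", {
            "fraction_short": f, "k": k,
            "t2_short": t2s, "t2_long": t2l,
            "t1_short": t1s[0], "t1_long": t1s[1]})
        te = t[0]
        echoes = engine.ideal_cpmg_echoes(model, te, len(t))
        return amp * echoes

    lo_s, hi_s = t2_bounds[0]
    lo_l, hi_l = t2_bounds[1]
    if mode == "none":
        x0 = [a1, np.clip(1 / r1, lo_s, hi_s), a2, np.clip(1 / r2, lo_l, hi_l)]
        lb = [0.0, lo_s, 0.0, lo_l]
        ub = [np.inf, hi_s, np.inf, hi_l]
    else:
        f0 = np.clip(a1 / total0, 0.01, 0.5)
        x0 = [total0, f0, np.clip(1 / r1, lo_s, hi_s),
              np.clip(1 / r2, lo_l, hi_l)]
        lb = [0.0, 0.0, lo_s, lo_l]
        ub = [np.inf, 1.0, hi_s, hi_l]
        if mode == "free":
            x0.append(5.0)
            lb.append(0.0)
            ub.append(100.0)

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(4):
        start = np.asarray(x0, dtype=float)
        if attempt:
            jitter = rng.uniform(0.7, 1.3, size=len(x0))
            start = np.clip(start * jitter, lb, ub)
        try:
            res = least_squares(lambda p: forward(p) - y, start,
                                bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-16 * max(1.0, y[0] ** 2) * len(y):
            break
    if best is None:
        return TwoPoolT2Fit(np.nan, np.nan, np.nan, np.nan, np.inf, False,
                            "optimizer failed")
    p = best.x
    if mode == "none":
        a1, t2s, a2, t2l = p
        if t2s > t2l:  # keep short/long ordering
            a1, a2, t2s, t2l = a2, a1, t2l, t2s
        mwf = a1 / (a1 + a2) if (a1 + a2) > 0 else np.nan
        k = 0.0
    else:
        mwf, t2s, t2l = p[1], p[2], p[3]
        k = p[4] if mode == "free" else k_fixed
    return TwoPoolT2Fit(float(mwf), float(t2s), float(t2l), float(k),
                        float(best.cost), best.success, best.message)


def fit_afi(s1, s2, n: float, nominal_flip_deg: float):
    """Invert the AFI signal ratio to the local flip angle.

    alpha = arccos((r n - 1)/(n - r)) with r = S2/S1.  Returns
    (flip map relative to nominal, valid mask); voxels whose arccos
    argument leaves [-1, 1] (or with S1 <= 0) are masked and counted
    out.
    """
    if n <= 1:
        raise ValueError("TR ratio n must exceed 1")
    s1 = np.abs(np.asarray(s1, dtype=float))
    s2 = np.abs(np.asarray(s2, dtype=float))
    valid = s1 > 0
    r = np.where(valid, s2 / np.where(valid, s1, 1.0), np.nan)
    arg = (r * n - 1.0) / (n - r)
    ok = valid & (arg >= -1.0) & (arg <= 1.0)
    alpha = np.full(s1.shape, np.nan)
    alpha[ok] = np.degrees(np.arccos(arg[ok]))
    return alpha / nominal_flip_deg, ok


@dataclass
class McriFit:
    mpf: float
    k: float
    residual: float
    converged: bool


def fit_mcri(signals, acquisitions, famap=1.0,
             model_template: dict | None = None, b0: float = 3.0,
             fit_k: bool = True, seed: int = 0) -> McriFit:
    """Estimate the macromolecular proton fraction from MT-weighted
    variable-flip-angle SPGR signals.

    ``signals``: measured magnitudes, one per acquisition;
    ``acquisitions``: list of dicts with keys ``tr``, ``te``,
    ``flip_deg`` and ``mt_pulse`` (None for MT-off); ``famap``: relative
    flip-angle scale from AFI used to correct both excitation and MT
    saturation power.  The forward model is the steady-state two-pool
    MT SPGR signal computed from the propagator fixed point; MPF (and
    optionally the bound-to-water rate) are fit by least squares with
    the remaining parameters taken from ``model_template``.
    """
    y = np.abs(np.asarray(signals, dtype=float))
    if len(y) != len(acquisitions):
        raise ValueError("signal / acquisition count mismatch")
    if len(y) < 3:
        raise ValueError("insufficient contrast points")
    template = dict(model_template or {})
    scale0 = None

    def forward(p):
        mpf = p[1]
        params = dict(template)
        params["mpf"] = mpf
        if fit_k:
            params["k_bound_to_water"] = p[2]
        model = preset_model("qmt_two_pool", params)
        out = np.empty(len(y))
        for i, acq in enumerate(acquisitions):
            out[i] = abs(engine.mt_spgr_steady_signal(
                model, acq["tr"], acq["te"], acq["flip_deg"],
                mt_pulse=acq.get("mt_pulse"), b1_scale=float(famap), b0=b0))
        return p[0] * out

    ratio = y.min() / max(y.max(), 1e-12)
    mpf0 = float(np.clip(0.2 * (1.0 - ratio), 0.02, 0.3))
    x0 = [1.0, mpf0] + ([template.get("k_bound_to_water", 30.0)] if fit_k else [])
    # amplitude scale initialization from the first point
    f0 = forward(np.asarray(x0))
    x0[0] = y[0] / max(f0[0], 1e-12)
    lb = [0.0, 0.0] + ([1.0] if fit_k else [])
    ub = [np.inf, 0.5] + ([200.0] if fit_k else [])
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(3):
        start = np.asarray(x0, dtype=float)
        if attempt:
            start = np.clip(start * rng.uniform(0.6, 1.4, len(x0)), lb, ub)
        res = least_squares(lambda p: forward(p) - y, start, bounds=(lb, ub),
                            xtol=1e-12, ftol=1e-12)
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-14 * len(y):
            break
    return McriFit(float(best.x[1]), float(best.x[2]) if fit_k else
                   float(template.get("k_bound_to_water", 30.0)),
                   float(best.cost), best.success)


def cest_asymmetry(z: ZSpectrum, delta_ppm: float) -> float:
    """Z-spectrum asymmetry in percent:
    100 * (S(-delta) - S(+delta)) / S(-delta)."""
    s_neg = z.value_at(-abs(delta_ppm))
    s_pos = z.value_at(abs(delta_ppm))
    return 100.0 * (s_neg - s_pos) / s_neg


def mtr(mt_off, mt_on) -> np.ndarray | float:
    """Magnetization transfer ratio in percent:
    100 * (MT_off - MT_on) / MT_off."""
    off = np.abs(np.asarray(mt_off, dtype=float))
    on = np.abs(np.asarray(mt_on, dtype=float))
    if np.any(off <= 0):
        raise ValueError("MT_off must be positive on the evaluation mask")
    out = 100.0 * (off - on) / off
    return float(out) if out.ndim == 0 else out


def local_polynomial_smooth(values, window: int = 5, order: int = 2):
    """Savitzky-Golay local-polynomial smoothing along the last axis."""
    v = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if v.shape[-1] < window:
        return v.copy()
    return savgol_filter(v, window, order, axis=-1)


def bland_altman(a, b):
    """Mean difference and +-1.96 sd limits of agreement of b - a."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    d = b - a
    bias = d.mean()
    sd = d.std(ddof=1) if len(d) > 1 else 0.0
    return bias, bias - 1.96 * sd, bias + 1.96 * sd
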