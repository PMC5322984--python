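"""Discrete-time Bloch-McConnell spin engine.

The state of one voxel is the stacked magnetization vector with three
components (Mx, My, Mz) per free pool and one longitudinal component
per bound pool.  A time step splits the dynamics into (1) an exact
rotation of each free pool about its effective field -- transverse RF
plus the pool's longitudinal offset -- and (2) the exponential of the
relaxation / exchange / saturation generator, applied with its affine
(T1-recovery) part.  Within a piecewise-constant sequence segment the
per-step propagator is constant, so a whole segment is advanced by a
matrix power of the augmented (affine) propagator; the result is
identical to sequential stepping.

The RF carrier offset enters as a longitudinal field term applied to
every pool for the duration of the RF segment (the rotating-frame
reading of the effective-field sum); bound pools see the RF through a
saturation rate W evaluated at the carrier offset with the pool's
lineshape.  Multi-peak chemical-shift spectra are expanded into one
sub-pool per spectral line before compilation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .constants import GAMMA
from .lineshape import (FieldContext, MicroFieldModel, sample_micro_field,
                        saturation_rate)
from .sequence import ExternalEvent, SequenceSegment, Timeline
from .tissue import TissueModel, expand_spectra

__all__ = [
    "SpinState",
    "PropagatorCache",
    "build_generator",
    "step",
    "evolve",
    "evolve_with_microfield",
    "ideal_cpmg_echoes",
    "mt_spgr_steady_signal",
    "afi_steady_signals",
]


@dataclass
class SpinState:
    """Stacked magnetization of one voxel, in units of total M0."""

    m_free: np.ndarray   # (n_free, 3)
    m_bound: np.ndarray  # (n_bound,)

    @classmethod
    def equilibrium(cls, model: TissueModel) -> "SpinState":
        model = expand_spectra(model)
        f = model.fractions()
        nf, nb = model.n_free, model.n_bound
        m_free = np.zeros((nf, 3))
        m_free[:, 2] = f[model.free_indices]
        return cls(m_free, f[model.bound_indices].copy())

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.m_free.ravel(), self.m_bound])

    @classmethod
    def from_vector(cls, x: np.ndarray, n_free: int) -> "SpinState":
        return cls(x[: 3 * n_free].reshape(n_free, 3).copy(),
                   x[3 * n_free:].copy())

    @property
    def transverse(self) -> complex:
        return complex(self.m_free[:, 0].sum() + 1j * self.m_free[:, 1].sum())


class PropagatorCache(dict):
    """Keyed store of augmented propagators; hits return the identical
    array object (bit-identical reuse)."""


@dataclass
class _Compiled:
    """Expanded model with flat parameter arrays used by the stepper."""

    model: TissueModel
    nf: int
    nb: int
    f: np.ndarray        # all fractions, free pools first
    t1_f: np.ndarray
    t2_f: np.ndarray
    ppm_f: np.ndarray    # per free pool chemical-shift offset (ppm)
    t1_b: np.ndarray
    t2_b: np.ndarray
    lineshape_b: list
    K: np.ndarray        # reordered: free pools first, then bound


def compile_model(model: TissueModel) -> _Compiled:
    m = expand_spectra(model)
    fi, bi = m.free_indices, m.bound_indices
    order = fi + bi
    K = m.exchange.rates[np.ix_(order, order)]
    pools = [m.pools[i] for i in order]
    nf, nb = len(fi), len(bi)
    return _Compiled(
        model=m, nf=nf, nb=nb,
        f=np.array([p.fraction for p in pools]),
        t1_f=np.array([p.t1 for p in pools[:nf]]),
        t2_f=np.array([p.t2 for p in pools[:nf]]),
        ppm_f=np.array([p.spectrum[0][0] if p.spectrum else 0.0
                        for p in pools[:nf]]),
        t1_b=np.array([p.t1 for p in pools[nf:]]),
        t2_b=np.array([p.t2 for p in pools[nf:]]),
        lineshape_b=[p.lineshape for p in pools[nf:]],
        K=K,
    )


def build_generator(model, w_bound=None, longitudinal_field_offsets=None,
                    b1: complex | None = None, gamma: float = GAMMA):
    """Linear generator (A, c) of dM/dt = A M + c over the stacked state.

    ``longitudinal_field_offsets`` are per-free-pool fields in tesla;
    ``w_bound`` the per-bound-pool saturation rates in s^-1; ``b1`` an
    optional complex transverse field in tesla whose rotation terms are
    included (used by the full-generator oracle; the stepper keeps the
    rotation separate).
    """
    c_mod = model if isinstance(model, _Compiled) else compile_model(model)
    nf, nb = c_mod.nf, c_mod.nb
    n = 3 * nf + nb
    if w_bound is None:
        w_bound = np.zeros(nb)
    if longitudinal_field_offsets is None:
        longitudinal_field_offsets = np.zeros(nf)
    w_bound = np.asarray(w_bound, dtype=float)
    bz = np.asarray(longitudinal_field_offsets, dtype=float)
    if len(w_bound) != nb or len(bz) != nf:
        raise ValueError("dimension mismatch between model and field terms")
    A = np.zeros((n, n))
    c = np.zeros(n)
    K = c_mod.K
    for i in range(nf):
        r = 3 * i
        # dM/dt = omega x M with omega = -gamma * B
        wz = -gamma * bz[i]
        A[r, r + 1] += -wz
        A[r + 1, r] += wz
        if b1:
            wx, wy = -gamma * b1.real, -gamma * b1.imag
            A[r + 1, r + 2] += -wx
            A[r + 2, r + 1] += wx
            A[r, r + 2] += wy
            A[r + 2, r] += -wy
        A[r, r] += -1.0 / c_mod.t2_f[i]
        A[r + 1, r + 1] += -1.0 / c_mod.t2_f[i]
        A[r + 2, r + 2] += -1.0 / c_mod.t1_f[i]
        c[r + 2] = c_mod.f[i] / c_mod.t1_f[i]
        # exchange: transverse only with other free pools, z with all
        for j in range(nf):
            if j == i:
                continue
            for comp in range(3):
                A[r + comp, r + comp] += -K[i, j]
                A[r + comp, 3 * j + comp] += K[j, i]
        for l in range(nb):
            A[r + 2, r + 2] += -K[i, nf + l]
            A[r + 2, 3 * nf + l] += K[nf + l, i]
    for l in range(nb):
        r = 3 * nf + l
        A[r, r] += -1.0 / c_mod.t1_b[l] - w_bound[l]
        c[r] = c_mod.f[nf + l] / c_mod.t1_b[l]
        for j in range(nf):
            A[r, r] += -K[nf + l, j]
            A[r, 3 * j + 2] += K[j, nf + l]
    return A, c


def _rotation_matrix(axis_rates: np.ndarray, dt: float) -> np.ndarray:
    """Rodrigues rotation for dM/dt = omega x M over dt."""
    w = np.asarray(axis_rates, dtype=float)
    theta = np.linalg.norm(w) * dt
    if theta == 0.0:
        return np.eye(3)
    k = w / np.linalg.norm(w)
    Kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(theta) * Kx + (1 - math.cos(theta)) * Kx @ Kx


def _augment(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Affine map x -> A x + b as an (n+1) homogeneous matrix."""
    n = A.shape[0]
    T = np.zeros((n + 1, n + 1))
    T[:n, :n] = A
    T[:n, n] = b
    T[n, n] = 1.0
    return T


def _augment_generator(A: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Generator of dx/dt = A x + c in homogeneous form (corner 0, so
    its exponential is the affine propagator)."""
    n = A.shape[0]
    G = np.zeros((n + 1, n + 1))
    G[:n, :n] = A
    G[:n, n] = c
    return G


def _split_step_propagator(c_mod: _Compiled, dt: float, b1: complex,
                           bz_free: np.ndarray, w_bound: np.ndarray,
                           gamma: float, strang: bool = False) -> np.ndarray:
    """Augmented propagator of one splitting step (rotation, then
    relaxation-exchange-saturation; Strang mode sandwiches half
    relaxation steps around the rotation)."""
    n = 3 * c_mod.nf + c_mod.nb
    R = np.eye(n)
    for i in range(c_mod.nf):
        w = -gamma * np.array([b1.real, b1.imag, bz_free[i]])
        R[3 * i:3 * i + 3, 3 * i:3 * i + 3] = _rotation_matrix(w, dt)
    A, c = build_generator(c_mod, w_bound=w_bound)
    if strang:
        Eh = expm(_augment_generator(A, c) * (dt / 2.0))
        return Eh @ _augment(R, np.zeros(n)) @ Eh
    E = expm(_augment_generator(A, c) * dt)
    return E @ _augment(R, np.zeros(n))


def step(state: SpinState, ctx: FieldContext, model, dt: float,
         b0: float = 3.0, strang: bool = False) -> SpinState:
    """Advance one voxel by a single split step of length dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    c_mod = model if isinstance(model, _Compiled) else compile_model(model)
    gamma = ctx.gamma
    base_bz = (-2.0 * math.pi * ctx.rf_offset_hz / gamma
               + float(np.dot(ctx.gradient, ctx.position))
               + ctx.delta_b_macro + ctx.micro_field)
    bz_free = base_bz + c_mod.ppm_f * 1e-6 * b0
    b1 = complex(ctx.b1_effective)
    w = np.array([saturation_rate(abs(b1), ctx.rf_offset_hz, c_mod.t2_b[l],
                                  c_mod.lineshape_b[l], gamma)
                  for l in range(c_mod.nb)]) if c_mod.nb else np.zeros(0)
    T = _split_step_propagator(c_mod, dt, b1, bz_free, w, gamma, strang)
    x = np.append(state.to_vector(), 1.0)
    x = T @ x
    return SpinState.from_vector(x[:-1], c_mod.nf)


@dataclass
class ADCRecord:
    """Complex transverse samples collected during evolve."""

    times: list = field(default_factory=list)
    values: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    def as_arrays(self):
        return np.asarray(self.times), np.asarray(self.values, dtype=complex)


def _interval_propagator(cache: PropagatorCache, c_mod: _Compiled, length: float,
                         b1: complex, rf_offset_hz: float, bz_base: float,
                         dt_max: float, dt_max_rf: float, gamma: float,
                         b0: float) -> np.ndarray:
    dt_target = dt_max_rf if b1 != 0 else dt_max
    nsub = max(1, int(math.ceil(length / dt_target - 1e-12)))
    dt = length / nsub
    bz_free = (bz_base - 2.0 * math.pi * rf_offset_hz / gamma
               + c_mod.ppm_f * 1e-6 * b0)
    key = (round(dt, 15), b1.real, b1.imag, rf_offset_hz,
           round(bz_base, 18), nsub)
    T = cache.get(key)
    if T is None:
        w = np.array([saturation_rate(abs(b1), rf_offset_hz, c_mod.t2_b[l],
                                      c_mod.lineshape_b[l], gamma)
                      for l in range(c_mod.nb)]) if c_mod.nb else np.zeros(0)
        T1 = _split_step_propagator(c_mod, dt, b1, bz_free, w, gamma)
        T = np.linalg.matrix_power(T1, nsub)
        cache[key] = T
    return T


def evolve(state: SpinState, timeline: Timeline, model,
           ctx=None, events=None, dt_max: float = 1e-5,
           dt_max_rf: float = 5e-7, b0: float = 3.0,
           transmit_scale: complex = 1.0,
           cache: PropagatorCache | None = None):
    """Run a full timeline; returns (final SpinState, ADCRecord).

    ``ctx`` is a static :class:`FieldContext` or a callable
    ``ctx(time) -> FieldContext`` evaluated at each segment start.
    Segment boundaries, ADC samples and external-event times split the
    stepping exactly; events are applied atomically at their timestamps.
    """
    c_mod = compile_model(model)
    cache = cache if cache is not None else PropagatorCache()
    static_ctx = None
    if ctx is None:
        static_ctx = FieldContext()
    elif isinstance(ctx, FieldContext):
        static_ctx = ctx
    all_events = list(timeline.events) + list(events or [])
    span = timeline.span
    for e in all_events:
        if e.time < -1e-12 or e.time > span + 1e-9:
            raise ValueError(f"event at t={e.time} outside timeline span")
    # breakpoints: segment starts/ends, adc times, event times
    marks = {0.0, span}
    for s in timeline.segments:
        marks.add(s.start)
        marks.add(s.end)
        marks.update(s.adc)
    for e in all_events:
        marks.add(e.time)
    times = sorted(marks)
    seg_iter = sorted(timeline.segments, key=lambda s: s.start)
    adc_by_time = {}
    for s in seg_iter:
        for t in s.adc:
            adc_by_time.setdefault(t, None)
    ev_by_time = {}
    for e in sorted(all_events, key=lambda e: e.time):
        ev_by_time.setdefault(e.time, []).append(e)
    labels = list(timeline.metadata.get("adc_labels", []))

    seg_ptr = [0]

    def active_segment(t0, t1):
        # intervals arrive in time order; advance a cursor over the
        # sorted, non-overlapping segments
        i = seg_ptr[0]
        while i < len(seg_iter) and seg_iter[i].end <= t0 + 1e-15:
            i += 1
        seg_ptr[0] = i
        if (i < len(seg_iter) and seg_iter[i].start <= t0 + 1e-15
                and t1 <= seg_iter[i].end + 1e-15):
            return seg_iter[i]
        return None

    x = np.append(state.to_vector(), 1.0)
    record = ADCRecord()
    pd = c_mod.model.proton_density

    def get_ctx(t):
        return static_ctx if static_ctx is not None else ctx(t)

    # allow update_field events to override the static context
    ctx_override = {}
    for t0, t1 in zip(times[:-1], times[1:]):
        length = t1 - t0
        if length > 1e-15:
            seg = active_segment(t0, t1)
            cur = get_ctx(t0)
            b1 = complex(cur.b1_effective)
            rf_off = cur.rf_offset_hz
            grad = cur.gradient
            if seg is not None and seg.rf is not None:
                amp, phase, off = seg.rf
                scale = ctx_override.get("b1_scale", transmit_scale)
                b1 = amp * scale * complex(math.cos(phase), math.sin(phase))
                rf_off = off
            if seg is not None:
                grad = np.asarray(seg.gradient)
            bz_base = (float(np.dot(grad, cur.position))
                       + ctx_override.get("delta_b_macro", cur.delta_b_macro)
                       + cur.micro_field)
            T = _interval_propagator(cache, c_mod, length, b1, rf_off,
                                     bz_base, dt_max, dt_max_rf, cur.gamma, b0)
            x = T @ x
        if t1 in adc_by_time:
            xt = x[:-1]
            sig = (xt[0:3 * c_mod.nf:3].sum()
                   + 1j * xt[1:3 * c_mod.nf:3].sum()) * pd
            record.times.append(t1)
            record.values.append(sig)
        for e in ev_by_time.get(t1, []):
            if e.action == "perfect_spoil":
                for i in range(c_mod.nf):
                    x[3 * i] = 0.0
                    x[3 * i + 1] = 0.0
            elif e.action == "reset":
                x = np.append(SpinState.equilibrium(c_mod.model).to_vector(),
                              1.0)
            elif e.action == "update_field":
                ctx_override.update(e.payload)
                cache = PropagatorCache()
            elif e.action == "update_model":
                c_mod = compile_model(e.payload["model"])
                cache = PropagatorCache()
                x = np.append(SpinState.equilibrium(c_mod.model).to_vector(),
                              1.0) if e.payload.get("reset", False) else x
            else:
                raise ValueError(f"unknown event action '{e.action}'")
    record.labels = labels[: len(record.values)]
    return SpinState.from_vector(x[:-1], c_mod.nf), record


def evolve_with_microfield(state0: SpinState, timeline: Timeline, model,
                           micro: MicroFieldModel, ctx=None,
                           stratified: bool = True, **kwargs):
    """Average the ADC record over microscopic-field realizations.

    Each realization draws one Cauchy-distributed field offset through
    the inverse CDF and runs :func:`evolve`; the mean complex record is
    returned.  By default the uniform variates are stratified midpoints
    (k + 1/2)/n -- a deterministic low-discrepancy stream that makes the
    realization average converge to the exp(-t/T2') envelope at small n;
    with ``stratified=False`` they are i.i.d. draws from the seeded
    generator (realization index = position in the stream).
    """
    n = micro.n_realizations
    if stratified:
        us = (np.arange(n) + 0.5) / n
    else:
        rng = np.random.default_rng(micro.seed)
        us = rng.uniform(1e-12, 1.0 - 1e-12, size=n)
    base = ctx if isinstance(ctx, FieldContext) else FieldContext()
    acc = None
    times = None
    final = None
    for u in us:
        db = sample_micro_field(micro, float(u), base.gamma)
        ctx_r = replace_ctx(base, micro_field=db)
        final, rec = evolve(state0, timeline, model, ctx=ctx_r, **kwargs)
        t, v = rec.as_arrays()
        acc = v if acc is None else acc + v
        times = t
    out = ADCRecord(times=list(times), values=list(acc / micro.n_realizations))
    return final, out


def replace_ctx(ctx: FieldContext, **kw) -> FieldContext:
    d = dict(b1_effective=ctx.b1_effective, rf_offset_hz=ctx.rf_offset_hz,
             gradient=ctx.gradient.copy(), position=ctx.position.copy(),
             delta_b_macro=ctx.delta_b_macro, micro_field=ctx.micro_field,
             gamma=ctx.gamma)
    d.update(kw)
    return FieldContext(**d)


# ---------------------------------------------------------------------------
# analytic / steady-state signal models built on the same propagators
# ---------------------------------------------------------------------------

def ideal_cpmg_echoes(model: TissueModel, te: float, n_echoes: int):
    """Echo amplitudes of an ideal on-resonance CPMG train.

    With instantaneous 90/180 pulses and all free pools on resonance the
    transverse dynamics reduce to the free-pool decay-exchange system;
    echo k has amplitude 1^T expm(A te)^k M0_free (scaled by proton
    density).  Serves as the exchange-aware forward model for
    multi-component T2 fitting and as an independent oracle for the
    stepper.
    """
    c_mod = compile_model(model)
    nf = c_mod.nf
    K = c_mod.K[:nf, :nf]
    A = np.diag(-1.0 / c_mod.t2_f).astype(float)
    for i in range(nf):
        for j in range(nf):
            if i != j:
                A[i, i] -= K[i, j]
                A[i, j] += K[j, i]
    E = expm(A * te)
    m = c_mod.f[:nf].copy()
    out = np.empty(n_echoes)
    for k in range(n_echoes):
        m = E @ m
        out[k] = m.sum()
    return out * c_mod.model.proton_density


def _fixed_point(T_aug: np.ndarray) -> np.ndarray:
    n = T_aug.shape[0] - 1
    A = np.eye(n) - T_aug[:n, :n]
    return np.linalg.solve(A, T_aug[:n, n])


def _spoil_matrix(c_mod: _Compiled) -> np.ndarray:
    n = 3 * c_mod.nf + c_mod.nb
    S = np.eye(n + 1)
    for i in range(c_mod.nf):
        S[3 * i, 3 * i] = 0.0
        S[3 * i + 1, 3 * i + 1] = 0.0
    return S


def _instant_rotation(c_mod: _Compiled, flip_rad: float,
                      phase: float = 0.0) -> np.ndarray:
    n = 3 * c_mod.nf + c_mod.nb
    R = np.eye(n + 1)
    # rotation by flip about the in-plane axis at `phase`
    axis = np.array([math.cos(phase), math.sin(phase), 0.0])
    Rot = _rotation_matrix(axis * flip_rad, 1.0)
    for i in range(c_mod.nf):
        R[3 * i:3 * i + 3, 3 * i:3 * i + 3] = Rot
    return R


def _relax_aug(c_mod: _Compiled, duration: float, b1: complex = 0.0,
               rf_offset_hz: float = 0.0, gamma: float = GAMMA,
               b0: float = 3.0, dt_max: float = 1e-5,
               dt_max_rf: float = 1e-6) -> np.ndarray:
    bz_free = (-2.0 * math.pi * rf_offset_hz / gamma
               + c_mod.ppm_f * 1e-6 * b0)
    w = np.array([saturation_rate(abs(b1), rf_offset_hz, c_mod.t2_b[l],
                                  c_mod.lineshape_b[l], gamma)
                  for l in range(c_mod.nb)]) if c_mod.nb else np.zeros(0)
    dt_target = dt_max_rf if b1 else dt_max
    nsub = max(1, int(math.ceil(duration / dt_target)))
    T1 = _split_step_propagator(c_mod, duration / nsub, complex(b1), bz_free,
                                w, gamma)
    return np.linalg.matrix_power(T1, nsub)


def _read_transverse(c_mod: _Compiled, x: np.ndarray) -> complex:
    return complex(x[0:3 * c_mod.nf:3].sum() + 1j * x[1:3 * c_mod.nf:3].sum()
                   ) * c_mod.model.proton_density


def mt_spgr_steady_signal(model: TissueModel, tr: float, te: float,
                          flip_deg: float, mt_pulse=None,
                          b1_scale: float = 1.0, b0: float = 3.0,
                          gamma: float = GAMMA) -> complex:
    """Steady-state signal of the (MT-weighted) spoiled gradient echo.

    Computed as the exact affine fixed point of the one-TR propagator
    cycle: [MT block pulse] -> spoil -> instantaneous excitation ->
    TE free evolution (sample) -> remainder of TR -> spoil.  The flip
    angle and MT pulse amplitude both scale with ``b1_scale``.
    """
    c_mod = compile_model(model)
    S = _spoil_matrix(c_mod)
    R = _instant_rotation(c_mod, math.radians(flip_deg) * b1_scale)
    t_sat = 0.0
    P_sat = None
    if mt_pulse is not None:
        offset_hz, eq_flip, dur, _shape = mt_pulse
        amp = (eq_flip / 360.0) / (gamma / (2 * math.pi) * dur) * b1_scale
        P_sat = _relax_aug(c_mod, dur, b1=amp, rf_offset_hz=offset_hz,
                           gamma=gamma, b0=b0)
        t_sat = dur
    E_te = _relax_aug(c_mod, te, gamma=gamma, b0=b0)
    t_rest = tr - te - t_sat
    if t_rest <= 0:
        raise ValueError("tr too short for te + saturation")
    E_rest = _relax_aug(c_mod, t_rest, gamma=gamma, b0=b0)
    cycle = S @ E_rest @ E_te @ R @ S
    if P_sat is not None:
        cycle = cycle @ P_sat
    x = np.append(_fixed_point(cycle), 1.0)
    if P_sat is not None:
        x = P_sat @ x
    x = E_te @ (R @ (S @ x))
    return _read_transverse(c_mod, x[:-1])


def afi_steady_signals(model: TissueModel, tr1: float, tr2: float,
                       flip_deg: float, b1_scale: float = 1.0,
                       b0: float = 3.0, gamma: float = GAMMA):
    """Steady-state (S1, S2) of the two-TR AFI cycle with ideal spoiling."""
    c_mod = compile_model(model)
    S = _spoil_matrix(c_mod)
    R = _instant_rotation(c_mod, math.radians(flip_deg) * b1_scale)
    E1 = _relax_aug(c_mod, tr1, gamma=gamma, b0=b0)
    E2 = _relax_aug(c_mod, tr2, gamma=gamma, b0=b0)
    cycle = S @ E2 @ R @ S @ E1 @ R
    x = np.append(_fixed_point(cycle), 1.0)
    x1 = R @ x
    s1 = _read_transverse(c_mod, x1[:-1])
    x2 = R @ (S @ (E1 @ x1))
    s2 = _read_transverse(c_mod, x2[:-1])
    return s1, s2
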