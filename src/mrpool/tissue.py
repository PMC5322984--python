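"""Generalized multi-pool exchange tissue models.

A tissue is described by an ordered collection of proton pools -- *free*
pools carrying full 3-vector magnetization (water, fat, solute protons)
and *bound* pools carrying longitudinal magnetization only (semi-solid
macromolecular protons) -- coupled by first-order magnetization exchange.
Pool fractions are equilibrium-magnetization fractions; the absolute
scale is carried by ``proton_density``.

Exchange rates are stored as a full directed matrix ``K[i, j]`` (rate
from pool *i* to pool *j*, in s^-1).  A model is *balanced* when
``K[i, j] * M0_i == K[j, i] * M0_j`` for every connected pair, in which
case thermal equilibrium is a stationary state of the exchange dynamics.
Presets derive the reverse rate from this balance identity when only a
forward rate is supplied; unbalanced matrices are permitted but trigger
a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PoolSpec",
    "ExchangeMatrix",
    "TissueModel",
    "validate_model",
    "check_equilibrium_balance",
    "preset_model",
    "aggregate_models",
    "expand_spectra",
]

FREE = "free"
BOUND = "bound"

_LINESHAPES = ("super_lorentzian", "gaussian")

#: Six-peak fat spectrum (offset ppm relative to water, amplitude).
#: A standard multi-peak discretization of the triglyceride spectrum;
#: user-overridable through ``PoolSpec.spectrum``.
FAT_SPECTRUM_6PEAK = (
    (-3.80, 0.087),
    (-3.40, 0.693),
    (-2.60, 0.128),
    (-1.94, 0.004),
    (-0.39, 0.039),
    (0.60, 0.049),
)


@dataclass(frozen=True)
class PoolSpec:
    """One proton pool.

    Parameters
    ----------
    name : str
        Human-readable label, used in diagnostics.
    kind : {"free", "bound"}
    fraction : float
        Equilibrium magnetization share (dimensionless, >= 0).
    t1, t2 : float
        Relaxation times in seconds.
    spectrum : tuple of (ppm, amplitude), free pools only
        Discretized chemical-shift spectrum; amplitudes must sum to 1.
    lineshape : {"super_lorentzian", "gaussian"}, bound pools only
        Absorption lineshape used for the RF saturation rate.
    """

    name: str
    kind: str
    fraction: float
    t1: float
    t2: float
    spectrum: tuple = ((0.0, 1.0),)
    lineshape: str | None = None

    def __post_init__(self):
        if self.kind == BOUND:
            object.__setattr__(self, "spectrum", ())
            if self.lineshape is None:
                object.__setattr__(self, "lineshape", "super_lorentzian")
        else:
            object.__setattr__(self, "spectrum", tuple(map(tuple, self.spectrum)))


@dataclass(frozen=True)
class ExchangeMatrix:
    """Directed exchange-rate matrix over all pools, s^-1."""

    rates: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))

    @property
    def n(self) -> int:
        return self.rates.shape[0]


@dataclass(frozen=True)
class TissueModel:
    """Ordered pools + exchange matrix + absolute proton density."""

    pools: tuple
    exchange: ExchangeMatrix
    proton_density: float = 1.0
    name: str = "tissue"

    def __post_init__(self):
        object.__setattr__(self, "pools", tuple(self.pools))
        if not isinstance(self.exchange, ExchangeMatrix):
            object.__setattr__(self, "exchange", ExchangeMatrix(self.exchange))

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def free_indices(self) -> list:
        return [i for i, p in enumerate(self.pools) if p.kind == FREE]

    @property
    def bound_indices(self) -> list:
        return [i for i, p in enumerate(self.pools) if p.kind == BOUND]

    @property
    def n_free(self) -> int:
        return len(self.free_indices)

    @property
    def n_bound(self) -> int:
        return len(self.bound_indices)

    def fractions(self) -> np.ndarray:
        return np.array([p.fraction for p in self.pools])


def validate_model(model: TissueModel) -> list:
    """Check all structural invariants; return a list of diagnostics.

    An empty list means the model is valid.  Violations are reported as
    strings naming the offending pool or matrix entry; no exception is
    raised.
    """
    diags = []
    K = model.exchange.rates
    n = model.n_pools
    if K.shape != (n, n):
        diags.append(
            f"exchange matrix shape {K.shape} does not match pool count {n}"
        )
        return diags
    for i, p in enumerate(model.pools):
        if p.kind not in (FREE, BOUND):
            diags.append(f"pool '{p.name}': unknown kind '{p.kind}'")
        if p.fraction < 0:
            diags.append(f"pool '{p.name}': fraction {p.fraction} < 0")
        if p.t1 <= 0:
            diags.append(f"pool '{p.name}': T1 {p.t1} <= 0")
        if p.t2 <= 0:
            diags.append(f"pool '{p.name}': T2 {p.t2} <= 0")
        if p.kind == FREE:
            if p.lineshape is not None:
                diags.append(f"pool '{p.name}': free pool carries a lineshape")
            amps = sum(a for _, a in p.spectrum)
            if abs(amps - 1.0) > 1e-9:
                diags.append(
                    f"pool '{p.name}': spectrum amplitudes sum to {amps}, "
                    "must sum to 1"
                )
        else:
            if p.lineshape not in _LINESHAPES:
                diags.append(f"pool '{p.name}': invalid lineshape '{p.lineshape}'")
    total = sum(p.fraction for p in model.pools)
    if abs(total - 1.0) > 1e-9:
        diags.append(f"pool fractions sum to {total}, != 1")
    if np.any(K < 0):
        i, j = np.argwhere(K < 0)[0]
        diags.append(f"exchange rate K[{i},{j}] = {K[i, j]} < 0")
    if np.any(np.diag(K) != 0):
        i = int(np.argwhere(np.diag(K) != 0)[0][0])
        diags.append(f"exchange matrix diagonal entry K[{i},{i}] nonzero")
    for i in model.bound_indices:
        for j in model.bound_indices:
            if i != j and K[i, j] != 0:
                diags.append(
                    f"bound-bound exchange K[{i},{j}] nonzero (only free-free "
                    "and free-bound pathways are defined)"
                )
    return diags


def check_equilibrium_balance(model: TissueModel, rtol: float = 1e-9):
    """Test the detailed-balance identity ``K_ij M0_i == K_ji M0_j``.

    Returns ``(balanced, residuals)`` where ``residuals`` maps each
    connected pair ``(i, j)`` to its relative imbalance.  When balanced,
    thermal equilibrium is a fixed point of the exchange dynamics with
    no RF applied.
    """
    K = model.exchange.rates
    f = model.fractions()
    residuals = {}
    ok = True
    for i in range(model.n_pools):
        for j in range(i + 1, model.n_pools):
            if K[i, j] == 0 and K[j, i] == 0:
                continue
            fwd = K[i, j] * f[i]
            rev = K[j, i] * f[j]
            scale = max(abs(fwd), abs(rev), 1e-300)
            res = (fwd - rev) / scale
            residuals[(i, j)] = res
            if abs(res) > rtol:
                ok = False
    return ok, residuals


def _balanced_reverse(k_fwd: float, f_from: float, f_to: float) -> float:
    return k_fwd * f_from / f_to


def _two_pool_free(params) -> TissueModel:
    f_s = params.get("fraction_short", 0.15)
    k = params.get("k", 25.0)  # short -> long rate, s^-1
    pools = (
        PoolSpec("myelin_water", FREE, f_s,
                 params.get("t1_short", 0.5), params.get("t2_short", 0.020)),
        PoolSpec("ie_water", FREE, 1.0 - f_s,
                 params.get("t1_long", 1.0), params.get("t2_long", 0.080)),
    )
    K = np.zeros((2, 2))
    if k > 0:
        K[0, 1] = k
        K[1, 0] = _balanced_reverse(k, f_s, 1.0 - f_s)
    return TissueModel(pools, ExchangeMatrix(K), name="mwf_two_pool")


def _qmt_two_pool(params) -> TissueModel:
    f_b = params.get("mpf", 0.12)
    k = params.get("k_bound_to_water", 30.0)
    pools = (
        PoolSpec("water", FREE, 1.0 - f_b,
                 params.get("t1_water", 1.0), params.get("t2_water", 0.070)),
        PoolSpec("bound", BOUND, f_b,
                 params.get("t1_bound", 1.0), params.get("t2_bound", 10e-6),
                 lineshape=params.get("lineshape", "super_lorentzian")),
    )
    K = np.zeros((2, 2))
    if k > 0:
        K[1, 0] = k
        K[0, 1] = _balanced_reverse(k, f_b, 1.0 - f_b)
    return TissueModel(pools, ExchangeMatrix(K), name="qmt_two_pool")


def _gagcest_three_pool(params) -> TissueModel:
    # Cartilage at 7 T: bound collagen protons, tissue water, and
    # glycosaminoglycan hydroxyl protons chemically shifted by +1 ppm.
    f_b = params.get("fraction_bound", 0.10)
    f_oh = params.get("fraction_oh", 0.0027)  # ~300 mM of 111 M water protons
    f_w = 1.0 - f_b - f_oh
    k_oh = params.get("k_oh_to_water", 700.0)
    k_b = params.get("k_bound_to_water", 40.0)
    pools = (
        PoolSpec("water", FREE, f_w,
                 params.get("t1_water", 1.8), params.get("t2_water", 0.040)),
        PoolSpec("hydroxyl", FREE, f_oh,
                 params.get("t1_oh", 1.0), params.get("t2_oh", 0.010),
                 spectrum=((params.get("oh_shift_ppm", 1.0), 1.0),)),
        PoolSpec("collagen", BOUND, f_b,
                 params.get("t1_bound", 1.0), params.get("t2_bound", 8.5e-6),
                 lineshape=params.get("lineshape", "super_lorentzian")),
    )
    K = np.zeros((3, 3))
    if k_oh > 0:
        K[1, 0] = k_oh
        K[0, 1] = _balanced_reverse(k_oh, f_oh, f_w)
    if k_b > 0:
        K[2, 0] = k_b
        K[0, 2] = _balanced_reverse(k_b, f_b, f_w)
    return TissueModel(pools, ExchangeMatrix(K), name="gagcest_three_pool")


def _mt_fat_three_pool(params) -> TissueModel:
    # Agar/water MT system plus non-exchanging fat (e.g. oil emulsion
    # phantoms); the fat pool carries a multi-peak chemical-shift
    # spectrum and no exchange pathway.
    ff = params.get("fat_fraction", 0.3)
    f_b = params.get("fraction_bound", 0.03) * (1.0 - ff)
    f_w = (1.0 - ff) - f_b
    k_b = params.get("k_bound_to_water", 50.0)
    spectrum = params.get("fat_spectrum", FAT_SPECTRUM_6PEAK)
    pools = (
        PoolSpec("water", FREE, f_w,
                 params.get("t1_water", 2.2), params.get("t2_water", 0.060)),
        PoolSpec("fat", FREE, ff,
                 params.get("t1_fat", 0.3), params.get("t2_fat", 0.060),
                 spectrum=spectrum),
        PoolSpec("agar_bound", BOUND, f_b,
                 params.get("t1_bound", 1.0), params.get("t2_bound", 10e-6),
                 lineshape=params.get("lineshape", "gaussian")),
    )
    K = np.zeros((3, 3))
    if k_b > 0 and f_b > 0:
        K[2, 0] = k_b
        K[0, 2] = _balanced_reverse(k_b, f_b, f_w)
    return TissueModel(pools, ExchangeMatrix(K), name="mt_fat_three_pool")


_PRESETS = {
    "mwf_two_pool": _two_pool_free,
    "qmt_two_pool": _qmt_two_pool,
    "gagcest_three_pool": _gagcest_three_pool,
    "mt_fat_three_pool": _mt_fat_three_pool,
}


def preset_model(name: str, params: dict | None = None) -> TissueModel:
    """Build one of the canonical model wirings.

    ``mwf_two_pool``
        Two free water pools (myelin / intra-extracellular) with
        bidirectional balanced exchange; ``k=0`` yields the simplified
        non-exchanging two-spin model.
    ``qmt_two_pool``
        Free water plus a bound macromolecular pool.
    ``gagcest_three_pool``
        Bound collagen + water + hydroxyl free pool at +1 ppm; two
        exchange pathways (bound<->water, water<->OH).
    ``mt_fat_three_pool``
        Bound + water exchanging, plus a non-exchanging fat free pool
        with a multi-peak spectrum.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset '{name}'; options: {sorted(_PRESETS)}")
    model = _PRESETS[name](dict(params or {}))
    diags = validate_model(model)
    if diags:  # pragma: no cover - presets are valid by construction
        raise ValueError(f"preset '{name}' invalid: {diags}")
    balanced, _ = check_equilibrium_balance(model)
    if not balanced:
        warnings.warn(
            f"preset '{name}': exchange matrix is not balanced against the "
            "pool fractions; equilibrium will drift", stacklevel=2)
    return model


def aggregate_models(models, volume_fractions) -> TissueModel:
    """Merge several tissue models into one intra-voxel aggregate.

    Pool lists are concatenated with magnetization fractions scaled by
    (volume fraction x proton density); there is no exchange across the
    source tissues.  This is the aggregate-model route to partial-volume
    simulation; the alternative route is grid refinement.
    """
    vf = np.asarray(volume_fractions, dtype=float)
    if np.any(vf < 0):
        raise ValueError("volume fractions must be >= 0")
    if abs(vf.sum() - 1.0) > 1e-9:
        raise ValueError(f"volume fractions sum to {vf.sum()}, != 1")
    weights = np.array([v * m.proton_density for v, m in zip(vf, models)])
    total_pd = weights.sum()
    pools = []
    blocks = []
    for w, m in zip(weights, models):
        scale = w / total_pd
        for p in m.pools:
            pools.append(replace(p, fraction=p.fraction * scale))
        blocks.append(m.exchange.rates)
    n = len(pools)
    K = np.zeros((n, n))
    off = 0
    for B in blocks:
        k = B.shape[0]
        K[off:off + k, off:off + k] = B
        off += k
    return TissueModel(tuple(pools), ExchangeMatrix(K), proton_density=total_pd,
                       name="+".join(m.name for m in models))


def expand_spectra(model: TissueModel) -> TissueModel:
    """Expand multi-peak free pools into one sub-pool per spectral line.

    Each spectral line of amplitude ``m_k`` becomes an independent free
    pool of fraction ``m_k * fraction`` at its own chemical-shift offset,
    sharing the parent's relaxation times.  Outgoing exchange rates are
    inherited unchanged; incoming rates are split by line amplitude, so
    the balance identity is preserved per sub-pool.  Models with only
    single-line pools are returned as-is.
    """
    if all(len(p.spectrum) <= 1 for p in model.pools if p.kind == FREE):
        return model
    sub = []  # (parent index, line amplitude, PoolSpec)
    for i, p in enumerate(model.pools):
        if p.kind == FREE and len(p.spectrum) > 1:
            for k, (ppm, amp) in enumerate(p.spectrum):
                sub.append((i, amp, replace(
                    p, name=f"{p.name}[{k}]", fraction=p.fraction * amp,
                    spectrum=((ppm, 1.0),))))
        else:
            sub.append((i, 1.0, p))
    n = len(sub)
    K0 = model.exchange.rates
    K = np.zeros((n, n))
    for a, (ia, _, _) in enumerate(sub):
        for b, (ib, amp_b, _) in enumerate(sub):
            if ia != ib:
                K[a, b] = K0[ia, ib] * amp_b
    return TissueModel(tuple(p for _, _, p in sub), ExchangeMatrix(K),
                       proton_density=model.proton_density,
                       name=model.name)


def equilibrium_fractions(model: TissueModel) -> np.ndarray:
    """Convenience: per-pool M0 shares as an array."""
    return model.fractions()


def _require_valid(model: TissueModel) -> None:
    diags = validate_model(model)
    if diags:
        raise ValueError("invalid tissue model: " + "; ".join(diags))
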