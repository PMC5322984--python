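# Methods

This note documents the model, the numerical scheme, the frozen study
conditions, and the design choices made where the design was open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Tissue model

A tissue is an ordered set of proton pools with equilibrium
magnetization fractions summing to 1; `proton_density` carries the
absolute scale (fractions are magnetization fractions, not volume
fractions). Free pools have T1, T2 and a discretized chemical-shift
spectrum (offset ppm, amplitude) whose amplitudes sum to 1; bound
pools have T1, a sub-microsecond T2, and an absorption lineshape kind.
Exchange is a full directed matrix K_ij ≥ 0 (s⁻¹) with zero diagonal
and no bound↔bound pathways.

Detailed balance K_ij·M0_i = K_ji·M0_j makes thermal equilibrium a
stationary state. Presets derive reverse rates from this identity when
given only a forward rate; unbalanced matrices are allowed but produce
a warning, since equilibrium then drifts. Multi-peak spectra are
expanded at compile time into one sub-pool per spectral line (fraction
scaled by line amplitude, incoming exchange split by amplitude), which
preserves balance and lets each line precess at its own frequency —
necessary for fat–water interference effects.

Intra-voxel tissue mixtures are formed either by `aggregate_models`
(concatenated pools, fractions weighted by volume fraction × proton
density, no cross-tissue exchange) or by simulating a refined grid and
acquiring at a coarser matrix; the two partial-volume routes agree to
1% for linear acquisitions (tested).

## Lineshapes and local fields

The super-Lorentzian is integrated adaptively over the fibre
orientation variable with the |3u²−1| singularity passed to the
quadrature as a break point. Below 1 kHz offset, where the raw shape
diverges on resonance, values are linearly extrapolated from the
1–2 kHz region (standard qMT practice). The Gaussian lineshape is
T2/√(2π)·exp(−(2πΩT2)²/2): both shapes then integrate to 1 over
angular offset frequency — the defining normalization of an
absorption lineshape — making the two media models mutually
consistent. The saturation rate is W = π(γB1/2π in Hz)²·g(Ω,T2); the
overall unit convention is absorbed by the calibrated bound-pool
parameters and cancels in the ratio/asymmetry quantities the studies
report.

The reversible dephasing rate is 1/T2′ = 1/T2* − 1/T2 (the
conventional decomposition). Microscopic field offsets are
Cauchy-distributed with scale 1/(γT2′), sampled by inverse CDF. The
realization stream defaults to stratified midpoints u_k = (k+½)/n
rather than i.i.d. draws: the Cauchy's heavy tails make i.i.d.
averaging at the customary n = 100 far too noisy to reproduce the
exp(−t/T2′) envelope (≈0.1 absolute error), while the stratified
stream reaches ≈0.03–0.05; an i.i.d. mode (seeded, realization index =
position in stream) is retained. Envelope tolerances are quoted as
absolute fractions of the initial amplitude because the relative error
at t ≳ 2T2′ is dominated by the vanishing envelope itself.

## Spin engine

State per voxel: (Mx, My, Mz) per free pool plus Mz per bound pool.
One step is (1) exact Rodrigues rotation of each free pool about its
effective field — transverse B1 plus the pool's longitudinal offset
sum — then (2) the exponential of the affine
relaxation/exchange/saturation generator. A Strang (half-relaxation)
mode exists for convergence testing. The RF carrier offset enters as a
longitudinal field applied to all pools for the duration of the RF
segment; bound pools see the RF through W evaluated at the carrier
offset.

Within a piecewise-constant segment the per-step propagator is
constant, so segment evolution is a matrix power of the augmented
(affine) propagator — bit-deterministic and identical to sequential
stepping up to floating-point association. Propagators are cached per
(dt, B1, offset, field) key; cache hits return the identical array.
Default step ceilings are 10 µs in free precession and 0.5 µs during
RF, which keeps the engine within 1e-5 relative of a dense
matrix-exponential reference on every preset model (tested); halving
the step changes ADC samples by < 1e-4 relative.

Steady-state signal models (SPGR/MT-SPGR, AFI) are computed exactly as
the affine fixed point of the one-cycle propagator (spoiling as a
transverse projection, excitation as an instantaneous rotation). These
serve as fitting forward models; the time-stepped engine generates the
data, so fits are cross-scheme rather than self-inverse.

## Sequences and acquisition

Timelines are piecewise-constant segments (RF amplitude/phase/carrier,
gradient vector, ADC sample times) plus external events
(perfect_spoil, update_model, update_field, reset) applied atomically.
Spoiling is idealized transverse zeroing; RF-spoiling phase cycles are
out of scope. Hard pulses are single segments; shaped pulses would be
segment lists. Builders cover CPMG multi-spin-echo, (MT-weighted)
SPGR, AFI, CEST saturation trains, and balanced SSFP with a Cartesian
phase-encode loop and zero net gradient area per TR. Validation checks
ordering, overlap, ADC placement, and amplitude/slew limits (defaults
20 µT, 40 mT/m, 150 T/m/s; amplitude steps at contiguous boundaries
are assumed ramped over a 100 µs allowance).

k-space uses the fftshift convention with DC at the grid center;
encode/reconstruct are exact inverses. Complex Gaussian noise is
seeded and specified absolutely or relative to the DC magnitude.
Voxels evolve independently (results are order-independent); ideal
Cartesian encoding of per-voxel signals is provided for
acquisition-level tests.

## Frozen study conditions

*Myelin water.* Two-pool white-matter model: MWF 0.15, T2 20/80 ms,
T1 0.5/1.0 s; K = myelin→IE rate, reverse by balance; CPMG TE 10 ms,
32 echoes, noise-free single voxel. An ideal CPMG train of this model
is exactly biexponential, so the no-exchange fit equals the
eigendecomposition of the transverse decay-exchange system; the bias
of the fitted MWF therefore depends only on (MWF, T2s, T2l, K). With
a free exchange rate the train exposes three observables against four
parameters, so (MWF, K) are jointly unidentifiable from one train;
the exchange-aware fit recovers MWF when the rate is supplied.

*gagCEST.* Cartilage at 7 T: water (f 0.8873, T1 1.8 s, T2 40 ms),
hydroxyl protons at +1 ppm (f 0.0027 ≈ 300 mM of 111 M, T1 1.0 s,
T2 10 ms, k_OH→w 700 s⁻¹), bound collagen (f 0.10, T1 1.0 s,
T2 8.5 µs, super-Lorentzian, k_b→w 40 s⁻¹). Saturation: ten
contiguous 100 ms block pulses, per-pulse equivalent flip α_CEST
(500/1000/2500° ⇒ 0.33/0.65/1.63 µT), offsets ±0.25…±4 ppm in 0.25 ppm
steps; readout: hard 90° + immediate sample; Z normalized by the
unsaturated signal. Parameters sit in published cartilage/gagCEST
ranges and were fixed once at design time to represent the documented
study conditions.

*MT + fat.* 3 T agar/fat system: water T1/T2 2.2 s/60 ms; agar bound
pool 3% of the aqueous compartment, Gaussian lineshape, T2 10 µs,
k_b→w 50 s⁻¹; fat T1/T2 0.3 s/60 ms with a six-peak triglyceride
spectrum (main peak −3.4 ppm), non-exchanging; volume fat fractions
0/0.3/0.5 via model aggregation. Sequence: MT-SPGR, TR 50 ms, flip
20°, MT pulse 500° at 1.5 kHz for 10 ms, echo sweep 1–12 ms in 0.5 ms
steps, 40 repetitions to steady state.

*B1 / MPF mapping.* AFI with TR 20/100 ms, flip 55°, 60 repetitions,
ideal spoiling, over transmit scales 0.85–1.15 (a synthetic smooth B1
map); inversion α = arccos((rn−1)/(n−r)). MPF mapping uses three
MT-off flips (5/15/30°) and two MT-on points (10/25°, 700° pulse at
4 kHz, 12 ms) at TR 30 ms; the fit adjusts (scale, MPF, exchange rate)
against the fixed-point forward model with the AFI scale correcting
both excitation and saturation power.

## What the synthetic data do and do not show

The generators produce noise-free (or seeded-Gaussian) signals from
exactly the model family the fits assume, on uniform cylinders, stripe
phantoms, and single voxels. Passing tests therefore demonstrate
correctness of the dynamics, the pipelines, and the estimators under
the stated models — not robustness to real-tissue deviations:
T2 spectra broader than two pools, B0/B1 inhomogeneity beyond the
provided smooth maps, imperfect spoiling, motion, diffusion, or
anatomical structure. The anatomical-template studies are replaced by
property-based checks (flip-angle and MPF recovery) for this reason.

## Known limitations

- Perfect-spoil events idealize gradient spoiling; intra-voxel
  spoiling by fine discretization is not modeled.
- The super-Lorentzian extrapolation makes bound-pool saturation
  approximate within ±1 kHz of resonance.
- Single effective transmit channel (complex scale); no SAR or
  field-interaction modeling; Cartesian encoding only.
- Transverse phase is tracked in the instantaneous RF frame per
  segment; sequences relying on transverse coherence across segments
  with different carriers should spoil between them (all bundled
  sequences do).
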