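# mrpool

MRI simulation with generalized multi-pool exchange tissue models.

Quantitative MRI methods — multi-component T2 relaxometry, quantitative
magnetization transfer (qMT), CEST, fat–water imaging — probe tissue
compartments that exchange magnetization. Simulators that treat a voxel
as independent isochromats cannot represent this physics: exchange
changes both the signal and the parameters recovered by quantitative
fits. `mrpool` simulates the full experiment — tissue model → pulse
sequence → spin dynamics → k-space → reconstruction → quantitative
fit — with tissues described by coupled free and bound proton pools.

## Model

A voxel contains N_F *free* pools (water, fat, solute protons; full
magnetization vector **M**_i) and N_B *bound* pools (semi-solid
macromolecular protons; longitudinal magnetization only), coupled by
first-order exchange rates K_ij. Free pools obey the Bloch–McConnell
equations in the rotating frame,

    dM_i/dt = γ M_i × B_i − R_i (M_i − M_0,i) − Σ_j (K_ij M_i − K_ji M_j),

with transverse exchange restricted to free↔free pairs; bound pools
obey the MT saturation formalism,

    dM_z,l/dt = −(M_z,l − M_0,l)/T1_l − W(Ω) M_z,l − Σ_j (K_lj M_z,l − K_jl M_z,j),

where the saturation rate W(Ω) = π (γB1)² g(Ω, T2_l) uses a
super-Lorentzian (biological tissue) or Gaussian (agar/gelatin)
absorption lineshape g. The per-pool effective field collects the RF
carrier offset, imaging gradients, macroscopic ΔB, the pool's
chemical-shift spectrum (multi-peak fat supported), and a stochastic
microscopic field drawn from a Cauchy distribution whose realization
average produces T2* decay.

The engine advances the coupled system with a split propagator —
exact rotation about each pool's effective field, then the exponential
of the relaxation/exchange/saturation generator — applied segment by
segment through piecewise-constant pulse-sequence timelines with
programmable external events (perfect spoiling, model/field updates).

## Worked example

Myelin-water imaging: generate a 32-echo CPMG train (TE = 10 ms) from
the two-pool exchange model of white matter (myelin water fraction
0.15, T2 = 20/80 ms, exchange rate 25 s⁻¹) and fit it with the
simplified non-exchanging biexponential used by standard analyses:

```python
from mrpool import preset_model
from mrpool.experiments import simulate_echo_train
from mrpool.fitting import fit_two_pool_t2

model = preset_model("mwf_two_pool", {"k": 25.0})   # myelin/IE water, 25 s^-1
train = simulate_echo_train(model, te=0.010, n_echoes=32)
fit = fit_two_pool_t2(train, exchange="none")       # simplified biexponential
```

Output:

```
true MWF   : 0.150
fitted MWF : 0.049  (T2 = 13.0 / 66.4 ms)
MWF error  : -67.0 %
```

Ignoring inter-compartmental exchange makes the fitted myelin water
fraction and both T2 components severely underestimate the truth — the
reason multi-pool simulation matters for validating MWF protocols.

The same machinery drives the other bundled studies
(`mrpool.experiments`): gagCEST Z-spectra of a three-pool cartilage
model at 7 T, MTR-versus-echo-time of agar/fat phantoms, AFI B1
mapping, and MPF mapping by a cross-relaxation fit. A `mrpool` CLI
exposes `simulate`, `fit`, `phantom`, `sequence`, `experiment`, and
`fixtures` subcommands.

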