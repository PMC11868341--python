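# Methods

## The model

`adexz` implements a three-variable extension of the adaptive exponential
integrate-and-fire (AdEx) neuron in which a slow variable *z* aggregates the
effect of impaired ionic regulation (e.g. a chronically elevated
extracellular potassium load) on membrane excitability:

    C dV/dt   = g_L((E_L + z) − V) + g_L Δ_T exp((V − (V_T − βz))/Δ_T) − w − g_p z + I_s
    τ_w dw/dt = a(V − (E_L + z)) − w
    dz/dt     = ε (Z₀ − V − z)

with the after-spike rule `V ≥ V_D ⇒ V → V_R, w → w + b` followed by a
`t_ref` refractory clamp at `V_R`. The impairment shifts the leak reversal
(`E_L + z`), lowers the spike-initiation threshold (`V_T − βz`, scaled by β
because sodium-channel activation need not track the reversal shift
one-for-one), and injects a counteractive current `−g_p z` standing for the
homeostatic machinery (Na/K pump, co-transporters, exchangers) that works
against the dysregulation. `Z₀` is the potential the impairment drags the
cell toward: the more depolarised (less negative) `Z₀`, the more severe the
impairment. With `z ≡ 0` and `ε = 0` the model is exactly the classical
two-variable AdEx, and the test suite holds the integrator to that limit
bit-for-bit.

### Units

All internal quantities live in a dimensionally consistent mV / ms / pA /
nS / pF system (`nS·mV = pA`, `pF·mV/ms = pA`). The reference parameter set
(`reference_params()`) is: C = 200 pF, g_L = 10 nS, E_L = −65 mV, V_T = −55 mV,
Δ_T = 2 mV, τ_w = 500 ms, a = 1 nS, b = 60 pA, I_s = 0, V_D = −40 mV,
V_R = −65 mV, t_ref = 5 ms, g_p = 10 nS, β = 0.5, Z₀ = −40 mV, and
ε = 5·10⁻⁴ per ms. The value of ε deserves a note: read instead as
5·10⁻⁴ per *second* the z variable would move less than 0.3 mV in 20 s and
no spontaneous regime would ever appear on the second timescale on which
they are observed; the per-ms reading (z time constant 2 s, an order of
magnitude slower than τ_w, two orders slower than the membrane) produces
the complete regime sequence with the quiescence boundary within 0.1 mV of
its expected location, and is therefore the package default.

## Numerics

* **Integration** is explicit Euler at `dt = 0.1 ms` (default). Spike
  detection (`V ≥ V_D`) is checked after each step and the spike is
  timestamped at the step's end; no sub-step interpolation is done, which at
  0.1 ms is immaterial for rate statistics. A convergence test pins the
  tonic-regime spike count at `dt = 0.1` against `dt = 0.05` ms, and an
  independent adaptive event-driven integration (`scipy.solve_ivp`, RK45 at
  rtol 10⁻⁸ with a terminal threshold-crossing event) reproduces the
  fixed-step spike times; the same oracle confirms the location of the
  dynamical transition between tonic and bursting regimes to 0.1 mV.
* **Refractory semantics**: during `t_ref` the membrane is clamped at `V_R`
  while `w` and `z` continue to integrate under the clamped potential
  (`freeze_w_in_refractory` switches `w` to hold instead). The minimum
  inter-spike interval is therefore `t_ref + dt`.
* **Exponential guard**: the exponential term is evaluated as written; in a
  valid run the reset fires long before it can overflow, so a non-finite
  value is reported as a hard error (a missed detection), never clipped.
* **Conductance decay** in the network uses the exact per-step factor
  `exp(−dt/τ_syn)`, so the stiffest linear part of the system carries no
  Euler error and conductances can never go negative.

## Fast-subsystem analysis

Because ε is the smallest rate in the system, *z* is treated as a frozen
parameter of the (V, w) fast subsystem. Equilibria are roots of the scalar
V-residual (with w eliminated through its nullcline `w = a(V − (E_L+z))`),
found by a 2000-point sign scan over `V ∈ [E_L − 40, V_D]` polished with
Brent's method — derivative-free and robust to the exponential's stiffness.
Stability comes from the closed-form Jacobian trace and determinant, checked
against central finite differences of the vector field.

Tracking the equilibria over z locates two bifurcations: an Andronov–Hopf
point (trace zero, determinant positive, by bisection along the non-saddle
branch) followed by a saddle-node (root-count collapse, by bisection on the
fold). For the reference parameters the two are extremely close — AH at
z = 13.8558 mV, SN at z = 13.8610 mV — because the subthreshold adaptation
`a` is weak; the Hopf exists only by virtue of `a > 0` (with `a = 0` the
determinant is negative wherever the trace vanishes, and the detector
correctly reports no Hopf). Since the Hopf can fall between any fixed grid
spacing and the fold, the refined fold point is appended to the trace-sign
scan before bracketing. Limit cycles are *not* continued: the spiking cycle
owes its existence to the reset, and the onset of spiking regimes is
delegated to direct simulation and the pattern classifier.

The V-nullsurface is sampled as a graph `w(V, z)` (w enters the membrane
equation linearly); its fold curve is analytic, `V = V_T − βz`, where the
top-left Jacobian entry vanishes.

## Pattern classification

Raising `Z₀` takes the isolated neuron through quiescence → tonic spiking →
pathological bursting → sustained ictal firing (near the refractory-limited
maximum with saturated adaptation; a status-epilepticus-like state). The
verbal descriptions of these patterns are inherently qualitative, so the
classifier below is this package's operative definition; every threshold is a field of
`ClassifierConfig`.

Runs last 20 s with the first 2 s discarded. On the post-transient train:

* a **segment** is a maximal spike group with no internal silence longer
  than `T_inter = 500 ms`; a **burst segment** additionally has ≥ 2 spikes
  at mean internal ISI < `T_intra = 50 ms` (a fast cluster, not paced slow
  spiking);
* **quiescent**: rate < 0.1 Hz;
* **bursting**: ≥ 3 burst segments, i.e. at least two long silences so the
  cluster/silence alternation demonstrably *recurs*. Requiring recurrence
  matters because the slow variable takes a few seconds to settle and a
  single long silence during settling is not a bursting rhythm;
* **sustained ictal**: mean ISI ≤ 1.5·t_ref (firing pinned near the 200 Hz
  refractory ceiling, which is what saturates w) and silences > 200 ms
  occupying < 10 % of the window;
* **tonic**: everything else that spikes.

With the reference parameters the bisected boundaries land at |Z₀| = 48.0
(quiescent→tonic), 43.0 (tonic→bursting) and 21.0 (bursting→ictal) mV. The
middle transition is dynamically sharp — at Z₀ = −43.5 mV the cell fires
3 Hz singleton spikes, at −43.0 mV it produces 100 Hz clusters — and its
location is confirmed by the adaptive-integration oracle, so it reflects
the model rather than the classifier thresholds.

## Network model

10,000 cells, 80 % excitatory regular-spiking (RS) and 20 % inhibitory
fast-spiking (FS), connected by a directed Erdős–Rényi graph with
p = 0.05 (every ordered pair independently). Synapses are conductance-based:
`I_syn = g_E(E_E − V) + g_I(E_I − V)` with E_E = 0, E_I = −80 mV; each
presynaptic spike adds Q_E = 1.5 nS or Q_I = 5 nS to its targets, and
conductances decay with τ_syn = 5 ms. Delivery is effective from the next
step (no conduction delay). `N_SC` excitatory cells are impaired (their Z₀
set to a pathological value); all others keep Z₀ = E_L, which guarantees
quiescence in isolation. There is no external drive: every network event is
seeded by the impaired subpopulation.

**FS parametrisation.** The reference table specifies a single cell type.
FS cells are assigned `a = 0, b = 0` (non-adapting interneurons) and a
sharper spike initiation, `Δ_T = 0.5 mV`, both standard for fast-spiking
interneurons in RS/FS AdEx conductance networks. The sharpness matters
structurally: with Δ_T shared at 2 mV, FS cells lose the race to threshold
against healthy RS cells during an impaired-population volley, inhibition
never contains anything, and the whole (Z₀, N_SC) plane collapses into
global seizure. Both choices are explicit arguments of `build_network`.

**Initial conditions** (`NetworkState.ignition`): V ~ U(E_L, E_L + 5 mV)
(all subthreshold), w = 0, and z = (Z₀ − E_L)·U(0.8, 1.1) — the impairment
is already essentially developed, heterogeneously, when the simulation
starts; healthy cells get exactly z = 0. Impaired cells whose z starts at or
above its equilibrium ignite in a staggered fashion through the adaptation
lag (w must first relax toward its negative equilibrium, during which V
drifts across the fold), which seeds activity without external input and
without artificial population-wide synchrony. Starting instead from exact
rest leaves the network permanently silent whenever the impaired cells are
individually below the spontaneous-activity boundary: the pathological
network state is a *coexisting* attractor that must be ignited.

**Rates and regions.** Population rates use 5 ms bins smoothed by a 25 ms
moving average; the maximum of the smoothed trace over an 8 s run summarises
each (Z₀, N_SC) point. Three regions are distinguished (thresholds 30 Hz,
configurable): (1) impaired peak rate below threshold — contained,
asynchronous-irregular-like; (2) impaired population oscillates at
pathological amplitude but the healthy excitatory peak stays normal —
inhibition confines the focus; (3) the healthy excitatory population is
recruited — global propagation, typically an alternation of seizure-like
surges and silences, terminated on the seconds timescale by adaptation and
by the collapse of z toward `Z₀ − V̄` during sustained depolarised firing
(which raises the effective threshold). In the reduced 3×3 grid used by the
test suite (Z₀ ∈ {−60, −50, −40} mV × N_SC ∈ {100, 1000, 4000}, full-size
networks) all three regions appear and the region index is non-decreasing
in N_SC at fixed Z₀.

## Problem sizes in the shipped tests and acceptance script

Single-neuron sweeps use 111 grid points at 20 s each plus bisection
(dt = 0.1 ms). Network checks run the full 10,000-cell system for 8 s; the
region grid uses 9 such runs and one seed, and the propagation-robustness
check uses 5 seeds at one parameter point. Unit tests use networks of
10–2,000 cells.

## Known limitations

* Depolarisation block cannot occur: the reset removes any stable
  depolarised state, so that clinical pattern class is out of reach of this
  model family by construction.
* During sustained ictal firing w grows to thousands of pA and the
  post-reset membrane transiently visits unphysiologically negative
  potentials; this is a known artifact of current-based adaptation in AdEx
  and does not qualitatively affect rates or network behaviour.
* Limit-cycle branches, homoclinic bifurcations and the period-doubling
  structure between bursting and tonic regimes are not computed.
* The synthetic network emulates only what the model defines: no synaptic
  plasticity, no conduction delays, no spatial topology, and no external
  background drive. Passing tests therefore say nothing about, e.g., the
  effect of realistic background states on containment thresholds.
* The impaired-population peak rate during flare onsets reaches the
  refractory-limited ceiling (≈ 200 Hz) under the 25 ms smoothing used
  here; wider smoothing kernels (≥ 100 ms) report correspondingly lower
  peaks. The measurement kernel is part of the result and is stated
  wherever a peak rate is quoted.
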