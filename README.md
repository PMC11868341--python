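# adexz

Modelling impaired ionic regulation in spiking neurons and the seizure-like
network activity it generates.

Elevated extracellular potassium and related failures of ionic homeostasis
make neurons hyperexcitable and can push cortical tissue into seizure.
Biophysical models capture this but are too stiff and parameter-heavy for
large, long network simulations. `adexz` implements a minimal alternative
for computational neuroscientists who need seizure-capable building blocks
at network scale: the adaptive exponential integrate-and-fire neuron (AdEx)
extended with one slow variable *z* that aggregates the ionic impairment,

```
C dV/dt   = g_L((E_L+z) − V) + g_L Δ_T exp((V − (V_T − βz))/Δ_T) − w − g_p z + I_s
τ_w dw/dt = a(V − (E_L+z)) − w
dz/dt     = ε (Z₀ − V − z)        if V ≥ V_D:  V → V_R,  w → w + b
```

together with:

* a fast fixed-step integrator (single neuron and 10,000-cell
  conductance-based excitatory/inhibitory network, numba-compiled);
* slow–fast analysis of the (V, w) fast subsystem with z as parameter:
  equilibria, stability, Andronov–Hopf and saddle-node bifurcation location,
  nullsurface sampling;
* a classifier of the four spontaneous regimes the impairment attractor Z₀
  produces — quiescent, tonic, pathological bursting, sustained ictal — and
  bisection of the Z₀ boundaries between them;
* network experiments over (Z₀, N_SC), the impairment severity and the
  number of impaired cells, mapping where inhibition contains a pathological
  focus and where it propagates to the healthy population.

## Worked example

Sweep the impairment attractor for an isolated neuron and locate the regime
boundaries, then compute the fast-subsystem bifurcation diagram:

```sh
$ adexz sweep --outdir runs
quiescent -> tonic at Z0 = -48.03 mV (|Z0| = 48.03)
tonic -> bursting at Z0 = -43.03 mV (|Z0| = 43.03)
bursting -> sustained_ictal at Z0 = -20.97 mV (|Z0| = 20.97)

$ adexz bif --outdir runs
andronov_hopf at z = 13.8558 mV (V = -61.849 mV)
saddle_node at z = 13.8610 mV (V = -61.740 mV)
```

Reading: as the impairment attractor Z₀ rises from rest (−65 mV), the
neuron starts firing spontaneously at −48.0 mV, switches from regular tonic
spiking to seizure-like bursting at −43.0 mV, and locks into continuous
near-maximal ("status epilepticus"-like) firing at −21.0 mV. The frozen-z
analysis explains the onset: the resting state first loses stability at an
Andronov–Hopf point and the two fixed points then annihilate in a
saddle-node as z grows, so a slow drift of z carries the cell across both.

The same model as a Python library:

```python
from adexz import reference_params, integrate_neuron, classify_trace

p = reference_params(Z0=-40.0)               # pathological impairment level
trace, spikes = integrate_neuron(p, duration=20_000.0, dt=0.1)
print(classify_trace(trace, spikes, p).label)   # -> "bursting"
```

A full network run with 1,000 impaired cells (of 8,000 excitatory, plus
2,000 fast-spiking interneurons, random 5 % connectivity):

```sh
adexz net --nsc 1000 --z0 -50 --outdir runs
```

writes `spikes.tsv`, `rates.csv` and a `summary.json` containing the peak
smoothed rate per population and the region label: 1 = contained, 2 =
pathological focus confined by inhibition, 3 = propagation to the healthy
population. `adexz grid` maps these labels over a (Z₀, N_SC) grid.

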