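"""Conductance-based spiking network with an impaired excitatory subpopulation.

The network mixes regular-spiking (RS) excitatory cells and fast-spiking (FS)
inhibitory interneurons (80/20 split) on a sparse directed Erdős–Rényi graph.
``N_SC`` excitatory cells are *impaired*: their impairment attractor Z0 is set
to a pathological value while every other cell keeps a resting Z0 equal to
E_L, which guarantees quiescence in isolation.  There is no external drive —
all network activity is seeded by the impaired cells.

Synapses are conductance-based: each presynaptic spike increments the
target's g_E or g_I by a fixed quantum, conductances decay exponentially
(integrated with the exact per-step factor, so the stiffest linear part of
the system carries no Euler error), and the synaptic current is
``g_E (E_E - V) + g_I (E_I - V)``.

FS cells are modelled as non-adapting (a = 0, b = 0), a standard convention
for AdEx interneurons; the reference parameter table gives a single cell
parametrisation and does not fix the interneuron adaptation, so this choice
is explicit and configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import STATUS_EXP_OVERFLOW, STATUS_NONFINITE, network_kernel
from .neuron import IntegrationError, Trace
from .params import ExtendedAdExParams, SynapseParams

__all__ = [
    "POP_RS_HEALTHY",
    "POP_RS_IMPAIRED",
    "POP_FS",
    "POPULATIONS",
    "NetworkModel",
    "NetworkState",
    "RasterResult",
    "build_network",
    "deliver_spikes",
    "integrate_network",
    "population_rate",
    "max_population_rates",
    "classify_region",
]

POP_RS_HEALTHY = "RS_healthy"
POP_RS_IMPAIRED = "RS_impaired"
POP_FS = "FS"
POPULATIONS = (POP_RS_IMPAIRED, POP_RS_HEALTHY, POP_FS)


@dataclass(frozen=True)
class NetworkModel:
    """Populations, impairment assignment, and directed connectivity.

    Connectivity is stored in CSR form over presynaptic cells: cell ``i``
    projects to ``targets[indptr[i]:indptr[i+1]]``.  ``labels`` holds the
    population name per cell; per-cell heterogeneity is limited to the
    adaptation parameters (a, b) and the impairment attractor Z0, everything
    else is shared through ``params``.
    """

    N: int
    params: ExtendedAdExParams
    labels: np.ndarray        # dtype object/str per cell
    Z0: np.ndarray            # per-cell impairment attractor (mV)
    a: np.ndarray             # per-cell subthreshold adaptation (nS)
    b: np.ndarray             # per-cell spike-triggered increment (pA)
    Delta_T: np.ndarray       # per-cell exponential sharpness (mV)
    is_exc: np.ndarray        # bool per cell
    indptr: np.ndarray
    targets: np.ndarray
    p: float
    seed: int

    @property
    def n_edges(self) -> int:
        return int(self.targets.size)

    def population_mask(self, population: str) -> np.ndarray:
        if population not in POPULATIONS:
            raise ValueError(f"unknown population {population!r}; expected one of {POPULATIONS}")
        return self.labels == population

    def population_size(self, population: str) -> int:
        return int(self.population_mask(population).sum())


@dataclass
class NetworkState:
    """Mutable per-cell dynamical state of a network simulation."""

    V: np.ndarray
    w: np.ndarray
    z: np.ndarray
    g_E: np.ndarray
    g_I: np.ndarray
    t_since_spike: np.ndarray
    time: float = 0.0

    @classmethod
    def resting(cls, model: NetworkModel) -> "NetworkState":
        N = model.N
        return cls(
            V=np.full(N, model.params.E_L),
            w=np.zeros(N),
            z=np.zeros(N),
            g_E=np.zeros(N),
            g_I=np.zeros(N),
            t_since_spike=np.full(N, np.inf),
        )

    @classmethod
    def ignition(cls, model: NetworkModel, seed: int = 0) -> "NetworkState":
        """Default initial state: developed, heterogeneous impairment.

        Membrane potentials start slightly and randomly depolarised from rest
        (U(E_L, E_L + 5 mV), everywhere below the spike-initiation saddle) and
        each cell's impairment variable starts near its attractor,
        z = (Z0 - E_L) * U(0.8, 1.1) — healthy cells, whose attractor is E_L,
        get exactly z = 0.  Impaired cells whose z starts at or above its
        equilibrium then ignite in a staggered fashion through the adaptation
        lag, which seeds network activity without any external drive and
        without artificial population-wide synchrony.
        """
        rng = np.random.default_rng(seed)
        state = cls.resting(model)
        state.V[:] = rng.uniform(model.params.E_L, model.params.E_L + 5.0, model.N)
        state.z[:] = (model.Z0 - model.params.E_L) * rng.uniform(0.8, 1.1, model.N)
        return state


@dataclass(frozen=True)
class RasterResult:
    """Spike events of a completed network run plus its configuration echo."""

    cells: np.ndarray        # int32 cell ids
    times: np.ndarray        # ms
    duration: float
    dt: float
    model_seed: int
    population_sizes: dict
    config: dict
    traces: dict = field(default_factory=dict)  # cell id -> Trace, if recorded

    def spike_counts(self) -> np.ndarray:
        counts = np.zeros(self.config["N"], dtype=np.int64)
        np.add.at(counts, self.cells, 1)
        return counts

    def __len__(self) -> int:
        return int(self.cells.size)


def build_network(
    N: int = 10000,
    frac_exc: float = 0.8,
    p: float = 0.05,
    N_SC: int = 0,
    Z0_impaired: float = -40.0,
    Z0_healthy: float = -65.0,
    seed: int = 0,
    params: ExtendedAdExParams | None = None,
    fs_a: float = 0.0,
    fs_b: float = 0.0,
    fs_Delta_T: float = 0.5,
) -> NetworkModel:
    """Assemble a directed Erdős–Rényi network with ``N_SC`` impaired cells.

    Every ordered pair (i, j), i != j, is connected independently with
    probability ``p``.  Excitatory cells occupy ids ``0..N_exc-1``; the
    impaired subset is drawn uniformly without replacement from them.  The
    whole construction is reproducible from ``seed``.
    """
    if params is None:
        params = ExtendedAdExParams()
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"connection probability must be in [0, 1], got {p}")
    n_inh = int(round((1.0 - frac_exc) * N))
    n_exc = N - n_inh
    if not 0 <= N_SC <= n_exc:
        raise ValueError(f"N_SC={N_SC} exceeds the excitatory population ({n_exc})")

    rng = np.random.default_rng(seed)
    impaired = rng.choice(n_exc, size=N_SC, replace=False) if N_SC else np.empty(0, int)

    labels = np.array([POP_RS_HEALTHY] * n_exc + [POP_FS] * n_inh, dtype=object)
    labels[impaired] = POP_RS_IMPAIRED
    is_exc = np.zeros(N, dtype=bool)
    is_exc[:n_exc] = True

    Z0 = np.full(N, Z0_healthy)
    Z0[impaired] = Z0_impaired
    a = np.full(N, params.a)
    b = np.full(N, params.b)
    Delta_T = np.full(N, params.Delta_T)
    a[n_exc:] = fs_a
    b[n_exc:] = fs_b
    Delta_T[n_exc:] = fs_Delta_T

    # row-wise sampling keeps peak memory at O(N) while drawing each ordered
    # pair independently
    rows = []
    for i in range(N):
        tgt = np.flatnonzero(rng.random(N) < p).astype(np.int32)
        rows.append(tgt[tgt != i])
    indptr = np.zeros(N + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([r.size for r in rows])
    targets = np.concatenate(rows) if rows else np.empty(0, np.int32)

    return NetworkModel(
        N=N, params=params, labels=labels, Z0=Z0, a=a, b=b, Delta_T=Delta_T,
        is_exc=is_exc, indptr=indptr, targets=targets, p=p, seed=seed,
    )


def deliver_spikes(
    state: NetworkState,
    spiking_cells: np.ndarray,
    model: NetworkModel,
    syn: SynapseParams,
) -> NetworkState:
    """Add one quantum per afferent spike to the postsynaptic conductances.

    Increments accumulate additively over simultaneous presynaptic spikes;
    excitatory senders (healthy or impaired) raise g_E by Q_E, inhibitory
    senders raise g_I by Q_I.  Modifies ``state`` in place and returns it.
    """
    for i in np.asarray(spiking_cells, dtype=np.int64):
        tgt = model.targets[model.indptr[i]:model.indptr[i + 1]]
        if model.is_exc[i]:
            np.add.at(state.g_E, tgt, syn.Q_E)
        else:
            np.add.at(state.g_I, tgt, syn.Q_I)
    return state


def integrate_network(
    model: NetworkModel,
    syn: SynapseParams | None = None,
    duration: float = 8000.0,
    dt: float = 0.1,
    seed: int = 0,
    init: NetworkState | None = None,
    record_cells: np.ndarray | list[int] | None = None,
    record_every: float = 1.0,
) -> RasterResult:
    """Fixed-step simulation of the full network.

    The update per step is synchronous: conductances decay by the exact
    factor ``exp(-dt/tau_syn)``, every cell takes one Euler step with the
    synaptic current evaluated at its pre-step potential, spikes are detected
    and reset, and this step's spikes increment their targets' conductances
    with effect from the next step.  When no explicit ``init`` is given the
    initial state is drawn from ``NetworkState.ignition`` with ``seed``.
    Identical model, synapse parameters, seed and config produce a
    bit-identical result.
    """
    if syn is None:
        syn = SynapseParams()
    if dt <= 0 or dt > 0.2:
        raise ValueError(f"network dt must be in (0, 0.2] ms, got {dt}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if init is None:
        init = NetworkState.ignition(model, seed)

    n_steps = int(round(duration / dt))
    decay = math.exp(-dt / syn.tau_syn)
    p = model.params

    if record_cells is None:
        rec_cells = np.empty(0, np.int64)
        stride = 1
        rec_V = rec_w = rec_z = np.empty((0, 0))
    else:
        rec_cells = np.asarray(record_cells, dtype=np.int64)
        stride = max(1, int(round(record_every / dt)))
        n_samples = n_steps // stride + 1
        rec_V = np.empty((n_samples, rec_cells.size))
        rec_w = np.empty((n_samples, rec_cells.size))
        rec_z = np.empty((n_samples, rec_cells.size))
        rec_V[0] = init.V[rec_cells]
        rec_w[0] = init.w[rec_cells]
        rec_z[0] = init.z[rec_cells]

    ev_cell, ev_step, n_ev, status, step, cell, n_rec_done = network_kernel(
        p.C, p.g_L, p.E_L, p.V_T, p.tau_w, p.I_s, p.V_D, p.V_R, p.t_ref,
        p.epsilon, p.g_p, p.beta,
        model.a, model.b, model.Z0, model.Delta_T, model.is_exc,
        syn.E_E, syn.E_I, syn.Q_E, syn.Q_I, decay,
        model.indptr, model.targets,
        init.V, init.w, init.z, init.g_E, init.g_I, init.t_since_spike,
        n_steps, dt,
        rec_cells, stride, rec_V, rec_w, rec_z,
    )
    if status == STATUS_NONFINITE:
        raise IntegrationError(f"cell {cell}: state became non-finite", step)
    if status == STATUS_EXP_OVERFLOW:
        raise IntegrationError(f"cell {cell}: exponential overflow", step)
    assert np.all(init.g_E >= 0) and np.all(init.g_I >= 0)
    init.time += n_steps * dt

    # events come out of the kernel already time-ordered
    cells = ev_cell[:n_ev].copy()
    times = ev_step[:n_ev].astype(float) * dt

    traces = {}
    if rec_cells.size:
        t = np.arange(n_rec_done) * (stride * dt)
        for r, cid in enumerate(rec_cells):
            traces[int(cid)] = Trace(
                t, rec_V[:n_rec_done, r], rec_w[:n_rec_done, r], rec_z[:n_rec_done, r]
            )

    pop_sizes = {pop: model.population_size(pop) for pop in POPULATIONS}
    config = {
        "N": model.N,
        "p": model.p,
        "duration": n_steps * dt,
        "dt": dt,
        "init_seed": seed,
        "synapses": syn.to_dict(),
        "params": p.to_dict(),
    }
    return RasterResult(
        cells=cells, times=times, duration=n_steps * dt, dt=dt,
        model_seed=model.seed, population_sizes=pop_sizes, config=config,
        traces=traces,
    )


def population_rate(
    result: RasterResult,
    model: NetworkModel,
    population: str,
    bin_ms: float = 5.0,
    smooth_ms: float = 25.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed per-cell average firing rate of one population, in Hz.

    The instantaneous rate is the spike count per ``bin_ms`` bin divided by
    the population size and the bin width, smoothed by a flat moving average
    of width ``smooth_ms``.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    mask = model.population_mask(population)
    n_cells = int(mask.sum())
    if n_cells == 0:
        raise ValueError(f"population {population!r} is empty")
    sel = mask[result.cells]
    edges = np.arange(0.0, result.duration + bin_ms, bin_ms)
    counts, _ = np.histogram(result.times[sel], bins=edges)
    rate = counts / (n_cells * bin_ms / 1000.0)
    width = max(1, int(round(smooth_ms / bin_ms)))
    kernel = np.ones(width) / width
    smoothed = np.convolve(rate, kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, smoothed


def max_population_rates(
    result: RasterResult,
    model: NetworkModel,
    bin_ms: float = 5.0,
    smooth_ms: float = 25.0,
) -> dict[str, float]:
    """Maximum of the smoothed rate trace per population over the run."""
    out = {}
    for pop in POPULATIONS:
        if model.population_size(pop):
            _, rate = population_rate(result, model, pop, bin_ms, smooth_ms)
            out[pop] = float(rate.max())
        else:
            out[pop] = 0.0
    return out


#: region labels of the (Z0, N_SC) plane
REGION_AI_CONTAINED = 1
REGION_INHIBITION_CONTAINED = 2
REGION_GLOBAL_PROPAGATION = 3


def classify_region(
    max_rates: dict[str, float],
    patho_threshold: float = 30.0,
    healthy_threshold: float = 30.0,
) -> int:
    """Three-region classification of a completed network run.

    Region 1: the impaired cells never reach pathological rates (the network
    stays in an asynchronous-irregular-like, contained state).  Region 2: the
    impaired population oscillates at pathological amplitude but inhibition
    confines it, the healthy excitatory cells staying at normal rates.
    Region 3: the pathological activity propagates to the healthy excitatory
    population as well.
    """
    impaired = max_rates.get(POP_RS_IMPAIRED, 0.0)
    healthy = max_rates.get(POP_RS_HEALTHY, 0.0)
    if impaired < patho_threshold:
        return REGION_AI_CONTAINED
    if healthy < healthy_threshold:
        return REGION_INHIBITION_CONTAINED
    return REGION_GLOBAL_PROPAGATION
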