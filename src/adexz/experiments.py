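"""Config-driven experiment drivers.

Each driver reproduces one of the package's canonical computational
experiments — reference single-neuron traces, the fast-subsystem bifurcation
diagram, the Z0 regime sweep, a single network run, and the (Z0, N_SC) grid
exploration — and writes plain CSV/JSON artifacts into a run directory
together with an echo of its configuration, so that every result is
reproducible from the written files alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fastslow import bifurcation_diagram, write_diagram
from .network import (
    POPULATIONS,
    build_network,
    classify_region,
    integrate_network,
    max_population_rates,
    population_rate,
)
from .neuron import NeuronState, SpikeTrain, integrate_neuron
from .params import ExtendedAdExParams, SynapseParams
from .patterns import ClassifierConfig, classify_trace, regime_boundaries
from .pattern_fixtures import constant_isi_train, clustered_train, poisson_train

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "run_exemplar_traces",
    "run_regime_sweep",
    "run_bifurcation",
    "run_network",
    "run_grid",
    "make_fixtures",
]

#: the three exemplar impairment levels: tonic, bursting, sustained ictal
EXEMPLAR_Z0 = (-45.0, -40.0, -20.0)

#: default desk-scale exploration grid of the (Z0, N_SC) plane
DEFAULT_GRID_Z0 = (-60.0, -50.0, -40.0, -30.0, -20.0, -10.0)
DEFAULT_GRID_NSC = (100, 500, 1000, 2000, 4000, 7500)


@dataclass
class ExperimentConfig:
    """Shared experiment settings; fields irrelevant to a driver are ignored."""

    outdir: str = "runs"
    overrides: dict = field(default_factory=dict)  # ExtendedAdExParams fields
    syn_overrides: dict = field(default_factory=dict)
    duration: float = 20000.0
    dt: float = 0.1
    seeds: tuple = (0,)
    Z0_grid: tuple = ()
    N_SC_grid: tuple = ()
    N: int = 10000
    p: float = 0.05
    net_duration: float = 8000.0
    plot: bool = False

    def params(self) -> ExtendedAdExParams:
        return ExtendedAdExParams(**self.overrides)

    def synapses(self) -> SynapseParams:
        return SynapseParams(**self.syn_overrides)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**json.loads(Path(path).read_text()))


def _prepare(config: ExperimentConfig, name: str) -> Path:
    out = Path(config.outdir) / name
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(asdict(config) | {"experiment": name, "hash": config.hash()},
                   indent=2, default=str) + "\n"
    )
    return out


def run_exemplar_traces(config: ExperimentConfig) -> dict:
    """Simulate the three exemplar impairment levels from identical rest state.

    Z0 = -45 / -40 / -20 mV from (V=E_L, w=0, z=0); traces, spike trains and
    pattern labels are written per level.  A label that disagrees with the
    expected tonic / bursting / sustained-ictal sequence is reported in the
    summary, never silently corrected.
    """
    out = _prepare(config, "exemplar_traces")
    expected = ("tonic", "bursting", "sustained_ictal")
    summary = []
    for Z0, want in zip(EXEMPLAR_Z0, expected):
        p = config.params().replace(Z0=Z0)
        init = NeuronState(V=p.E_L, w=0.0, z=0.0)
        trace, spikes = integrate_neuron(p, config.duration, config.dt, init=init)
        label = classify_trace(trace, spikes, p)
        tag = f"Z0_{Z0:+.0f}".replace("+", "p").replace("-", "m")
        trace.to_csv(out / f"trace_{tag}.csv")
        spikes.to_tsv(out / f"spikes_{tag}.tsv")
        summary.append(
            {"Z0": Z0, "expected": want, **label.to_dict(), "matches": label.label == want}
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {s["Z0"]: s for s in summary}


def run_regime_sweep(config: ExperimentConfig) -> dict:
    """Sweep Z0, classify each run, and bisect the regime boundaries."""
    out = _prepare(config, "regime_sweep")
    grid = np.array(config.Z0_grid) if config.Z0_grid else np.arange(-65.0, -9.9, 0.5)
    p = config.params()
    cfg = ClassifierConfig()
    from .patterns import classify_Z0

    labels = [(z0, classify_Z0(p, z0, config.duration, config.dt, cfg).label) for z0 in grid]
    bounds = regime_boundaries(p, grid, config.duration, config.dt, cfg)
    pd.DataFrame(labels, columns=["Z0_mV", "label"]).to_csv(out / "labels.csv", index=False)
    payload = [
        {"between": list(pair), "Z0_mV": z} for pair, z in bounds
    ]
    (out / "boundaries.json").write_text(json.dumps(payload, indent=2) + "\n")
    return {"labels": labels, "boundaries": bounds}


def run_bifurcation(config: ExperimentConfig) -> dict:
    """Fast-subsystem equilibria and bifurcations over the default z window."""
    out = _prepare(config, "bifurcation")
    eqs, events = bifurcation_diagram(config.params())
    write_diagram(eqs, events, out / "diagram.csv", out / "events.json")
    return {"n_equilibria": len(eqs), "events": events}


def _plot_rates(traces: dict, path: Path) -> None:
    """Optional side-effect-free figure; CSV/JSON remain the canonical outputs."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        logger.warning("matplotlib unavailable; skipping %s", path)
        return
    fig, ax = plt.subplots(figsize=(9, 3))
    t = traces.get("time_ms")
    for key, rate in traces.items():
        if key != "time_ms":
            ax.plot(t / 1000.0, rate, label=key.removeprefix("rate_").removesuffix("_Hz"))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("population rate (Hz)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _network_run(config: ExperimentConfig, N_SC: int, Z0: float, seed: int) -> dict:
    model = build_network(
        N=config.N, p=config.p, N_SC=N_SC, Z0_impaired=Z0,
        params=config.params(), seed=seed,
    )
    result = integrate_network(
        model, config.synapses(), duration=config.net_duration,
        dt=config.dt, seed=seed + 1,
    )
    rates = max_population_rates(result, model)
    return {
        "model": model,
        "result": result,
        "max_rates": rates,
        "region": classify_region(rates),
    }


def run_network(config: ExperimentConfig, N_SC: int, Z0: float) -> dict:
    """One full network run; writes the raster, rate traces and summary."""
    out = _prepare(config, f"net_Z0{Z0:+.0f}_NSC{N_SC}")
    seed = int(config.seeds[0])
    t0 = time.perf_counter()
    run = _network_run(config, N_SC, Z0, seed)
    elapsed = time.perf_counter() - t0
    result, model = run["result"], run["model"]

    with open(out / "spikes.tsv", "w") as fh:
        for c, t in zip(result.cells, result.times):
            fh.write(f"{c}\t{t:.1f}\n")
    traces = {}
    for pop in POPULATIONS:
        if model.population_size(pop):
            t, rate = population_rate(result, model, pop)
            traces["time_ms"] = t
            traces[f"rate_{pop}_Hz"] = rate
    pd.DataFrame(traces).to_csv(out / "rates.csv", index=False)
    if config.plot:
        _plot_rates(traces, out / "rates.png")
    summary = {
        "N_SC": N_SC, "Z0": Z0, "seed": seed,
        "population_sizes": result.population_sizes,
        "n_events": len(result),
        "max_rates": run["max_rates"], "region": run["region"],
        "wall_time_s": round(elapsed, 2), "config_hash": config.hash(),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    logger.info("network run %s: %s", out.name, summary)
    return summary


def run_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Explore the (Z0, N_SC) plane: max rates and region label per point.

    Results accumulate in ``regime_map.csv``; completed (Z0, N_SC, seed)
    points of the same configuration hash are skipped on re-run, so an
    interrupted grid resumes where it stopped.  Per-point failures are
    recorded with a null region and do not abort the remaining points.
    """
    out = _prepare(config, "grid")
    z0s = config.Z0_grid or DEFAULT_GRID_Z0
    nscs = config.N_SC_grid or DEFAULT_GRID_NSC
    map_path = out / "regime_map.csv"
    done: set[tuple] = set()
    rows: list[dict] = []
    if map_path.exists():
        prev = pd.read_csv(map_path)
        prev = prev[prev["config_hash"] == config.hash()]
        rows = prev.to_dict("records")
        done = {(r["Z0"], r["N_SC"], r["seed"]) for r in rows}

    for Z0 in z0s:
        for N_SC in nscs:
            for seed in config.seeds:
                key = (Z0, N_SC, int(seed))
                if key in done:
                    continue
                t0 = time.perf_counter()
                try:
                    run = _network_run(config, int(N_SC), float(Z0), int(seed))
                    rec = {
                        "Z0": Z0, "N_SC": N_SC, "seed": int(seed),
                        **{f"max_rate_{k}_Hz": v for k, v in run["max_rates"].items()},
                        "region": run["region"], "error": "",
                    }
                except Exception as exc:  # keep the grid going, mark the point
                    logger.exception("grid point %s failed", key)
                    rec = {"Z0": Z0, "N_SC": N_SC, "seed": int(seed), "region": None,
                           "error": str(exc)}
                rec["wall_time_s"] = round(time.perf_counter() - t0, 2)
                rec["config_hash"] = config.hash()
                rows.append(rec)
                pd.DataFrame(rows).to_csv(map_path, index=False)
    return pd.DataFrame(rows)


def make_fixtures(seed: int = 0, outdir: str | Path | None = None) -> dict:
    """Small deterministic test assets.

    A 200-cell network (160 excitatory / 40 inhibitory at the default 80/20
    split), three synthetic spike trains with known structure (constant-ISI,
    clustered, Poisson), and a reference trace of the classical AdEx limit
    (z frozen at zero).
    """
    model = build_network(N=200, p=0.05, N_SC=10, Z0_impaired=-40.0, seed=seed)
    trains = {
        "constant_isi": constant_isi_train(isi=100.0, duration=10000.0),
        "clustered": clustered_train(
            n_clusters=8, cluster_size=5, intra_isi=10.0, gap=1000.0
        ),
        "poisson": poisson_train(rate_hz=10.0, duration=10000.0, seed=seed),
    }
    p = ExtendedAdExParams(I_s=200.0)
    ref_trace, ref_spikes = integrate_neuron(
        p, 2000.0, init=NeuronState(V=p.E_L), frozen_z=True
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, train in trains.items():
            train.to_tsv(outdir / f"train_{name}.tsv")
        ref_trace.to_csv(outdir / "classical_adex_trace.csv")
    return {"network": model, "trains": trains,
            "classical_trace": ref_trace, "classical_spikes": ref_spikes}
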