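"""Single-neuron extended AdEx model: equations, reset, and fixed-step integration.

The model augments the classical AdEx (membrane potential V, adaptation
current w) with a slow impairment variable z:

    C dV/dt  = g_L((E_L+z) - V) + g_L*Delta_T*exp((V - (V_T - beta*z))/Delta_T)
               - w - g_p*z + I_s
    tau_w dw/dt = a(V - (E_L+z)) - w
    dz/dt    = epsilon (Z0 - V - z)

with the after-spike rule: if V >= V_D then V -> V_R, w -> w + b, followed by
an absolute refractory period t_ref during which V is clamped at V_R.
With z identically zero (and epsilon = 0) the system is the classical AdEx.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import STATUS_EXP_OVERFLOW, STATUS_NONFINITE, neuron_kernel
from .params import ExtendedAdExParams

__all__ = [
    "NeuronState",
    "SpikeTrain",
    "Trace",
    "vector_field",
    "apply_reset",
    "integrate_neuron",
]


@dataclass(frozen=True)
class NeuronState:
    """Instantaneous dynamical state (V in mV, w in pA, z in mV).

    ``t_since_spike`` is the refractory clock in ms; ``inf`` means the cell
    has never spiked.
    """

    V: float
    w: float = 0.0
    z: float = 0.0
    t_since_spike: float = math.inf

    def __post_init__(self) -> None:
        for name in ("V", "w", "z"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite state variable {name}={getattr(self, name)}")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) over a simulation of the given duration."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return int(self.times.size)

    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    def after(self, t0: float) -> "SpikeTrain":
        """Spikes at times strictly greater than ``t0`` (duration preserved)."""
        return SpikeTrain(self.times[self.times > t0], self.duration)

    def to_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.times[:, None], fmt="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path, duration: float) -> "SpikeTrain":
        times = np.loadtxt(path, ndmin=1)
        return cls(times, duration)


@dataclass(frozen=True)
class Trace:
    """Sampled trajectory of (V, w, z)."""

    sample_times: np.ndarray
    V: np.ndarray
    w: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_times)
        if not (len(self.V) == len(self.w) == len(self.z) == n):
            raise ValueError("trace arrays must have equal length")
        if n > 1 and np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample times must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_ms": self.sample_times, "V_mV": self.V, "w_pA": self.w, "z_mV": self.z}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        df = pd.read_csv(path)
        return cls(
            df["time_ms"].to_numpy(),
            df["V_mV"].to_numpy(),
            df["w_pA"].to_numpy(),
            df["z_mV"].to_numpy(),
        )


def vector_field(
    params: ExtendedAdExParams, state: NeuronState
) -> tuple[float, float, float]:
    """Right-hand side (dV/dt, dw/dt, dz/dt) of the smooth flow.

    Raises
    ------
    OverflowError
        If the exponential term is non-finite.  Within a valid run the reset
        fires at V_D, so V never reaches values where the exponential
        overflows; a non-finite value indicates a missed spike detection and
        is reported rather than clipped.
    """
    p = params
    expo = math.exp((state.V - (p.V_T - p.beta * state.z)) / p.Delta_T)
    if not math.isfinite(expo):
        raise OverflowError(
            f"exponential term overflow at V={state.V}: spike detection was missed"
        )
    dV = (
        p.g_L * ((p.E_L + state.z) - state.V)
        + p.g_L * p.Delta_T * expo
        - state.w
        - p.g_p * state.z
        + p.I_s
    ) / p.C
    dw = (p.a * (state.V - (p.E_L + state.z)) - state.w) / p.tau_w
    dz = p.epsilon * (p.Z0 - state.V - state.z)
    return dV, dw, dz


def apply_reset(state: NeuronState, params: ExtendedAdExParams) -> NeuronState:
    """After-spike rule: V -> V_R, w -> w + b, z untouched, refractory clock zeroed.

    Calling this with V < V_D is a contract violation and raises.
    """
    if state.V < params.V_D:
        raise ValueError(
            f"apply_reset called with V={state.V} below detection V_D={params.V_D}"
        )
    return NeuronState(V=params.V_R, w=state.w + params.b, z=state.z, t_since_spike=0.0)


class IntegrationError(RuntimeError):
    """Non-finite state or exponential overflow during integration."""

    def __init__(self, message: str, step: int):
        super().__init__(f"{message} (step {step})")
        self.step = step


def integrate_neuron(
    params: ExtendedAdExParams,
    duration: float,
    dt: float = 0.1,
    init: NeuronState | None = None,
    sample_every: float = 1.0,
    frozen_z: bool = False,
    freeze_w_in_refractory: bool = False,
) -> tuple[Trace, SpikeTrain]:
    """Explicit-Euler integration with spike detection and refractory clamp.

    Spikes are detected by V >= V_D after each Euler step and timestamped at
    the step's end.  During the refractory window V is clamped at V_R while w
    and z keep evolving under the clamped potential (set
    ``freeze_w_in_refractory`` to hold w instead).  With ``frozen_z`` the z
    equation is switched off (the epsilon -> 0 fast subsystem).

    Parameters
    ----------
    duration, dt, sample_every : ms
        ``dt`` must be positive and at most 1 ms (an explicit Euler step
        larger than the synaptic/refractory timescales is rejected);
        ``sample_every`` is rounded to a whole number of steps.
    init
        Initial state; defaults to rest, (V=E_L, w=0, z=0).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if dt > 1.0:
        raise ValueError(f"dt={dt} ms is too coarse for explicit Euler (max 1 ms)")
    if duration < dt:
        raise ValueError("duration must be at least one step")
    if init is None:
        init = NeuronState(V=params.E_L, w=0.0, z=0.0)

    n_steps = int(round(duration / dt))
    sample_stride = max(1, int(round(sample_every / dt)))
    p = params
    sV, sw, sz, spike_times, n_spikes, status, step = neuron_kernel(
        p.C, p.g_L, p.E_L, p.V_T, p.Delta_T, p.tau_w, p.a, p.b, p.I_s,
        p.V_D, p.V_R, p.t_ref, p.epsilon, p.Z0, p.g_p, p.beta,
        init.V, init.w, init.z, init.t_since_spike,
        n_steps, dt, sample_stride, frozen_z, freeze_w_in_refractory,
    )
    if status == STATUS_NONFINITE:
        raise IntegrationError("state became non-finite", step)
    if status == STATUS_EXP_OVERFLOW:
        raise IntegrationError(
            "exponential term overflow: spike detection was missed", step
        )
    n_samples = n_steps // sample_stride + 1
    t = np.arange(n_samples) * (sample_stride * dt)
    trace = Trace(t, sV[:n_samples], sw[:n_samples], sz[:n_samples])
    spikes = SpikeTrain(spike_times[:n_spikes].copy(), duration=n_steps * dt)
    return trace, spikes
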