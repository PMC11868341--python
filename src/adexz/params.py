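"""Parameter sets for the extended AdEx neuron and conductance-based synapses.

Canonical internal units are mV / ms / pA / nS / pF, which form a
dimensionally consistent system (nS·mV = pA, pF·mV/ms = pA).  Parameter
tables in this literature often mix seconds and milliseconds; values quoted
in seconds are converted once, at load time, by the helpers below.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = ["ExtendedAdExParams", "SynapseParams", "reference_params", "reference_synapses"]


@dataclass(frozen=True)
class ExtendedAdExParams:
    """Constants of the extended AdEx neuron (membrane V, adaptation w, impairment z).

    The impairment variable z shifts the leak reversal to ``E_L + z`` and the
    spike-initiation threshold to ``V_T - beta*z``, and injects a counteractive
    current ``-g_p*z`` standing in for homeostatic machinery (Na/K pump,
    co-transporters) that works against the ionic dysregulation.  z relaxes
    toward ``Z0 - V`` at rate ``epsilon``; Z0 is the potential the impairment
    drags the cell toward, so larger (less negative) Z0 means a more severe
    impairment.

    Attributes
    ----------
    C : membrane capacitance (pF)
    g_L : leak conductance (nS)
    E_L : resting (leak reversal) potential (mV)
    V_T : exponential spike-initiation threshold (mV)
    Delta_T : exponential sharpness (mV)
    tau_w : adaptation time constant (ms)
    a : subthreshold adaptation conductance (nS)
    b : spike-triggered adaptation increment (pA)
    I_s : constant input current (pA)
    V_D : spike-detection potential (mV)
    V_R : post-spike reset potential (mV)
    t_ref : absolute refractory period (ms)
    epsilon : relaxation rate of z (1/ms)
    Z0 : impairment attractor potential (mV)
    g_p : counteractive (pump-equivalent) conductance (nS)
    beta : dimensionless scale of the threshold shift by z
    """

    C: float = 200.0
    g_L: float = 10.0
    E_L: float = -65.0
    V_T: float = -55.0
    Delta_T: float = 2.0
    tau_w: float = 500.0
    a: float = 1.0
    b: float = 60.0
    I_s: float = 0.0
    V_D: float = -40.0
    V_R: float = -65.0
    t_ref: float = 5.0
    epsilon: float = 5e-4
    Z0: float = -40.0
    g_p: float = 10.0
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.g_L < 0:
            raise ValueError(f"g_L must be non-negative, got {self.g_L}")
        if not self.Delta_T > 0:
            raise ValueError(f"Delta_T must be positive, got {self.Delta_T}")
        if not self.tau_w > 0:
            raise ValueError(f"tau_w must be positive, got {self.tau_w}")
        if self.t_ref < 0:
            raise ValueError(f"t_ref must be non-negative, got {self.t_ref}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon}")
        if self.g_p < 0:
            raise ValueError(f"g_p must be non-negative, got {self.g_p}")
        if not self.V_R < self.V_D:
            raise ValueError(
                f"reset must lie strictly below detection: V_R={self.V_R}, V_D={self.V_D}"
            )

    def replace(self, **changes) -> "ExtendedAdExParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExtendedAdExParams":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ExtendedAdExParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SynapseParams:
    """Conductance-based synapse constants.

    An incoming spike increments the target's excitatory (inhibitory)
    conductance by ``Q_E`` (``Q_I``); conductances decay exponentially with
    time constant ``tau_syn`` and drive the current
    ``I_syn = g_E (E_E - V) + g_I (E_I - V)``.
    """

    E_E: float = 0.0
    E_I: float = -80.0
    Q_E: float = 1.5
    Q_I: float = 5.0
    tau_syn: float = 5.0

    def __post_init__(self) -> None:
        if self.Q_E < 0 or self.Q_I < 0:
            raise ValueError("quantal increments must be non-negative")
        if not self.tau_syn > 0:
            raise ValueError(f"tau_syn must be positive, got {self.tau_syn}")
        if not self.E_I < self.E_E:
            raise ValueError(
                f"inhibitory reversal must lie below excitatory: E_I={self.E_I}, E_E={self.E_E}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynapseParams":
        return cls(**d)


def reference_params(**overrides) -> ExtendedAdExParams:
    """Reference single-neuron parameter set in canonical units.

    Quantities quoted in seconds are converted here: tau_w = 0.5 s ->
    500 ms.  The z relaxation rate is epsilon = 5e-4 per ms (time constant
    2 s), an order of magnitude slower than the adaptation and the rate at
    which seizure-like activity builds up on the seconds timescale.
    """
    logger.debug("tau_w converted 0.5 s -> 500 ms; epsilon = 5e-4 / ms (tau_z = 2 s)")
    return ExtendedAdExParams(**overrides)


def reference_synapses(**overrides) -> SynapseParams:
    """Reference synapse parameter set (already in canonical units)."""
    return SynapseParams(**overrides)
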