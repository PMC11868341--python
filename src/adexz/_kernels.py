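"""Numba-compiled fixed-step integration kernels.

The single-neuron and network kernels perform the per-cell Euler update with
statement-for-statement identical arithmetic, so that a network with all
synaptic increments set to zero reproduces the isolated-neuron trajectory
bit-for-bit (the decoupled-limit invariant the test suite asserts).

Status codes returned by the kernels: 0 = ok, 1 = non-finite state (the
offending step index, and for the network the cell id, are returned
alongside), 2 = exponential-term overflow, which signals a missed spike
detection rather than a tolerable rounding issue.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_EXP_OVERFLOW = 2


@njit(cache=True)
def neuron_kernel(
    C, g_L, E_L, V_T, Delta_T, tau_w, a, b, I_s, V_D, V_R, t_ref,
    epsilon, Z0, g_p, beta,
    V0, w0, z0, tsl0,
    n_steps, dt, sample_stride, frozen_z, freeze_w_in_ref,
):
    n_samples = n_steps // sample_stride + 1
    sV = np.empty(n_samples)
    sw = np.empty(n_samples)
    sz = np.empty(n_samples)
    max_spikes = int(n_steps * dt / max(t_ref, dt)) + 2
    spike_times = np.empty(max_spikes)
    n_spikes = 0

    V = V0
    w = w0
    z = z0
    tsl = tsl0

    sV[0] = V
    sw[0] = w
    sz[0] = z
    i_sample = 1

    for k in range(n_steps):
        refractory = tsl < t_ref
        Vc = V_R if refractory else V
        expo = np.exp((Vc - (V_T - beta * z)) / Delta_T)
        if not np.isfinite(expo):
            return sV, sw, sz, spike_times, n_spikes, STATUS_EXP_OVERFLOW, k
        dV = (g_L * ((E_L + z) - Vc) + g_L * Delta_T * expo - w - g_p * z + I_s) / C
        dw = (a * (Vc - (E_L + z)) - w) / tau_w
        dz = epsilon * (Z0 - Vc - z)
        if refractory:
            V = V_R
            if not freeze_w_in_ref:
                w = w + dt * dw
        else:
            V = V + dt * dV
            w = w + dt * dw
        if not frozen_z:
            z = z + dt * dz
        tsl = tsl + dt
        if not refractory and V >= V_D:
            V = V_R
            w = w + b
            tsl = 0.0
            spike_times[n_spikes] = (k + 1) * dt
            n_spikes += 1
        if not (np.isfinite(V) and np.isfinite(w) and np.isfinite(z)):
            return sV, sw, sz, spike_times, n_spikes, STATUS_NONFINITE, k
        if (k + 1) % sample_stride == 0:
            sV[i_sample] = V
            sw[i_sample] = w
            sz[i_sample] = z
            i_sample += 1

    return sV, sw, sz, spike_times, n_spikes, STATUS_OK, n_steps


@njit(cache=True)
def network_kernel(
    C, g_L, E_L, V_T, tau_w, I_s, V_D, V_R, t_ref,
    epsilon, g_p, beta,
    a_cell, b_cell, Z0_cell, Delta_T_cell, is_exc,
    E_E, E_I, Q_E, Q_I, decay,
    indptr, targets,
    V, w, z, g_E, g_I, tsl,
    n_steps, dt,
    rec_cells, rec_stride, rec_V, rec_w, rec_z,
):
    """Synchronous network update.

    Per step: (1) exact exponential conductance decay, (2) Euler update of
    every cell with the synaptic current evaluated at the pre-step V,
    (3) spike detection and reset, (4) delivery of this step's spikes to
    postsynaptic conductances, effective from the next step.  State arrays
    are updated in place; spike events are returned as (cell, step) pairs.
    """
    N = V.shape[0]
    max_events = int(np.ceil(n_steps * dt / max(t_ref, dt)) + 2) * N
    ev_cell = np.empty(max_events, np.int32)
    ev_step = np.empty(max_events, np.int32)
    n_ev = 0
    spiking = np.empty(N, np.int32)
    n_rec = rec_cells.shape[0]
    i_rec = 1

    for k in range(n_steps):
        for i in range(N):
            g_E[i] = g_E[i] * decay
            g_I[i] = g_I[i] * decay

        n_spk = 0
        for i in range(N):
            refractory = tsl[i] < t_ref
            Vc = V_R if refractory else V[i]
            zi = z[i]
            wi = w[i]
            Delta_T = Delta_T_cell[i]
            expo = np.exp((Vc - (V_T - beta * zi)) / Delta_T)
            if not np.isfinite(expo):
                return ev_cell, ev_step, n_ev, STATUS_EXP_OVERFLOW, k, i, i_rec
            I_tot = I_s + g_E[i] * (E_E - Vc) + g_I[i] * (E_I - Vc)
            dV = (g_L * ((E_L + zi) - Vc) + g_L * Delta_T * expo - wi - g_p * zi + I_tot) / C
            dw = (a_cell[i] * (Vc - (E_L + zi)) - wi) / tau_w
            dz = epsilon * (Z0_cell[i] - Vc - zi)
            if refractory:
                V[i] = V_R
                w[i] = wi + dt * dw
            else:
                V[i] = Vc + dt * dV
                w[i] = wi + dt * dw
            z[i] = zi + dt * dz
            tsl[i] = tsl[i] + dt
            if not refractory and V[i] >= V_D:
                V[i] = V_R
                w[i] = w[i] + b_cell[i]
                tsl[i] = 0.0
                ev_cell[n_ev] = i
                ev_step[n_ev] = k + 1
                n_ev += 1
                spiking[n_spk] = i
                n_spk += 1
            if not (np.isfinite(V[i]) and np.isfinite(w[i]) and np.isfinite(z[i])):
                return ev_cell, ev_step, n_ev, STATUS_NONFINITE, k, i, i_rec

        for s in range(n_spk):
            i = spiking[s]
            if is_exc[i]:
                for e in range(indptr[i], indptr[i + 1]):
                    g_E[targets[e]] += Q_E
            else:
                for e in range(indptr[i], indptr[i + 1]):
                    g_I[targets[e]] += Q_I

        if n_rec > 0 and (k + 1) % rec_stride == 0:
            for r in range(n_rec):
                rec_V[i_rec, r] = V[rec_cells[r]]
                rec_w[i_rec, r] = w[rec_cells[r]]
                rec_z[i_rec, r] = z[rec_cells[r]]
            i_rec += 1

    return ev_cell, ev_step, n_ev, STATUS_OK, n_steps, -1, i_rec
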