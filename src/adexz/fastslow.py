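"""Slow-fast analysis of the (V, w) fast subsystem with z frozen as a parameter.

Taking the epsilon -> 0 limit turns z into a bifurcation parameter of the
two-dimensional membrane/adaptation subsystem.  This module locates its
equilibria, classifies their stability from the Jacobian trace and
determinant, tracks them over a z window to find the Andronov-Hopf and
saddle-node bifurcations through which spiking activity appears and the
resting state disappears, and samples the V- and w-nullsurfaces for
three-dimensional phase-space visualisation.

Limit cycles are not continued here: the onset of the spiking cycle
(which owes its existence to the reset) is delegated to direct simulation
and the pattern classifier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .params import ExtendedAdExParams

__all__ = [
    "Equilibrium",
    "BifurcationEvent",
    "fixed_points",
    "jacobian",
    "trace_det",
    "bifurcation_diagram",
    "nullsurface_samples",
    "NullsurfaceGrid",
    "write_diagram",
]

#: |trace| (1/ms) resp. |det| (1/ms^2) below which an event is accepted
EVENT_TOL = 1e-8
#: bisection resolution in z (mV) for event location
Z_BISECT_TOL = 1e-6


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the fast subsystem at frozen z, with its stability."""

    z: float
    V_star: float
    w_star: float
    trace: float
    det: float
    stability: str  # stable_node | stable_focus | saddle | unstable_node | unstable_focus

    @property
    def is_stable(self) -> bool:
        return self.stability.startswith("stable")

    @property
    def is_saddle(self) -> bool:
        return self.stability == "saddle"


@dataclass(frozen=True)
class BifurcationEvent:
    kind: str  # andronov_hopf | saddle_node
    z_value: float
    V_value: float


def _v_residual(p: ExtendedAdExParams, V: float, z: float) -> float:
    """dV/dt * C with w eliminated through the w-nullcline w = a(V - (E_L+z)).

    Zeros of this scalar function in V are the fast-subsystem equilibria.
    """
    return (
        p.g_L * ((p.E_L + z) - V)
        + p.g_L * p.Delta_T * math.exp((V - (p.V_T - p.beta * z)) / p.Delta_T)
        - p.a * (V - (p.E_L + z))
        - p.g_p * z
        + p.I_s
    )


def jacobian(params: ExtendedAdExParams, V: float, z: float) -> np.ndarray:
    """Jacobian of the (V, w) subsystem at the given point (rows in 1/ms)."""
    p = params
    expo = math.exp((V - (p.V_T - p.beta * z)) / p.Delta_T)
    return np.array(
        [
            [p.g_L / p.C * (-1.0 + expo), -1.0 / p.C],
            [p.a / p.tau_w, -1.0 / p.tau_w],
        ]
    )


def trace_det(params: ExtendedAdExParams, V: float, z: float) -> tuple[float, float]:
    """Closed-form trace (1/ms) and determinant (1/ms^2) of the Jacobian."""
    p = params
    expo = math.exp((V - (p.V_T - p.beta * z)) / p.Delta_T)
    tr = p.g_L / p.C * (-1.0 + expo) - 1.0 / p.tau_w
    det = (-p.g_L * (-1.0 + expo) + p.a) / (p.C * p.tau_w)
    return tr, det


def _classify(tr: float, det: float) -> str:
    if det < 0:
        return "saddle"
    disc = tr * tr - 4.0 * det
    if tr < 0:
        return "stable_node" if disc >= 0 else "stable_focus"
    return "unstable_node" if disc >= 0 else "unstable_focus"


def _default_window(p: ExtendedAdExParams) -> tuple[float, float]:
    return (p.E_L - 40.0, p.V_D)


def fixed_points(
    params: ExtendedAdExParams,
    z: float,
    v_window: tuple[float, float] | None = None,
    n_scan: int = 2000,
) -> list[Equilibrium]:
    """All equilibria of the fast subsystem at frozen z, sorted by V_star.

    Roots of the V-residual are bracketed by a sign scan over ``n_scan``
    points of the search window (default [E_L - 40, V_D]) and polished by
    Brent's method; generic parameters yield zero or two roots, the fold
    (saddle-node) being the tangency in between.
    """
    p = params
    lo, hi = v_window if v_window is not None else _default_window(p)
    grid = np.linspace(lo, hi, n_scan)
    res = np.array([_v_residual(p, v, z) for v in grid])
    roots: list[float] = []
    for i in range(n_scan - 1):
        r0, r1 = res[i], res[i + 1]
        if r0 == 0.0:
            roots.append(grid[i])
        elif r0 * r1 < 0:
            roots.append(brentq(lambda v: _v_residual(p, v, z), grid[i], grid[i + 1],
                                xtol=1e-12))
    if res[-1] == 0.0:
        roots.append(grid[-1])

    out = []
    for V_star in roots:
        w_star = p.a * (V_star - (p.E_L + z))
        tr, det = trace_det(p, V_star, z)
        out.append(Equilibrium(z, V_star, w_star, tr, det, _classify(tr, det)))
    return sorted(out, key=lambda e: e.V_star)


def _lower_equilibrium(p: ExtendedAdExParams, z: float) -> Equilibrium | None:
    eqs = fixed_points(p, z)
    return eqs[0] if eqs else None


def bifurcation_diagram(
    params: ExtendedAdExParams,
    z_min: float = -30.0,
    z_max: float = 60.0,
    n_grid: int = 400,
) -> tuple[list[Equilibrium], list[BifurcationEvent]]:
    """Track fast-subsystem equilibria over a z window and locate bifurcations.

    The Andronov-Hopf point is found by bisection on the sign change of the
    Jacobian trace along the lower (non-saddle) branch, verifying det > 0
    there; the saddle-node by bisection on the change of the equilibrium
    count as the two branches collide at the fold.  For the reference
    parameters the Hopf precedes the fold as z increases, which is the order
    in which the resting state loses stability and then disappears.
    """
    if not z_min < z_max:
        raise ValueError("need z_min < z_max")
    if n_grid < 100:
        raise ValueError("n_grid must be at least 100")
    p = params

    z_grid = list(np.linspace(z_min, z_max, n_grid))
    branch: list[list[Equilibrium]] = [fixed_points(p, z) for z in z_grid]

    # refine intervals where a tracked equilibrium jumps by more than 5 mV
    refined_z, refined_b = [z_grid[0]], [branch[0]]
    for i in range(1, len(z_grid)):
        prev, cur = refined_b[-1], branch[i]
        jump = (
            bool(prev)
            and bool(cur)
            and abs(cur[0].V_star - prev[0].V_star) > 5.0
        )
        if jump:
            for zf in np.linspace(refined_z[-1], z_grid[i], 12)[1:-1]:
                refined_z.append(zf)
                refined_b.append(fixed_points(p, zf))
        refined_z.append(z_grid[i])
        refined_b.append(cur)
    z_grid, branch = refined_z, refined_b

    events: list[BifurcationEvent] = []

    # saddle-node: equilibrium count drops from 2 to 0
    fold_lo: float | None = None  # largest z at which equilibria still exist
    for i in range(len(z_grid) - 1):
        n0, n1 = len(branch[i]), len(branch[i + 1])
        if n0 >= 2 and n1 == 0:
            lo, hi = z_grid[i], z_grid[i + 1]
            while hi - lo > Z_BISECT_TOL:
                mid = 0.5 * (lo + hi)
                if fixed_points(p, mid):
                    lo = mid
                else:
                    hi = mid
            eqs = fixed_points(p, lo)
            V_sn = 0.5 * (eqs[0].V_star + eqs[-1].V_star) if eqs else math.nan
            events.append(BifurcationEvent("saddle_node", 0.5 * (lo + hi), V_sn))
            fold_lo = lo

    # Andronov-Hopf: trace sign change along the lower (non-saddle) branch
    # with det > 0.  With weak subthreshold adaptation the Hopf sits very
    # close to the fold, so the refined fold point is appended to the scan:
    # a sign change between the last populated grid point and the fold is
    # bracketed there rather than lost past the grid resolution.
    def branch_trace(z: float) -> float:
        eq = _lower_equilibrium(p, z)
        return eq.trace if eq is not None else math.nan

    scan: list[tuple[float, float]] = [
        (z, eqs[0].trace) for z, eqs in zip(z_grid, branch) if eqs
    ]
    if fold_lo is not None and (not scan or fold_lo > scan[-1][0]):
        scan.append((fold_lo, branch_trace(fold_lo)))
    for (za, ta), (zb, tb) in zip(scan, scan[1:]):
        if ta == 0.0 or not (math.isfinite(ta) and math.isfinite(tb)) or ta * tb >= 0:
            continue
        z_ah = brentq(branch_trace, za, zb, xtol=Z_BISECT_TOL * 1e-3)
        eq = _lower_equilibrium(p, z_ah)
        if eq is not None and eq.det > 0:
            events.append(BifurcationEvent("andronov_hopf", z_ah, eq.V_star))

    events.sort(key=lambda e: e.z_value)
    equilibria = [e for eqs in branch for e in eqs]
    return equilibria, events


@dataclass(frozen=True)
class NullsurfaceGrid:
    """Sampled V- and w-nullsurfaces over a (V, z) grid.

    ``w_V_null[i, j]`` is the unique w solving dV/dt = 0 at (V[i], z[j]) —
    w enters the membrane equation linearly, so the V-nullsurface is a graph
    over (V, z).  ``fold_V[j] = V_T - beta*z[j]`` is the fold curve of that
    surface, where its tangent plane becomes vertical in V (the saddle-node
    condition of the fast subsystem at a = 0).
    """

    V: np.ndarray
    z: np.ndarray
    w_V_null: np.ndarray
    w_w_null: np.ndarray
    fold_V: np.ndarray


def nullsurface_samples(
    params: ExtendedAdExParams,
    V_range: tuple[float, float],
    z_range: tuple[float, float],
    n_V: int = 100,
    n_z: int = 100,
) -> NullsurfaceGrid:
    p = params
    V = np.linspace(*V_range, n_V)
    z = np.linspace(*z_range, n_z)
    Vg, zg = np.meshgrid(V, z, indexing="ij")
    w_V_null = (
        p.g_L * ((p.E_L + zg) - Vg)
        + p.g_L * p.Delta_T * np.exp((Vg - (p.V_T - p.beta * zg)) / p.Delta_T)
        - p.g_p * zg
        + p.I_s
    )
    w_w_null = p.a * (Vg - (p.E_L + zg))
    fold_V = p.V_T - p.beta * z
    return NullsurfaceGrid(V, z, w_V_null, w_w_null, fold_V)


def write_diagram(
    equilibria: list[Equilibrium],
    events: list[BifurcationEvent],
    csv_path: str | Path,
    events_path: str | Path,
) -> None:
    pd.DataFrame(
        {
            "z_mV": [e.z for e in equilibria],
            "V_star_mV": [e.V_star for e in equilibria],
            "w_star_pA": [e.w_star for e in equilibria],
            "trace": [e.trace for e in equilibria],
            "det": [e.det for e in equilibria],
            "stability": [e.stability for e in equilibria],
        }
    ).to_csv(csv_path, index=False)
    Path(events_path).write_text(
        json.dumps(
            [
                {"kind": e.kind, "z_value": e.z_value, "V_value": e.V_value}
                for e in events
            ],
            indent=2,
        )
        + "\n"
    )
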