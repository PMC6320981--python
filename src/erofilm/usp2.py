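"""Drug release from a swelling/eroding film under perfect-sink conditions.

This is the USP II (paddle) configuration: both film faces exposed, the bulk
is large and well stirred, so the drug concentration at the gel-solvent
front is pinned at zero.  Drug diffuses through the rubbery gel R(t) < z <
S(t) with a Stefan condition at the receding glassy-rubbery front (the glassy
core carries the drug at its loading concentration c0 and releases it into
the gel as the front passes), and the front kinematics come from the
swelling-erosion solver (one-way coupling).

The cumulative release is inventory-based:

    Mt = A [ c0 L0 - 2 (c0 R(t) + \\int_R^S cG dz) ]

so erosion automatically releases the drug contained in removed gel.  The
same front-fixed transport core is reusable for any prescribed front motion
(e.g. a frozen fully swollen slab, which has a classical eigenfunction
solution used as a validation oracle).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .swelling import FrontMotion, SwellingParams, SwellingTrajectory, solve_swelling

__all__ = ["USP2Config", "USP2Release", "solve_usp2_release", "solve_gel_drug_1d", "slab_release_series"]


@dataclass(frozen=True)
class USP2Config:
    """Film and loading for a paddle-apparatus release run.

    ``swelling`` must use the symmetric geometry (both faces wetted); ``DG``
    is the drug diffusivity in the swollen gel (m²/s), ``c0`` the initial
    drug loading (kg/m³) and ``A`` the film area (m²).
    """

    swelling: SwellingParams
    DG: float
    c0: float
    A: float = 1e-4

    def __post_init__(self):
        if self.swelling.geometry != "symmetric":
            raise ValueError("USP II release requires symmetric swelling geometry")
        if min(self.DG, self.c0, self.A) <= 0:
            raise ValueError("DG, c0 and A must be positive")


@dataclass
class USP2Release:
    """Release curve: cumulative mass Mt (kg), fraction Mt/(A c0 L0) and the
    dimensionless time tau = t DGs / L0²."""

    config: USP2Config
    t: np.ndarray
    Mt: np.ndarray
    Mt_frac: np.ndarray
    tau: np.ndarray
    fronts: FrontMotion
    meta: dict = field(default_factory=dict)


def solve_gel_drug_1d(
    fronts: FrontMotion,
    DG: float,
    c0: float,
    t_grid: np.ndarray,
    *,
    n_nodes: int = 41,
    rtol: float = 1e-6,
    atol: float = None,
    t_start: float | None = None,
):
    """Integrate sink-boundary drug diffusion on the moving gel domain.

    Returns ``(t_grid, inventory)`` where ``inventory(t) = c0 R(t) +
    \\int_R^S c dz`` is the drug column remaining per unit area on one side.
    Front positions/rates are taken from ``fronts``; the gel node at the
    outer front is held at zero (perfect sink) and the inner boundary obeys
    the drug Stefan condition (no-flux once the glassy core is gone,
    automatically, since the front rate is then zero).
    """
    N = int(n_nodes)
    xi = np.linspace(0.0, 1.0, N)
    dxi = xi[1] - xi[0]
    if atol is None:
        atol = 1e-9 * c0

    t0 = float(fronts.t[0]) if t_start is None else float(t_start)
    t_diss = fronts.t_dissolved
    t_end = float(t_grid[-1])
    t_stop = t_end if t_diss is None else min(t_end, t_diss)

    def rhs(t, y):
        R = fronts.R_at(t)
        S = fronts.S_at(t)
        Rdot = fronts.Rdot_at(t)
        Sdot = fronts.Sdot_at(t)
        h = max(S - R, 1e-9 * (fronts.S_at(t0) - fronts.R_at(t0) + 1e-30))
        c = np.empty(N)
        c[:-1] = y
        c[-1] = 0.0  # perfect sink at the gel-solvent front
        dz = h * dxi
        J_half = DG * np.diff(c) / dz           # physical fluxes at half nodes
        J_R = Rdot * (c0 - c[0])                # Stefan flux at the inner front
        dy = np.empty(N - 1)
        dy[0] = 2.0 * (J_half[0] - J_R) / dz + Rdot * J_R / DG
        v = Rdot * (1.0 - xi[1:-1]) + Sdot * xi[1:-1]
        dy[1:] = (J_half[1:] - J_half[:-1]) / dz + v * (c[2:] - c[:-2]) / (2.0 * dz)
        return dy

    y0 = np.full(N - 1, c0)
    seg_breaks = [t0]
    if fronts.t_glassy is not None and t0 < fronts.t_glassy < t_stop:
        seg_breaks.append(float(fronts.t_glassy))
    seg_breaks.append(t_stop)

    inv = np.empty(len(t_grid))
    done = np.zeros(len(t_grid), dtype=bool)
    for i, t in enumerate(t_grid):
        if t <= t0:
            inv[i] = c0 * fronts.S_at(t0)  # everything still in the film
            done[i] = True
        elif t_diss is not None and t >= t_diss:
            inv[i] = 0.0
            done[i] = True

    y = y0
    for a, b in zip(seg_breaks[:-1], seg_breaks[1:]):
        mask = (~done) & (t_grid > a) & (t_grid <= b)
        t_eval = np.sort(t_grid[mask])
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval if len(t_eval) else None,
                        rtol=rtol, atol=atol, lband=1, uband=1, dense_output=len(t_eval) == 0)
        if not sol.success:
            raise RuntimeError(f"drug transport integration failed: {sol.message}")
        if len(t_eval):
            for k, t in enumerate(sol.t):
                idx = np.nonzero((t_grid == t) & mask)[0]
                c = np.concatenate([sol.y[:, k], [0.0]])
                h = fronts.S_at(t) - fronts.R_at(t)
                val = fronts.R_at(t) * c0 + h * np.trapezoid(c, xi)
                for j in idx:
                    inv[j] = val
                    done[j] = True
            y = sol.y[:, -1]
        else:
            y = sol.sol(b) if sol.sol is not None else sol.y[:, -1]
    # anything after t_stop but before dissolution keeps the last inventory
    for i, t in enumerate(t_grid):
        if not done[i]:
            c = np.concatenate([y, [0.0]])
            h = fronts.S_at(t_stop) - fronts.R_at(t_stop)
            inv[i] = fronts.R_at(t_stop) * c0 + h * np.trapezoid(c, xi)
    return np.asarray(t_grid, float), inv


def solve_usp2_release(
    config: USP2Config,
    t_grid,
    *,
    n_nodes: int = 41,
    swelling_kwargs: dict | None = None,
    rtol: float = 1e-6,
) -> USP2Release:
    """Solve swelling-erosion plus sink-boundary drug diffusion.

    ``t_grid`` must start at 0; ``Mt = A (c0 L0 - 2 * inventory_per_side)``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")
    p = config.swelling
    traj = solve_swelling(p, t_end=float(t_grid[-1]), **(swelling_kwargs or {}))
    fronts = traj.fronts
    _, inv = solve_gel_drug_1d(fronts, config.DG, config.c0, t_grid,
                               n_nodes=n_nodes, rtol=rtol)
    M_inf = config.A * config.c0 * p.L0
    Mt = M_inf - 2.0 * config.A * inv
    Mt = np.maximum.accumulate(np.clip(Mt, 0.0, M_inf))
    return USP2Release(
        config=config, t=t_grid, Mt=Mt, Mt_frac=Mt / M_inf,
        tau=t_grid * p.DGs / p.L0**2, fronts=fronts,
        meta={"t_dissolved": traj.t_dissolved, "n_nodes": n_nodes},
    )


def slab_release_series(t, DG: float, h: float, n_terms: int = 200):
    """Closed-form release fraction for a frozen slab 0<z<h, no-flux at 0,
    sink at h, uniform initial load (eigenfunction expansion); oracle for the
    moving-boundary solver in its degenerate limit."""
    t = np.asarray(t, dtype=float)
    k = np.arange(n_terms)[:, None]
    lam = (2 * k + 1) * np.pi / (2 * h)
    series = (8 / ((2 * k + 1) ** 2 * np.pi**2)) * np.exp(-DG * lam**2 * t[None, :])
    return 1.0 - series.sum(axis=0)
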