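"""1D moving-boundary swelling and erosion of a water-soluble polymer film.

The film is described by the solvent volume fraction phi(z, t) on the rubbery
(gel) region R(t) < z < S(t):

    d(phi)/dt = d/dz [ Ds(phi) (1 - phi) d(phi)/dz ]

with a swelling (glassy-rubbery) front R(t) governed by a Stefan condition at
the threshold fraction phi_g, and an erosion (gel-solvent) front S(t) held at
the equilibrium fraction phi_eq and moved by the competition between solvent
influx and chain disentanglement:

    dS/dt = DGs * d(phi)/dz|_S - Rdis,      Rdis = C (1 - phi)^1.625 .

Below the glassy-rubbery front the film is dry polymer at phi_0.  Two
geometries are supported: ``symmetric`` (both faces wetted, domain is the half
film, symmetry plane at z = 0) and ``anchored`` (film glued to an impermeable
wall at z = 0, single wetted face).

Numerics: front-fixing (Landau) map of [R, S] onto the unit interval,
conservative method-of-lines in space, stiff adaptive time integration
(scipy ``solve_ivp``), with explicit events for glassy-core exhaustion and
complete dissolution.  The t = 0 contact singularity is regularised by seeding
a thin gel layer (a fraction ``seed_frac`` of L0 wide, linear profile); tests
verify insensitivity to the seed width.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SwellingParams",
    "FrontState",
    "FrontMotion",
    "SwellingTrajectory",
    "solvent_diffusivity",
    "disentanglement_rate",
    "solve_swelling",
    "weight_ratio",
]

#: exponent of the reptation/disentanglement law
DISENTANGLEMENT_EXPONENT = 1.625


@dataclass(frozen=True)
class SwellingParams:
    """Material and process constants of the swelling-erosion model.

    Parameters
    ----------
    L0 : float
        Initial dry-film thickness, m.
    phi0, phig, phieq : float
        Solvent volume fraction in the dry film, at the glassy-rubbery
        threshold and at gel-solvent equilibrium; 0 <= phi0 < phig < phieq < 1.
    DGs : float
        Solvent diffusivity in the fully swollen gel, m²/s.
    beta_s : float
        Exponent of the concentration dependence of the solvent diffusivity
        (0 means constant Ds = DGs).
    C : float
        Erosion (disentanglement) constant, m/s.
    geometry : str
        ``symmetric`` (swelling test / USP II) or ``anchored`` (flow channel).
    rho_s, rho_p : float
        Solvent and polymer densities, kg/m³ (equal by default, in which case
        the weight ratio reduces to a thickness ratio).
    stefan_variant : str
        ``printed`` uses dS/dt = DGs dphi/dz - Rdis (which is exactly polymer
        conserving because the PDE flux carries the (1-phi) factor);
        ``scaled`` divides the influx term by (1 - phieq), the alternative
        kinematic convention.
    """

    L0: float
    phi0: float
    phig: float
    phieq: float
    DGs: float
    beta_s: float = 0.0
    C: float = 0.0
    geometry: str = "symmetric"
    rho_s: float = 1000.0
    rho_p: float = 1000.0
    stefan_variant: str = "printed"

    def __post_init__(self):
        if not (0.0 <= self.phi0 < self.phig < self.phieq < 1.0):
            raise ValueError("require 0 <= phi0 < phig < phieq < 1")
        if self.L0 <= 0 or self.DGs <= 0:
            raise ValueError("L0 and DGs must be positive")
        if self.C < 0 or self.beta_s < 0:
            raise ValueError("C and beta_s must be non-negative")
        if self.geometry not in ("symmetric", "anchored"):
            raise ValueError("geometry must be 'symmetric' or 'anchored'")
        if self.stefan_variant not in ("printed", "scaled"):
            raise ValueError("stefan_variant must be 'printed' or 'scaled'")

    @property
    def z_init(self) -> float:
        """Initial front position: L0/2 (symmetric) or L0 (anchored)."""
        return 0.5 * self.L0 if self.geometry == "symmetric" else self.L0

    @classmethod
    def from_config(cls, cfg: dict) -> "SwellingParams":
        """Build from a config mapping with unit-suffixed keys.

        Recognised keys: ``L0_um``, ``phi0``, ``phig``, ``phieq``,
        ``DGs_m2s``, ``C_um_s``, plus optional ``beta_s``, ``geometry``,
        ``rho_s``, ``rho_p``, ``stefan_variant`` and the plain-SI spellings
        ``L0``/``C``.
        """
        kw = {}
        if "L0_um" in cfg:
            kw["L0"] = float(cfg["L0_um"]) * 1e-6
        elif "L0" in cfg:
            kw["L0"] = float(cfg["L0"])
        else:
            raise KeyError("config must provide L0_um or L0")
        if "C_um_s" in cfg:
            kw["C"] = float(cfg["C_um_s"]) * 1e-6
        elif "C" in cfg:
            kw["C"] = float(cfg["C"])
        for k in ("phi0", "phig", "phieq"):
            kw[k] = float(cfg[k])
        kw["DGs"] = float(cfg["DGs_m2s"] if "DGs_m2s" in cfg else cfg["DGs"])
        for k in ("beta_s", "rho_s", "rho_p"):
            if k in cfg:
                kw[k] = float(cfg[k])
        for k in ("geometry", "stefan_variant"):
            if k in cfg:
                kw[k] = str(cfg[k])
        return cls(**kw)


def solvent_diffusivity(phi, params: SwellingParams):
    """Concentration-dependent solvent diffusivity Ds(phi), m²/s.

    Ds = DGs * exp[-beta_s (phi - phieq) / (phi0 - phieq)]; increases from
    DGs*exp(-beta_s) at phi0 to DGs at phieq, constant when beta_s = 0.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < params.phi0 - 1e-12) or np.any(phi > params.phieq + 1e-12):
        raise ValueError("phi outside [phi0, phieq]")
    out = params.DGs * np.exp(
        -params.beta_s * (phi - params.phieq) / (params.phi0 - params.phieq)
    )
    return float(out) if out.ndim == 0 else out


def disentanglement_rate(phi, C):
    """Erosion front speed Rdis = C (1 - phi)**1.625.

    Unit-agnostic in C (returns the units of C); phi must be below 1.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi >= 1.0) or np.any(phi < 0.0):
        raise ValueError("phi must lie in [0, 1)")
    if np.any(np.asarray(C) < 0):
        raise ValueError("C must be non-negative")
    out = C * (1.0 - phi) ** DISENTANGLEMENT_EXPONENT
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FrontState:
    """Snapshot of the moving-boundary solution at one time."""

    t: float
    R: float
    S: float
    phi_profile: np.ndarray  # sampled on the unit (Landau) grid over [R, S]
    dissolved: bool = False


class FrontMotion:
    """Interpolable front kinematics R(t), S(t) and their rates.

    Built from the swelling solver's own step points (dense where the fronts
    move fast); drug-transport solvers consume this one-way coupling.
    """

    def __init__(self, t, R, S, Rdot, Sdot, t_glassy=None, t_dissolved=None):
        self.t = np.asarray(t, float)
        self._R = np.asarray(R, float)
        self._S = np.asarray(S, float)
        self._Rdot = np.asarray(Rdot, float)
        self._Sdot = np.asarray(Sdot, float)
        self.t_glassy = t_glassy
        self.t_dissolved = t_dissolved

    @classmethod
    def from_arrays(cls, t, R, S, t_glassy=None, t_dissolved=None):
        t = np.asarray(t, float)
        R = np.asarray(R, float)
        S = np.asarray(S, float)
        return cls(t, R, S, np.gradient(R, t), np.gradient(S, t), t_glassy, t_dissolved)

    @classmethod
    def static(cls, R: float, S: float, t_end: float = np.inf):
        """Frozen fronts (e.g. a fully swollen, non-eroding slab)."""
        t = np.array([0.0, min(t_end, 1e12)])
        z = np.zeros(2)
        return cls(t, R + z, S + z, z, z, t_glassy=0.0, t_dissolved=None)

    def R_at(self, t):
        return np.interp(t, self.t, self._R)

    def S_at(self, t):
        return np.interp(t, self.t, self._S)

    def Rdot_at(self, t):
        if self.t_glassy is not None and np.ndim(t) == 0 and t >= self.t_glassy:
            return 0.0
        return np.interp(t, self.t, self._Rdot)

    def Sdot_at(self, t):
        return np.interp(t, self.t, self._Sdot)


@dataclass
class SwellingTrajectory:
    """Time evolution of the swelling-erosion moving-boundary problem.

    ``t``/``R``/``S``/``phi`` are sampled on the requested output grid; the
    ``dense_*`` arrays hold every accepted solver step (used for maxima,
    dissolution-time detection and coupling to drug solvers); ``tau`` is the
    dimensionless time t*DGs/L0².
    """

    params: SwellingParams
    t: np.ndarray
    R: np.ndarray
    S: np.ndarray
    phi: np.ndarray  # (len(t), n_nodes) on the unit grid
    xi: np.ndarray
    weight_ratio: np.ndarray
    tau: np.ndarray
    dense_t: np.ndarray
    dense_R: np.ndarray
    dense_S: np.ndarray
    dense_weight_ratio: np.ndarray
    dense_Rdot: np.ndarray
    dense_Sdot: np.ndarray
    t_glassy: float | None
    t_dissolved: float | None
    states: list = field(default_factory=list)

    @property
    def dissolved(self) -> bool:
        return self.t_dissolved is not None

    @property
    def dissolution_time(self) -> float | None:
        return self.t_dissolved

    @property
    def max_weight_ratio(self) -> float:
        return float(np.max(self.dense_weight_ratio))

    @property
    def fronts(self) -> FrontMotion:
        return FrontMotion(
            self.dense_t, self.dense_R, self.dense_S, self.dense_Rdot,
            self.dense_Sdot, self.t_glassy, self.t_dissolved,
        )

    def polymer_inventory(self) -> np.ndarray:
        """Column polymer content (1-phi) integrated over the film, m."""
        out = np.empty(len(self.t))
        for i in range(len(self.t)):
            h = self.S[i] - self.R[i]
            if h <= 0:
                out[i] = (1.0 - self.params.phi0) * self.R[i]
                continue
            gel = h * np.trapezoid(1.0 - self.phi[i], self.xi)
            out[i] = (1.0 - self.params.phi0) * self.R[i] + gel
        return out


def _weight_per_area(params: SwellingParams, R: float, S: float, phi: np.ndarray, xi: np.ndarray) -> float:
    """Film weight per unit area: glassy core at phi0 plus the gel column."""
    h = S - R
    rho_p, rho_s = params.rho_p, params.rho_s
    w = R * (rho_p * (1.0 - params.phi0) + rho_s * params.phi0)
    if h > 0:
        w += h * np.trapezoid(rho_p * (1.0 - phi) + rho_s * phi, xi)
    return w


def weight_ratio(traj: SwellingTrajectory, params: SwellingParams | None = None) -> np.ndarray:
    """Recompute W(t)/W0 from the stored profiles (W(0)/W0 = 1)."""
    p = params or traj.params
    w0 = p.z_init * (p.rho_p * (1.0 - p.phi0) + p.rho_s * p.phi0)
    out = np.empty(len(traj.t))
    for i in range(len(traj.t)):
        if traj.t[i] == 0.0:
            out[i] = 1.0
        elif traj.S[i] <= 0.0:
            out[i] = 0.0
        else:
            out[i] = _weight_per_area(p, traj.R[i], traj.S[i], traj.phi[i], traj.xi) / w0
    return out


class FrontCrossingError(RuntimeError):
    """Raised when the gel layer collapses (S meets R) before dissolution."""


def _seed_state(params: SwellingParams, seed_frac: float, xi: np.ndarray):
    """Thin-gel initial layer replacing the t = 0 contact discontinuity.

    The layer width is split between the two fronts in the ratio of their
    initial Stefan speeds (linear-profile estimate), so the seed is close to
    the short-time similarity shape.
    """
    p = params
    w = seed_frac * p.L0
    Dg = p.DGs * np.exp(-p.beta_s * (p.phig - p.phieq) / (p.phi0 - p.phieq))
    rate_R = Dg * (1.0 - p.phig) / (p.phig - p.phi0)
    rate_S = p.DGs
    wR = w * rate_R / (rate_R + rate_S)
    wS = w - wR
    R0 = p.z_init - wR
    S0 = p.z_init + wS
    phi0_profile = p.phig + (p.phieq - p.phig) * xi
    return R0, S0, phi0_profile


def solve_swelling(
    params: SwellingParams,
    t_grid: Sequence[float] | None = None,
    *,
    t_end: float | None = None,
    n_nodes: int = 61,
    seed_frac: float = 1e-3,
    dissolve_frac: float = 1e-3,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "LSODA",
) -> SwellingTrajectory:
    """Integrate the two-front Stefan problem and return the trajectory.

    Parameters
    ----------
    params : SwellingParams
    t_grid : array-like, optional
        Output times (must start at 0 when given).  Times past complete
        dissolution yield the dissolved state.
    t_end : float, optional
        Integration horizon; defaults to ``t_grid[-1]``.
    n_nodes : int
        Landau-grid resolution of the gel region.
    seed_frac : float
        Initial gel-layer width as a fraction of L0 (regularisation).
    dissolve_frac : float
        Dissolution is declared when S drops below ``dissolve_frac * L0``;
        the (tiny) residual erosion time S/Rdis is added to the reported
        dissolution time.
    """
    p = params
    if t_grid is not None:
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid[0] != 0.0:
            raise ValueError("t_grid must start at 0")
        if np.any(np.diff(t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        if t_end is None:
            t_end = float(t_grid[-1])
    if t_end is None:
        raise ValueError("provide t_grid or t_end")

    N = int(n_nodes)
    if N < 7:
        raise ValueError("n_nodes must be at least 7")
    xi = np.linspace(0.0, 1.0, N)
    dxi = xi[1] - xi[0]
    Rdis_eq = disentanglement_rate(p.phieq, p.C)
    phi_lo, phi_hi = p.phi0, p.phieq

    def Deff(phi):
        phi = np.clip(phi, phi_lo, phi_hi)
        Ds = p.DGs * np.exp(-p.beta_s * (phi - p.phieq) / (p.phi0 - p.phieq))
        return Ds * (1.0 - phi)

    Dg_edge = float(Deff(np.array(p.phig)))  # Ds(phig)*(1-phig)

    def front_rates(phi_full, h):
        gradR = (-3.0 * phi_full[0] + 4.0 * phi_full[1] - phi_full[2]) / (2.0 * dxi)
        gradS = (3.0 * phi_full[-1] - 4.0 * phi_full[-2] + phi_full[-3]) / (2.0 * dxi)
        Rdot = -Dg_edge * gradR / ((p.phig - p.phi0) * h)
        influx = p.DGs * gradS / h
        if p.stefan_variant == "scaled":
            influx /= 1.0 - p.phieq
        Sdot = influx - Rdis_eq
        return Rdot, Sdot

    def rhs_core(phi_full, h, Rdot, Sdot):
        flux = 0.5 * (Deff(phi_full[:-1]) + Deff(phi_full[1:])) * np.diff(phi_full) / dxi
        div = (flux[1:] - flux[:-1]) / dxi
        v = Rdot * (1.0 - xi[1:-1]) + Sdot * xi[1:-1]
        grad_c = (phi_full[2:] - phi_full[:-2]) / (2.0 * dxi)
        return div / h**2 + v * grad_c / h, flux

    def rhs1(t, y):
        phi_full = np.empty(N)
        phi_full[0], phi_full[-1] = p.phig, p.phieq
        phi_full[1:-1] = y[:-2]
        R, S = y[-2], y[-1]
        h = max(S - R, 1e-6 * p.L0)
        Rdot, Sdot = front_rates(phi_full, h)
        dphi, _ = rhs_core(phi_full, h, Rdot, Sdot)
        return np.concatenate([dphi, [Rdot, Sdot]])

    def rhs2(t, y):
        phi_full = np.empty(N)
        phi_full[-1] = p.phieq
        phi_full[:-1] = y[:-1]
        S = y[-1]
        h = max(S, 1e-6 * p.L0)
        gradS = (3.0 * phi_full[-1] - 4.0 * phi_full[-2] + phi_full[-3]) / (2.0 * dxi)
        influx = p.DGs * gradS / h
        if p.stefan_variant == "scaled":
            influx /= 1.0 - p.phieq
        Sdot = influx - Rdis_eq
        dphi, flux = rhs_core(phi_full, h, 0.0, Sdot)
        dphi0 = 2.0 * flux[0] / (dxi * h**2)  # half-cell, no-flux at z=0
        dy = np.empty(N)
        dy[0] = dphi0
        dy[1:-1] = dphi
        dy[-1] = Sdot
        return dy

    R0, S0, phi_seed = _seed_state(p, seed_frac, xi)
    y0 = np.concatenate([phi_seed[1:-1], [R0, S0]])

    def ev_glassy(t, y):
        return y[-2]

    ev_glassy.terminal = True
    ev_glassy.direction = -1.0

    def ev_collapse(t, y):
        return (y[-1] - y[-2]) - 1e-5 * p.L0

    ev_collapse.terminal = True
    ev_collapse.direction = -1.0

    sol1 = solve_ivp(
        rhs1, (0.0, t_end), y0, method=method, events=[ev_glassy, ev_collapse],
        dense_output=True, rtol=rtol, atol=atol,
    )
    if not sol1.success:
        raise RuntimeError(f"swelling integration failed in the two-front phase: {sol1.message}")
    if len(sol1.t_events[1]):
        te = sol1.t_events[1][0]
        ye = sol1.y_events[1][0]
        raise FrontCrossingError(
            f"gel layer collapsed (S -> R) at t = {te:.4g} s with R = {ye[-2]:.4g} m, "
            f"S = {ye[-1]:.4g} m: erosion outruns swelling for these parameters"
        )

    t_glassy = None
    sol2 = None
    t_dissolved = None
    if len(sol1.t_events[0]):
        t_glassy = float(sol1.t_events[0][0])
        y_ev = sol1.y_events[0][0]
        y0b = np.concatenate([[p.phig], y_ev[:-2], [y_ev[-1]]])

        s_min = dissolve_frac * p.L0

        def ev_dissolved(t, y):
            return y[-1] - s_min

        ev_dissolved.terminal = True
        ev_dissolved.direction = -1.0

        if t_glassy < t_end:
            sol2 = solve_ivp(
                rhs2, (t_glassy, t_end), y0b, method=method, events=[ev_dissolved],
                dense_output=True, rtol=rtol, atol=atol,
            )
            if not sol2.success:
                raise RuntimeError(f"swelling integration failed after glassy-core exhaustion: {sol2.message}")
            if len(sol2.t_events[0]):
                t_hit = float(sol2.t_events[0][0])
                s_hit = float(sol2.y_events[0][0][-1])
                tail = s_hit / Rdis_eq if Rdis_eq > 0 else 0.0
                t_dissolved = t_hit + tail

    # --- assemble dense (solver-step) arrays -------------------------------
    def unpack1(y):
        phi_full = np.empty(N)
        phi_full[0], phi_full[-1] = p.phig, p.phieq
        phi_full[1:-1] = y[:-2]
        return phi_full, y[-2], y[-1]

    def unpack2(y):
        phi_full = np.empty(N)
        phi_full[-1] = p.phieq
        phi_full[:-1] = y[:-1]
        return phi_full, 0.0, y[-1]

    w0 = p.z_init * (p.rho_p * (1.0 - p.phi0) + p.rho_s * p.phi0)
    dt_list, dR, dS, dW, dRd, dSd = [], [], [], [], [], []

    def collect(t, phi_full, R, S, phase):
        h = max(S - R, 1e-12)
        if phase == 1:
            Rdot, Sdot = front_rates(phi_full, h)
        else:
            gradS = (3.0 * phi_full[-1] - 4.0 * phi_full[-2] + phi_full[-3]) / (2.0 * dxi)
            influx = p.DGs * gradS / h
            if p.stefan_variant == "scaled":
                influx /= 1.0 - p.phieq
            Rdot, Sdot = 0.0, influx - Rdis_eq
        dt_list.append(t)
        dR.append(R)
        dS.append(S)
        dW.append(_weight_per_area(p, R, S, phi_full, xi) / w0)
        dRd.append(Rdot)
        dSd.append(Sdot)

    for k, t in enumerate(sol1.t):
        phi_full, R, S = unpack1(sol1.y[:, k])
        collect(t, phi_full, R, S, 1)
    if sol2 is not None:
        for k, t in enumerate(sol2.t):
            if k == 0 and len(dt_list) and t <= dt_list[-1]:
                continue
            phi_full, R, S = unpack2(sol2.y[:, k])
            collect(t, phi_full, R, S, 2)
    dense_t = np.asarray(dt_list)
    dense_R = np.asarray(dR)
    dense_S = np.asarray(dS)
    dense_W = np.asarray(dW)
    dense_Rdot = np.asarray(dRd)
    dense_Sdot = np.asarray(dSd)

    # --- sample on the requested grid --------------------------------------
    if t_grid is None:
        t_out = dense_t
    else:
        t_out = t_grid
    nt = len(t_out)
    R_out = np.empty(nt)
    S_out = np.empty(nt)
    phi_out = np.empty((nt, N))
    W_out = np.empty(nt)
    states = []
    t1_last = sol1.t[-1]
    for i, t in enumerate(t_out):
        if t == 0.0:
            R_out[i] = S_out[i] = p.z_init
            phi_out[i] = phi_seed
            W_out[i] = 1.0
            states.append(FrontState(0.0, p.z_init, p.z_init, phi_seed.copy()))
            continue
        if t_dissolved is not None and t >= t_dissolved:
            R_out[i], S_out[i] = 0.0, 0.0
            phi_out[i] = np.full(N, p.phieq)
            W_out[i] = 0.0
            states.append(FrontState(float(t), 0.0, 0.0, phi_out[i].copy(), dissolved=True))
            continue
        if t <= t1_last:
            phi_full, R, S = unpack1(sol1.sol(t))
        elif sol2 is not None and t <= sol2.t[-1]:
            phi_full, R, S = unpack2(sol2.sol(t))
        else:
            # past the last integrated point (e.g. just inside the dissolution tail)
            phi_full, R, S = phi_out[i - 1], R_out[i - 1], S_out[i - 1]
        R_out[i], S_out[i] = R, S
        phi_out[i] = phi_full
        W_out[i] = _weight_per_area(p, R, S, phi_full, xi) / w0
        states.append(FrontState(float(t), float(R), float(S), phi_full.copy()))

    return SwellingTrajectory(
        params=p,
        t=np.asarray(t_out, float),
        R=R_out,
        S=S_out,
        phi=phi_out,
        xi=xi,
        weight_ratio=W_out,
        tau=np.asarray(t_out, float) * p.DGs / p.L0**2,
        dense_t=dense_t,
        dense_R=dense_R,
        dense_S=dense_S,
        dense_weight_ratio=dense_W,
        dense_Rdot=dense_Rdot,
        dense_Sdot=dense_Sdot,
        t_glassy=t_glassy,
        t_dissolved=t_dissolved,
        states=states,
    )
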