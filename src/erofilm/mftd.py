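"""2D drug release in the millifluidic flow-through device (MFTD).

A thin film lies on the bottom wall of a shallow rectangular channel
(Lz × Ly × Lx = 2 × 9 × 30 mm by default) and swells/erodes under a laminar
tangential solvent flow.  The model couples

* the 1D swelling-erosion front kinematics (anchored geometry), solved
  independently and supplied as R(t), S(t);
* drug diffusion in the gel layer R < z < S (diffusivity ``DG``) with a
  Stefan condition at the glassy front (the glassy core below R carries the
  drug at the loading concentration c0 and hands it to the gel as the front
  recedes);
* convection-diffusion in the shrinking channel lumen S < z < Lz
  (diffusivity ``D0``) with a lubrication velocity profile that rides on the
  moving gel surface and conserves the flow rate Q at every instant:

      vx(z, t) = 6 Q (z - S)(Lz - z) / (Ly (Lz - S)^3);

* concentration and flux continuity at the gel-solvent interface, zero inlet
  concentration, Danckwerts (zero-gradient) outflow and impermeable walls.

Numerics.  Both layers are mapped onto fixed unit intervals (front-fixing)
and discretised as moving-mesh finite volumes in conservative form,

    d/dt (h c) = d/ds [ (D/h) dc/ds + v(s) c ],    v = Rdot (1-s) + Sdot s,

so the kinematic terms that exchange drug across the moving interface (gel
erosion sheds drug to the fluid; a swelling surface swallows the fluid
boundary layer) appear as a single shared interface flux and the global
balance glassy + gel + fluid + outflow telescopes exactly.  Grids are
stretched geometrically towards the interface, where concentration boundary
layers of thickness ~D/|dS/dt| (microns during early swelling) live.  All
z-direction terms are advanced implicitly as one tridiagonal solve per
column spanning gel and fluid; axial convection (upwind) and axial
diffusion are explicit, so the time step is limited only by the axial CFL
plus an accuracy cap on front displacement per step.

The differential release curve is F(t) = Ly * int vx cF(Lx, z) dz (the
outlet mixing-cup flux), cs = F/Q, and Mt the time integral of F.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .swelling import SwellingParams, solve_swelling

__all__ = ["ChannelGeometry", "MFTDState", "MFTDRelease", "velocity_profile",
           "solve_mftd_release", "outlet_release"]


@dataclass(frozen=True)
class ChannelGeometry:
    """Flow-cell dimensions and volumetric flow rate (SI).

    ``Lx`` along the flow, ``Ly`` across (film width), ``Lz`` the channel
    height (swelling direction).  Use :meth:`with_flow_mL_min` for the
    laboratory unit of Q.
    """

    Lx: float = 30e-3
    Ly: float = 9e-3
    Lz: float = 2e-3
    Q: float = 2.0 * 1e-6 / 60.0  # m³/s (2 mL/min)

    def __post_init__(self):
        if min(self.Lx, self.Ly, self.Lz, self.Q) <= 0:
            raise ValueError("channel dimensions and flow rate must be positive")

    @classmethod
    def with_flow_mL_min(cls, Q_mL_min: float, **kw) -> "ChannelGeometry":
        return cls(Q=Q_mL_min * 1e-6 / 60.0, **kw)


def velocity_profile(z, S: float, geometry: ChannelGeometry):
    """Lubrication axial velocity above the gel surface, m/s.

    Vanishes at z = S and z = Lz (no slip) and integrates to Q/Ly across the
    lumen at every instant.
    """
    g = geometry
    if S >= g.Lz:
        raise ValueError("gel surface has reached the channel top: channel blocked")
    z = np.asarray(z, dtype=float)
    if np.any(z < S - 1e-15) or np.any(z > g.Lz + 1e-15):
        raise ValueError("z outside the fluid lumen [S, Lz]")
    out = 6.0 * g.Q * (z - S) * (g.Lz - z) / (g.Ly * (g.Lz - S) ** 3)
    return float(out) if out.ndim == 0 else out


@dataclass
class MFTDState:
    """Field snapshot (optional output of the solver)."""

    t: float
    R: float
    S: float
    cG: np.ndarray  # (Nx, Ng) gel cell averages (cells clustered at surface)
    cF: np.ndarray  # (Nx, Nf) fluid cell averages (cells clustered at surface)
    F: float
    Mt: float


@dataclass
class MFTDRelease:
    """Sampled release series plus mass-balance diagnostics.

    ``cs = F/Q`` is the mixing-cup outlet concentration; ``mass_*`` are the
    drug inventories (kg) entering the global balance check
    ``mass_glassy + mass_gel + mass_fluid + mass_out ≈ M0``.  ``s_fluid``
    holds the fluid cell-centre coordinates on the unit lumen grid
    (clustered at the gel surface).
    """

    t: np.ndarray
    F: np.ndarray
    cs: np.ndarray
    Mt: np.ndarray
    S: np.ndarray
    R: np.ndarray
    mass_gel: np.ndarray
    mass_glassy: np.ndarray
    mass_fluid: np.ndarray
    mass_out: np.ndarray
    M0: float
    geometry: ChannelGeometry
    outlet_profiles: np.ndarray  # (n_samples, Nf) outlet-column fluid conc.
    s_fluid: np.ndarray
    s_widths: np.ndarray
    tau: np.ndarray
    states: list = field(default_factory=list)

    @property
    def balance_error(self) -> np.ndarray:
        tot = self.mass_gel + self.mass_glassy + self.mass_fluid + self.mass_out
        return (tot - self.M0) / self.M0


def _stretched_faces(n_cells: int, beta: float) -> np.ndarray:
    """n_cells+1 unit-interval cell faces clustered at 0."""
    u = np.linspace(0.0, 1.0, n_cells + 1)
    return (np.exp(beta * u) - 1.0) / (np.exp(beta) - 1.0)


def solve_mftd_release(
    swelling: SwellingParams,
    geometry: ChannelGeometry,
    DG: float,
    D0: float,
    c0: float,
    t_end: float,
    *,
    Nx: int = 32,
    Ng: int = 24,
    Nf: int = 32,
    stretch: float = 4.5,
    cfl: float = 0.4,
    front_frac: float = 0.04,
    sample_dt: float = 2.0,
    keep_fields: bool = False,
    swelling_kwargs: dict | None = None,
) -> MFTDRelease:
    """March the coupled gel/channel drug transport to ``t_end``.

    ``swelling`` must use the anchored geometry (film on the bottom wall).
    The swelling problem is solved first on its own grid; drug transport
    sees only the interpolated front motion.  ``front_frac`` caps the front
    displacement per step at that fraction of the gel thickness.
    """
    if swelling.geometry != "anchored":
        raise ValueError("MFTD release requires anchored swelling geometry")
    if min(DG, D0) <= 0 or c0 < 0 or t_end <= 0:
        raise ValueError("DG, D0 must be positive; c0 non-negative; t_end positive")
    g = geometry
    if swelling.L0 >= g.Lz:
        raise ValueError("film thicker than the channel")

    traj = solve_swelling(swelling, t_end=t_end, **(swelling_kwargs or {}))
    if np.max(traj.dense_S) >= g.Lz:
        raise ValueError("swollen film reaches the channel top: channel blocked")
    fronts = traj.fronts
    t_diss = fronts.t_dissolved

    dx = g.Lx / Nx
    # gel cells: face 0 at the glassy front, faces clustered at the surface
    gf = 1.0 - _stretched_faces(Ng, stretch)[::-1]
    dsg = np.diff(gf)                    # cell widths
    sgc = 0.5 * (gf[:-1] + gf[1:])       # cell centres
    dcg = np.diff(sgc)                   # centre distances (internal faces)
    # fluid cells: face 0 at the surface, clustered there
    ff = _stretched_faces(Nf, stretch)
    dsf = np.diff(ff)
    sfc = 0.5 * (ff[:-1] + ff[1:])
    dcf = np.diff(sfc)
    vx_unit = 6.0 * sfc * (1.0 - sfc)    # × Q/(Ly·hf) at fluid cell centres

    hg_min = 0.05 * swelling.L0
    hg_dense = fronts._S - fronts._R
    k0 = int(np.argmax(hg_dense >= hg_min))
    t0 = float(fronts.t[k0]) if hg_dense[k0] >= hg_min else 0.0
    R0 = float(fronts.R_at(t0))
    S0 = float(fronts.S_at(t0))
    hg0 = S0 - R0

    # the seed gel holds exactly the drug of the glassy column converted so far
    cG = np.full((Nx, Ng), c0 * (swelling.L0 - R0) / hg0)
    cF = np.zeros((Nx, Nf))
    gel_active = True
    M0 = g.Ly * g.Lx * swelling.L0 * c0
    Mout = 0.0
    t = t0
    M = Ng + Nf  # coupled column size

    samples = {k: [] for k in ("t", "F", "cs", "Mt", "S", "R", "mg", "mgl", "mf", "prof")}
    states: list[MFTDState] = []
    next_sample = t0

    def outlet_flux(hf):
        vx = vx_unit * g.Q / (g.Ly * hf)
        return g.Ly * hf * float(np.dot(dsf, vx * cF[-1]))

    def record(tr, R, S, F):
        hg = max(S - R, 0.0)
        hf = g.Lz - S
        mg = g.Ly * dx * hg * float(np.sum(cG @ dsg)) if gel_active else 0.0
        mgl = g.Ly * g.Lx * R * c0
        mf = g.Ly * dx * hf * float(np.sum(cF @ dsf))
        for key, val in (("t", tr), ("F", F), ("cs", F / g.Q), ("Mt", Mout),
                         ("S", S), ("R", R), ("mg", mg), ("mgl", mgl), ("mf", mf)):
            samples[key].append(val)
        samples["prof"].append(cF[-1].copy())
        if keep_fields:
            states.append(MFTDState(tr, R, S, cG.copy(), cF.copy(), F, Mout))

    while t < t_end - 1e-12:
        if gel_active and t_diss is not None and t >= t_diss:
            # film fully dissolved: hand residual gel drug to the fluid and
            # regrid the lumen to the full channel (conservative rebinning
            # via the cumulative-mass profile)
            S_old = float(fronts.S_at(min(t, t_diss)))
            hg = max(S_old - float(fronts.R_at(min(t, t_diss))), 0.0)
            m_res = hg * (cG @ dsg)  # column inventory per unit area, kg/m²
            zf_old = S_old + ff * (g.Lz - S_old)
            zf_new = ff * g.Lz
            cF_new = np.empty_like(cF)
            for i in range(Nx):
                cum = np.concatenate([[0.0], np.cumsum(cF[i] * np.diff(zf_old))])
                cum_new = np.interp(zf_new, zf_old, cum)
                cF_new[i] = np.diff(cum_new) / np.diff(zf_new)
            cF = cF_new
            cF[:, 0] += m_res / (dsf[0] * g.Lz)
            gel_active = False

        if gel_active:
            R = float(fronts.R_at(t))
            S = float(fronts.S_at(t))
        else:
            R = S = 0.0
        hg_old = max(S - R, 1e-12)
        hf_old = g.Lz - S
        vmax = 1.5 * g.Q / (g.Ly * hf_old)

        cand = [cfl * dx / vmax, cfl * dx**2 / (2.0 * max(D0, DG)), 0.5 * sample_dt]
        if gel_active:
            vfront = max(abs(float(fronts.Rdot_at(t))), abs(float(fronts.Sdot_at(t))), 1e-30)
            cand.append(front_frac * hg_old / vfront)
        dt = min(cand)
        dt = min(dt, t_end - t)
        if next_sample > t:
            dt = min(dt, next_sample - t)
        if t_diss is not None and gel_active and t < t_diss:
            dt = min(dt, t_diss - t)
        dt = max(dt, 1e-9)

        tn = t + dt
        if gel_active:
            Rn = float(fronts.R_at(tn))
            Sn = float(fronts.S_at(tn))
            Rdot = (Rn - R) / dt
            Sdot = (Sn - S) / dt
            hg_new = max(Sn - Rn, 1e-12)
        else:
            Rn = Sn = Rdot = Sdot = 0.0
            hg_new = hg_old
        hf_new = g.Lz - Sn

        # ---- explicit axial terms (mass rates built on the old geometry) ----
        F_now = outlet_flux(hf_old)
        if gel_active:
            gx = np.pad(cG, ((1, 1), (0, 0)), mode="edge")
            xg = DG * (gx[2:] - 2.0 * gx[1:-1] + gx[:-2]) / dx**2
        vx = vx_unit * g.Q / (g.Ly * hf_old)
        upw = np.empty_like(cF)
        upw[0] = vx * cF[0] / dx  # zero inlet concentration
        upw[1:] = vx * (cF[1:] - cF[:-1]) / dx
        fxp = np.pad(cF, ((1, 1), (0, 0)), mode="edge")
        fxp[0] = 0.0
        xf = -upw + D0 * (fxp[2:] - 2.0 * fxp[1:-1] + fxp[:-2]) / dx**2

        # ---- implicit z solve on the coupled gel+fluid column -------------
        ab = np.zeros((3, M))
        rhs = np.empty((M, Nx))
        if gel_active:
            Vg_old = hg_old * dsg
            Vg_new = hg_new * dsg
            rhs[:Ng] = (cG * Vg_old + dt * xg * Vg_old).T
            ab[1, :Ng] = Vg_new
            # internal gel faces
            alpha = DG / (hg_new * dcg)
            vfc = Rdot * (1.0 - gf[1:-1]) + Sdot * gf[1:-1]
            vp = np.maximum(vfc, 0.0)
            vm = np.minimum(vfc, 0.0)
            # face j+1/2 seen from cell j (flux +): and from cell j+1 (flux -)
            ab[1, :Ng - 1] += dt * (alpha - vm)
            ab[0, 1:Ng] += -dt * (alpha + vp)
            ab[1, 1:Ng] += dt * (alpha + vp)
            ab[2, :Ng - 1] += -dt * (alpha - vm)
            # glassy face: flux = Rdot*c0 (exact handover from the core)
            rhs[0] += -dt * Rdot * c0
        else:
            ab[1, :Ng] = 1.0
            rhs[:Ng] = 0.0

        Vf_old = hf_old * dsf
        Vf_new = hf_new * dsf
        rhs[Ng:] = (cF * Vf_old + dt * xf * Vf_old).T
        ab[1, Ng:] = Vf_new
        alphaf = D0 / (hf_new * dcf)
        vff = Sdot * (1.0 - ff[1:-1])
        vpf = np.maximum(vff, 0.0)
        vmf = np.minimum(vff, 0.0)
        ab[1, Ng:M - 1] += dt * (alphaf - vmf)
        ab[0, Ng + 1:] += -dt * (alphaf + vpf)
        ab[1, Ng + 1:] += dt * (alphaf + vpf)
        ab[2, Ng:M - 1] += -dt * (alphaf - vmf)
        # top wall: zero flux (mesh velocity vanishes there too)

        if gel_active:
            # shared interface flux: diffusion in series + upwinded capture
            aG = DG / (hg_new * dsg[-1] / 2.0)
            aF = D0 / (hf_new * dsf[0] / 2.0)
            kappa = aG * aF / (aG + aF)
            sp = max(Sdot, 0.0)
            sm = min(Sdot, 0.0)
            # gel cell Ng-1: -dt*Phi_int;   fluid cell 0: +dt*Phi_int
            ab[1, Ng - 1] += dt * (kappa - sm)
            ab[0, Ng] += -dt * (kappa + sp)
            ab[1, Ng] += dt * (kappa + sp)
            ab[2, Ng - 1] += -dt * (kappa - sm)

        sol = solve_banded((1, 1), ab, rhs)
        if gel_active:
            cG = sol[:Ng].T.copy()
        cF = sol[Ng:].T.copy()

        Mout += dt * F_now
        t = tn

        if t >= next_sample - 1e-9:
            Rn_s = float(fronts.R_at(t)) if gel_active else 0.0
            Sn_s = float(fronts.S_at(t)) if gel_active else 0.0
            record(t, Rn_s, Sn_s, outlet_flux(g.Lz - Sn_s))
            next_sample = t + sample_dt

    return MFTDRelease(
        t=np.asarray(samples["t"]), F=np.asarray(samples["F"]),
        cs=np.asarray(samples["cs"]), Mt=np.asarray(samples["Mt"]),
        S=np.asarray(samples["S"]), R=np.asarray(samples["R"]),
        mass_gel=np.asarray(samples["mg"]), mass_glassy=np.asarray(samples["mgl"]),
        mass_fluid=np.asarray(samples["mf"]), mass_out=np.asarray(samples["Mt"]),
        M0=M0, geometry=g,
        outlet_profiles=np.asarray(samples["prof"]), s_fluid=sfc, s_widths=dsf,
        tau=np.asarray(samples["t"]) * swelling.DGs / swelling.L0**2,
        states=states,
    )


def outlet_release(release: MFTDRelease):
    """Differential and integral release curves from the stored outlet
    profiles: F(t) = Ly * int vx cF(Lx, z) dz, cs = F/Q, Mt by trapezoid.

    Returns ``(t, F, cs, Mt)``.
    """
    g = release.geometry
    s = release.s_fluid
    w = release.s_widths
    F = np.empty(len(release.t))
    for k, (S, prof) in enumerate(zip(release.S, release.outlet_profiles)):
        hf = g.Lz - S
        vx = 6.0 * g.Q * s * (1.0 - s) / (g.Ly * hf)
        F[k] = g.Ly * hf * float(np.dot(w, vx * prof))
    cs = F / g.Q
    Mt = np.concatenate([[0.0], np.cumsum(0.5 * (F[1:] + F[:-1]) * np.diff(release.t))])
    Mt += release.Mt[0]
    return release.t, F, cs, Mt
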