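"""Drug transport models for the vertical Franz diffusion cell.

Model hierarchy
---------------
* **Model I** — uniform donor, perfect-sink receptor: closed-form release.
* **Model IIa/IIb/IIc** — 1D diffusion through donor and membrane; receptor
  treated as perfectly mixed: sink (IIa), finite volume (IIb), finite volume
  with withdrawal/replacement events (IIc).
* **Model III** — imperfect mixing: the receptor is resolved as a 1D chain of
  three sub-domains (stirred cylindrical body, truncated-cone transition at
  the sampling port, quiescent lateral arm) with a position-dependent drug
  diffusivity that decays exponentially from the stirred value ``mix_factor *
  D0`` to the molecular value ``D0``.  The withdrawal concentration is the
  average over the truncated cone, which the syringe empties (and fresh
  solvent refills) at every sampling instant.

All compartments are discretised as a conservative finite-volume chain with
position-dependent cross-section area; fluxes use two-half-cell resistances,
so concentration and mass-flux continuity at every internal boundary hold by
construction.  The linear ODE system is integrated with a stiff solver
between withdrawal events.

Note on the mixing-decay constant: the transition between the stirred body
and the quiescent cone must be sharp on the scale of the cone (decay length
of order microns); a smooth decay over the whole cone would make the cone
effectively stirred and destroy the imperfect-mixing ordering cp < c̄cil that
the model exists to capture.  Default ``beta_D = 5e5`` 1/m.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import csc_matrix

__all__ = [
    "FranzGeometry",
    "DiffusivitySet",
    "WithdrawalSchedule",
    "FranzRun",
    "donor_from_loading",
    "model_I_mt",
    "solve_model_II",
    "solve_model_III",
    "integral_release_estimators",
]


@dataclass(frozen=True)
class FranzGeometry:
    """Franz-cell compartment description (SI units).

    The receptor chamber splits into a stirred cylindrical body (volume
    ``Vcil``), a truncated-cone transition at the sampling port (``Vtc``) and
    a quiescent lateral arm (``Varm``).  Only volumes are specified by the
    apparatus; the 1D chain uses the cylinder area ``A_cil``, the arm area
    ``A_arm`` and lengths derived from the volumes (the cone tapers linearly
    between the two areas).
    """

    A: float = 1e-4              # donor/membrane cross-section, m²
    delta_m: float = 45e-6       # membrane thickness, m
    delta_d: float = 1e-3        # donor liquid/gel thickness, m
    Vcil: float = 7.1e-6         # m³
    Vtc: float = 0.25e-6         # m³
    Varm: float = 0.55e-6        # m³
    Vres: float = 7.9e-6         # m³
    A_cil: float = 1.77e-4       # m²
    A_arm: float = 0.28e-4       # m²
    beta_D: float = 5e5          # mixing-decay constant, 1/m
    mix_factor: float = 1e6      # Dcil / D0, admissible 1e5..1e7

    def __post_init__(self):
        for name in ("A", "delta_m", "delta_d", "Vcil", "Vtc", "Varm", "Vres",
                     "A_cil", "A_arm", "beta_D", "mix_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.Vcil + self.Vtc + self.Varm - self.Vres) > 0.05 * self.Vres:
            raise ValueError("sub-domain volumes must sum to Vres within 5%")

    @property
    def L_cil(self) -> float:
        return self.Vcil / self.A_cil

    @property
    def L_tc(self) -> float:
        # linear area taper A_cil -> A_arm holding the stated cone volume
        return 2.0 * self.Vtc / (self.A_cil + self.A_arm)

    @property
    def L_arm(self) -> float:
        return self.Varm / self.A_arm


@dataclass(frozen=True)
class DiffusivitySet:
    """Drug diffusivities: donor (``Dd``), membrane (``Dm``), receptor
    quiescent solution (``D0``), all m²/s.  ``Dd`` is the solution value for
    blank runs and the swollen-gel value for film runs."""

    Dd: float
    Dm: float
    D0: float

    def __post_init__(self):
        if min(self.Dd, self.Dm, self.D0) <= 0:
            raise ValueError("diffusivities must be positive")
        if self.Dm > self.D0 * (1 + 1e-12):
            raise ValueError("membrane diffusivity must not exceed D0")


@dataclass(frozen=True)
class WithdrawalSchedule:
    """Sampling instants and withdrawal volume.

    ``Vp = None`` means "equal to the cone volume Vtc" (the modelling
    assumption that lets a withdrawal be represented as emptying the cone).
    """

    times: np.ndarray
    Vp: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("schedule needs at least one withdrawal time")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("withdrawal times must be positive and strictly increasing")
        object.__setattr__(self, "times", t)
        if self.Vp is not None and self.Vp <= 0:
            raise ValueError("Vp must be positive")


@dataclass
class FranzRun:
    """Outcome of a Franz-cell simulation.

    ``cp`` are withdrawal concentrations (pre-withdrawal), ``Mts`` the
    perfect-mixing integral-release estimator built from them, ``Mt`` the
    model's mass accounting (receptor content + withdrawn), and the ``cbar_*``
    arrays the sub-domain average concentrations at the sampling instants
    (Model III; for Models II they all equal the receptor concentration).
    """

    model: str
    M0: float
    t_w: np.ndarray
    cp: np.ndarray
    Mt_w: np.ndarray
    Mts: np.ndarray
    cbar_cil: np.ndarray
    cbar_tc: np.ndarray
    cbar_arm: np.ndarray
    t: np.ndarray
    Mt: np.ndarray
    mass_total: np.ndarray
    withdrawn: np.ndarray
    meta: dict = field(default_factory=dict)


def donor_from_loading(volume: float, concentration: float, A: float) -> tuple[float, float]:
    """Donor load M0 (kg) and liquid thickness delta_d (m) from the pipetted
    volume (m³), its concentration (kg/m³) and the donor cross-section (m²)."""
    if volume <= 0 or concentration < 0 or A <= 0:
        raise ValueError("volume and area must be positive, concentration non-negative")
    return volume * concentration, volume / A


def model_I_mt(t, M0: float, Dm: float, A: float, delta_m: float, Vd: float):
    """Closed-form release of the uniform-donor, perfect-sink model:
    Mt = M0 (1 - exp(-Dm A t / (delta_m Vd)))."""
    for name, v in (("M0", M0), ("Dm", Dm), ("A", A), ("delta_m", delta_m), ("Vd", Vd)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    t = np.asarray(t, dtype=float)
    out = M0 * (1.0 - np.exp(-Dm * A * t / (delta_m * Vd)))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# finite-volume chain machinery
# ---------------------------------------------------------------------------

class _Chain:
    """Conservative FV chain of 1D segments with varying area and D(s)."""

    def __init__(self, segments):
        centers, widths, areas, Ds, labels = [], [], [], [], []
        seg_edge_areas = []  # (area at segment start, area at segment end)
        for seg in segments:
            n = seg["n"]
            L = seg["length"]
            ds = L / n
            s_local = (np.arange(n) + 0.5) * ds
            area = seg["area"](s_local) if callable(seg["area"]) else np.full(n, seg["area"])
            D = seg["D"](s_local) if callable(seg["D"]) else np.full(n, seg["D"])
            centers.append(s_local)
            widths.append(np.full(n, ds))
            areas.append(area)
            Ds.append(D)
            labels += [seg["name"]] * n
            a0 = seg["area"](np.array([0.0]))[0] if callable(seg["area"]) else seg["area"]
            a1 = seg["area"](np.array([L]))[0] if callable(seg["area"]) else seg["area"]
            seg_edge_areas.append((a0, a1))
        self.widths = np.concatenate(widths)
        self.areas = np.concatenate(areas)
        self.D = np.concatenate(Ds)
        self.labels = np.asarray(labels)
        self.V = self.areas * self.widths
        self.n = len(self.V)
        # internal faces
        Aface = 0.5 * (self.areas[:-1] + self.areas[1:])
        # at segment junctions the connecting opening is the smaller port
        idx = 0
        for k in range(len(segments) - 1):
            idx += segments[k]["n"]
            Aface[idx - 1] = min(seg_edge_areas[k][1], seg_edge_areas[k + 1][0])
        half = 0.5 * self.widths
        resist = half[:-1] / self.D[:-1] + half[1:] / self.D[1:]
        self.G = Aface / resist  # conductance: flux = G * (c_i - c_{i+1}), kg/s per kg/m³

    def mass(self, c):
        return float(np.dot(self.V, c))

    def matrix(self, end_conductance: float = 0.0):
        """dC/dt = M C with optional Dirichlet-0 conductance at the far end."""
        n = self.n
        M = np.zeros((n, n))
        for i in range(n - 1):
            g = self.G[i]
            M[i, i] -= g / self.V[i]
            M[i, i + 1] += g / self.V[i]
            M[i + 1, i + 1] -= g / self.V[i + 1]
            M[i + 1, i] += g / self.V[i + 1]
        if end_conductance > 0:
            M[n - 1, n - 1] -= end_conductance / self.V[n - 1]
        return M


def _integrate_linear(Mmat, c0, t0, t1, t_eval=None, rtol=1e-7, atol=None):
    sp = csc_matrix(Mmat)
    if atol is None:
        atol = 1e-12 * max(1.0, float(np.max(np.abs(c0))) or 1.0)

    def rhs(t, y):
        return sp @ y

    sol = solve_ivp(rhs, (t0, t1), c0, method="BDF", jac=lambda t, y: sp,
                    t_eval=t_eval, rtol=rtol, atol=atol, dense_output=False)
    if not sol.success:
        raise RuntimeError(f"stiff integration failed: {sol.message}")
    return sol


def _membrane_segments(geom: FranzGeometry, diff: DiffusivitySet, n_donor, n_membrane):
    return [
        {"name": "donor", "length": geom.delta_d, "n": n_donor, "area": geom.A, "D": diff.Dd},
        {"name": "membrane", "length": geom.delta_m, "n": n_membrane, "area": geom.A, "D": diff.Dm},
    ]


def solve_model_II(
    geometry: FranzGeometry,
    diffusivities: DiffusivitySet,
    M0: float,
    variant: str = "with_withdrawals",
    schedule: WithdrawalSchedule | None = None,
    t_end: float | None = None,
    *,
    n_donor: int = 30,
    n_membrane: int = 8,
    n_dense: int = 120,
    rtol: float = 1e-7,
) -> FranzRun:
    """Donor+membrane diffusion with a perfectly mixed receptor.

    ``variant``: ``sink`` (IIa, receptor concentration pinned at zero),
    ``finite_volume`` (IIb, macroscopic receptor balance) or
    ``with_withdrawals`` (IIc, receptor balance with sampling events).
    """
    if variant not in ("sink", "finite_volume", "with_withdrawals"):
        raise ValueError("variant must be sink | finite_volume | with_withdrawals")
    if variant == "with_withdrawals":
        if schedule is None:
            raise ValueError("variant 'with_withdrawals' requires a schedule")
    if t_end is None:
        if schedule is None:
            raise ValueError("provide t_end or a schedule")
        t_end = float(schedule.times[-1])
    if schedule is not None and schedule.times[-1] > t_end:
        raise ValueError("schedule times outside the integration window")

    geom, diff = geometry, diffusivities
    chain = _Chain(_membrane_segments(geom, diff, n_donor, n_membrane))
    donor = chain.labels == "donor"
    c0val = M0 / (geom.A * geom.delta_d)
    c = np.where(donor, c0val, 0.0)
    Vres = geom.Vres
    Vp = geom.Vtc if (schedule is None or schedule.Vp is None) else schedule.Vp
    # membrane -> receptor coupling conductance (half-cell resistance)
    g_end = geom.A / (0.5 * chain.widths[-1] / diff.Dm)

    n = chain.n
    if variant == "sink":
        Mmat = chain.matrix(end_conductance=g_end)
        t_eval = np.linspace(0.0, t_end, n_dense)
        sol = _integrate_linear(Mmat, c, 0.0, t_end, t_eval=t_eval, rtol=rtol)
        Mt = M0 - np.array([chain.mass(sol.y[:, k]) for k in range(sol.y.shape[1])])
        tw = schedule.times if schedule is not None else np.array([t_end])
        cp = np.zeros_like(tw)
        zero = np.zeros_like(tw)
        return FranzRun("IIa", M0, tw, cp, np.interp(tw, sol.t, Mt), zero,
                        zero, zero, zero, sol.t, Mt,
                        np.full_like(sol.t, M0), np.zeros_like(sol.t),
                        meta={"variant": variant})

    # IIb / IIc: augment state with cres
    base = chain.matrix()
    M_aug = np.zeros((n + 1, n + 1))
    M_aug[:n, :n] = base
    M_aug[n - 1, n - 1] -= g_end / chain.V[n - 1]
    M_aug[n - 1, n] += g_end / chain.V[n - 1]
    M_aug[n, n - 1] += g_end / Vres
    M_aug[n, n] -= g_end / Vres

    y = np.concatenate([c, [0.0]])
    events = list(schedule.times) if (variant == "with_withdrawals" and schedule is not None) else []
    breaks = sorted(set(events + [t_end]))
    t_all, Mt_all, mass_all, wd_all = [0.0], [0.0], [M0], [0.0]
    cp_list, Mtw_list, cbar_list = [], [], []
    withdrawn = 0.0
    t_prev = 0.0
    for tb in breaks:
        n_pts = max(8, int(n_dense * (tb - t_prev) / t_end))
        t_eval = np.linspace(t_prev, tb, n_pts + 1)[1:]
        sol = _integrate_linear(M_aug, y, t_prev, tb, t_eval=t_eval, rtol=rtol)
        for k in range(sol.y.shape[1]):
            yk = sol.y[:, k]
            t_all.append(sol.t[k])
            Mt_all.append(Vres * yk[n] + withdrawn)
            mass_all.append(chain.mass(yk[:n]) + Vres * yk[n] + withdrawn)
            wd_all.append(withdrawn)
        y = sol.y[:, -1].copy()
        if tb in events:
            cp_i = y[n]
            cp_list.append(cp_i)
            Mtw_list.append(Vres * cp_i + withdrawn)
            cbar_list.append(cp_i)
            y[n] *= 1.0 - Vp / Vres
            withdrawn += Vp * cp_i
        t_prev = tb
    tw = np.asarray(events) if events else np.array([t_end])
    if not events:
        cp_list = [y[n]]
        Mtw_list = [Vres * y[n]]
        cbar_list = [y[n]]
    cp = np.asarray(cp_list)
    cbar = np.asarray(cbar_list)
    Mts = np.array([Vres * cp[i] + np.sum(Vp * cp[:i]) for i in range(len(cp))])
    label = "IIb" if variant == "finite_volume" else "IIc"
    return FranzRun(label, M0, tw, cp, np.asarray(Mtw_list), Mts, cbar, cbar, cbar,
                    np.asarray(t_all), np.asarray(Mt_all), np.asarray(mass_all),
                    np.asarray(wd_all), meta={"variant": variant, "Vp": Vp})


def solve_model_III(
    geometry: FranzGeometry,
    diffusivities: DiffusivitySet,
    schedule: WithdrawalSchedule,
    donor_mode: str = "solution",
    *,
    M0: float,
    t_end: float | None = None,
    n_donor: int = 24,
    n_membrane: int = 8,
    n_cil: int = 24,
    n_tc: int = 16,
    n_arm: int = 24,
    n_dense: int = 120,
    rtol: float = 1e-7,
    receptor_mixing: str = "model",
) -> FranzRun:
    """Imperfect-mixing five-domain Franz-cell model.

    ``donor_mode='solution'`` treats the donor as a drug solution of
    thickness ``geometry.delta_d`` with diffusivity ``Dd``;
    ``donor_mode='swollen_film'`` is the same equations with ``delta_d`` set
    to the swollen-film thickness and ``Dd`` to the gel diffusivity (the film
    is taken fully swollen from the first instants).  ``receptor_mixing``:
    ``model`` uses the exponential mixing decay; ``full`` applies the stirred
    diffusivity to cone and arm as well (perfect-mixing limit, for
    cross-checks against Model IIc).
    """
    if donor_mode not in ("solution", "swollen_film"):
        raise ValueError("donor_mode must be 'solution' or 'swollen_film'")
    if receptor_mixing not in ("model", "full"):
        raise ValueError("receptor_mixing must be 'model' or 'full'")
    if t_end is None:
        t_end = float(schedule.times[-1])
    if schedule.times[-1] > t_end:
        raise ValueError("schedule times outside the integration window")

    geom, diff = geometry, diffusivities
    Dcil = geom.mix_factor * diff.D0
    L_tc, L_arm, L_cil = geom.L_tc, geom.L_arm, geom.L_cil

    def D_tc(s):
        if receptor_mixing == "full":
            return np.full_like(s, Dcil)
        return diff.D0 + (Dcil - diff.D0) * np.exp(-geom.beta_D * s)

    def A_tc(s):
        return geom.A_cil + (geom.A_arm - geom.A_cil) * s / L_tc

    segments = _membrane_segments(geom, diff, n_donor, n_membrane) + [
        {"name": "cil", "length": L_cil, "n": n_cil, "area": geom.A_cil, "D": Dcil},
        {"name": "tc", "length": L_tc, "n": n_tc, "area": A_tc, "D": D_tc},
        {"name": "arm", "length": L_arm, "n": n_arm, "area": geom.A_arm,
         "D": Dcil if receptor_mixing == "full" else diff.D0},
    ]
    chain = _Chain(segments)
    donor = chain.labels == "donor"
    cil = chain.labels == "cil"
    tc = chain.labels == "tc"
    arm = chain.labels == "arm"
    V = chain.V
    Vp = geom.Vtc if schedule.Vp is None else schedule.Vp

    c = np.where(donor, M0 / (geom.A * geom.delta_d), 0.0)
    Mmat = chain.matrix()

    def dom_mean(cv, mask):
        return float(np.dot(V[mask], cv[mask]) / V[mask].sum())

    withdrawn = 0.0
    wsum_vp = 0.0  # printed-formula withdrawal sum (uses Vp)
    t_all, Mt_all, mass_all, wd_all = [0.0], [0.0], [M0], [0.0]
    cp_list, Mtw_list, ccil_list, ctc_list, carm_list, Mts_list = [], [], [], [], [], []
    t_prev = 0.0
    breaks = sorted(set(list(schedule.times) + [t_end]))
    for tb in breaks:
        n_pts = max(8, int(n_dense * (tb - t_prev) / t_end))
        t_eval = np.linspace(t_prev, tb, n_pts + 1)[1:]
        sol = _integrate_linear(Mmat, c, t_prev, tb, t_eval=t_eval, rtol=rtol)
        for k in range(sol.y.shape[1]):
            ck = sol.y[:, k]
            t_all.append(sol.t[k])
            rec = float(np.dot(V[cil], ck[cil]) + np.dot(V[tc], ck[tc]) + np.dot(V[arm], ck[arm]))
            Mt_all.append(rec + wsum_vp)
            mass_all.append(chain.mass(ck) + withdrawn)
            wd_all.append(withdrawn)
        c = sol.y[:, -1].copy()
        if tb in schedule.times:
            ccil = dom_mean(c, cil)
            ctc = dom_mean(c, tc)
            carm = dom_mean(c, arm)
            cp_i = ctc
            Mts_list.append(geom.Vres * cp_i + wsum_vp)
            Mtw_list.append(geom.Vcil * ccil + geom.Vtc * ctc + geom.Varm * carm + wsum_vp)
            cp_list.append(cp_i)
            ccil_list.append(ccil)
            ctc_list.append(ctc)
            carm_list.append(carm)
            withdrawn += float(np.dot(V[tc], c[tc]))  # actual mass removed
            wsum_vp += Vp * cp_i
            c[tc] = 0.0  # withdrawal + fresh-solvent replacement
        t_prev = tb

    return FranzRun(
        "III", M0, np.asarray(schedule.times), np.asarray(cp_list),
        np.asarray(Mtw_list), np.asarray(Mts_list), np.asarray(ccil_list),
        np.asarray(ctc_list), np.asarray(carm_list),
        np.asarray(t_all), np.asarray(Mt_all), np.asarray(mass_all),
        np.asarray(wd_all),
        meta={"donor_mode": donor_mode, "receptor_mixing": receptor_mixing, "Vp": Vp},
    )


def integral_release_estimators(run: FranzRun, Vres: float, Vp: float,
                                Vcil: float | None = None, Vtc: float | None = None,
                                Varm: float | None = None):
    """Recompute the two integral-release estimators from a run's samples.

    ``Mts(ti) = Vres cp(ti) + sum_{j<i} Vp cp(tj)`` (the experimental,
    perfect-mixing bookkeeping) and, when the domain averages are available,
    ``Mt(ti) = Vcil c̄cil + Vtc c̄tc + Varm c̄arm + sum_{j<i} Vp c̄tc(tj)``.
    """
    cp = np.asarray(run.cp)
    Mts = np.array([Vres * cp[i] + Vp * np.sum(cp[:i]) for i in range(len(cp))])
    if Vcil is None:
        return Mts.copy(), Mts
    ctc = np.asarray(run.cbar_tc)
    Mt = np.array([
        Vcil * run.cbar_cil[i] + Vtc * ctc[i] + Varm * run.cbar_arm[i] + Vp * np.sum(ctc[:i])
        for i in range(len(cp))
    ])
    return Mt, Mts
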