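"""Least-squares parameter estimation from release and swelling curves.

Reproduces the estimation workflow of the film-characterisation pipeline:

1. :func:`fit_swelling` — solvent diffusivity ``DGs`` and erosion constant
   ``C`` from a weight-ratio curve W(t)/W0 (the threshold and equilibrium
   fractions are held fixed);
2. :func:`fit_gel_diffusivity` — drug diffusivity in the swollen gel from
   Franz-cell withdrawal concentrations (imperfect-mixing model, film donor);
3. :func:`fit_erosion_constant` — apparatus-specific erosion constant ``C``
   (equivalently the disentanglement rate at the equilibrium fraction) from a
   USP II or flow-through cumulative release curve, all diffusivities fixed.

All fits are bounded least squares (scipy ``least_squares``/trf) with a
small log-spaced multi-start whose jitter comes from a caller-provided seed,
so results are reproducible.  Uniform (absolute) residual weighting by
default; a relative-weighting switch is provided.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .franz import DiffusivitySet, FranzGeometry, WithdrawalSchedule, solve_model_III
from .swelling import SwellingParams, disentanglement_rate, solve_swelling
from .usp2 import USP2Config, solve_usp2_release

__all__ = ["FitResult", "fit_swelling", "fit_gel_diffusivity", "fit_erosion_constant"]


@dataclass
class FitResult:
    """Outcome of a bounded least-squares fit.

    ``estimates``/``units`` are keyed by parameter name; ``residual_norm``
    is the root-sum-of-squares at the optimum; ``extras`` holds derived
    quantities (e.g. the disentanglement rate implied by a fitted C).
    """

    names: list
    estimates: dict
    units: dict
    residual_norm: float
    n_evals: int
    converged: bool
    message: str
    seed: int | None = None
    bounds: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def _multistart(residual, starts, lb, ub, xtol=1e-8, ftol=1e-9, diff_step=1e-3):
    # diff_step must straddle the forward solver's tolerance noise, or the
    # finite-difference jacobian is garbage
    best = None
    n_ev = 0
    for x0 in starts:
        try:
            res = least_squares(residual, x0, bounds=(lb, ub), method="trf",
                                xtol=xtol, ftol=ftol, diff_step=diff_step)
        except Exception:
            continue
        n_ev += res.nfev
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    return best, n_ev


def _weights(y, relative):
    # residuals are normalised to O(1) so the optimiser's default gradient
    # and cost tolerances are meaningful regardless of the data's units
    ymax = np.max(np.abs(y))
    if ymax == 0:
        return np.ones_like(y)
    if not relative:
        return np.full_like(y, 1.0 / ymax)
    scale = np.maximum(np.abs(y), 0.05 * ymax)
    return 1.0 / scale


def fit_swelling(
    t,
    w,
    template: SwellingParams,
    *,
    bounds_DGs=(1e-11, 1e-7),
    bounds_C_um=(0.0, 1e3),
    n_starts: int = 3,
    seed: int = 0,
    relative_weights: bool = False,
    n_nodes: int = 41,
) -> FitResult:
    """Estimate (DGs, C) from a weight-ratio series.

    ``template`` supplies the fixed parameters (L0, phi0, phig, phieq,
    geometry, densities); its DGs/C entries are ignored.  Internally the
    search runs over (log10 DGs, C in μm/s).
    """
    t = np.asarray(t, float)
    w = np.asarray(w, float)
    if t.shape != w.shape or t.ndim != 1 or len(t) < 4:
        raise ValueError("need matching 1D t and W/W0 arrays with >= 4 points")
    order = np.argsort(t)
    t, w = t[order], w[order]
    if t[0] != 0.0:
        t = np.concatenate([[0.0], t])
        w = np.concatenate([[1.0], w])
    wts = _weights(w, relative_weights)

    def forward(logD, C_um):
        p = replace(template, DGs=10.0**logD, C=C_um * 1e-6)
        traj = solve_swelling(p, t_grid=t, n_nodes=n_nodes)
        return traj.weight_ratio

    def residual(x):
        try:
            pred = forward(x[0], x[1])
        except Exception:
            return np.full_like(w, 1e3)
        return (pred - w) * wts

    rng = np.random.default_rng(seed)
    lo = [np.log10(bounds_DGs[0]), bounds_C_um[0]]
    hi = [np.log10(bounds_DGs[1]), bounds_C_um[1]]

    # physics-informed initial guess: the dissolution time pins the erosion
    # constant through the polymer budget, t_d ≈ (1-phi0) z_init /
    # ((1-phieq)^2.625 C); a coarse 1D scan then pins DGs
    p0 = template
    w_max = float(np.max(w))
    decayed = w[-1] < 0.5 * w_max
    if decayed:
        k_d = int(np.argmax((w < 0.05 * w_max) & (t > t[np.argmax(w)])))
        t_d = t[k_d] if k_d > 0 else t[-1]
        C_guess = (1.0 - p0.phi0) * p0.z_init / ((1.0 - p0.phieq) ** 2.625 * t_d) * 1e6
    else:
        C_guess = lo[1] + 1e-6  # curve never decays: essentially no erosion
    C_guess = min(max(C_guess, lo[1] + 1e-9), hi[1] - 1e-9)
    scan = np.linspace(lo[0] + 0.25, hi[0] - 0.25, 7)
    scan_obj = [float(np.sum(residual([ld, C_guess]) ** 2)) for ld in scan]
    logD_guess = float(scan[int(np.argmin(scan_obj))])
    starts = [[logD_guess, C_guess]]
    for _ in range(max(n_starts - 1, 0)):
        starts.append([
            float(np.clip(logD_guess + rng.uniform(-0.5, 0.5), lo[0], hi[0])),
            float(np.clip(C_guess * rng.uniform(0.7, 1.4), lo[1] + 1e-9, hi[1] - 1e-9)),
        ])
    best, n_ev = _multistart(residual, starts, lo, hi)
    DGs_hat = 10.0 ** best.x[0]
    C_hat_um = best.x[1]
    return FitResult(
        names=["DGs", "C"],
        estimates={"DGs": DGs_hat, "C": C_hat_um * 1e-6},
        units={"DGs": "m^2/s", "C": "m/s"},
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        n_evals=n_ev,
        converged=bool(best.status > 0),
        message=best.message,
        seed=seed,
        bounds={"DGs": bounds_DGs, "C_um_s": bounds_C_um},
        extras={"C_um_s": C_hat_um,
                "Rdis_eq": disentanglement_rate(template.phieq, C_hat_um * 1e-6)},
    )


def fit_gel_diffusivity(
    t_withdraw,
    cp,
    geometry: FranzGeometry,
    *,
    Dm: float,
    D0: float,
    M0: float,
    bounds_DG=(1e-12, 1e-9),
    n_starts: int = 3,
    seed: int = 0,
    relative_weights: bool = False,
    solver_kwargs: dict | None = None,
) -> FitResult:
    """Estimate the swollen-gel drug diffusivity from Franz-cell withdrawal
    concentrations (imperfect-mixing model, film donor of thickness
    ``geometry.delta_d``)."""
    t_withdraw = np.asarray(t_withdraw, float)
    cp = np.asarray(cp, float)
    if t_withdraw.shape != cp.shape or len(cp) < 2:
        raise ValueError("need matching withdrawal times and concentrations")
    sched = WithdrawalSchedule(times=t_withdraw)
    wts = _weights(cp, relative_weights)
    kw = solver_kwargs or {}

    def residual(x):
        DG = 10.0 ** x[0]
        diff = DiffusivitySet(Dd=DG, Dm=Dm, D0=D0)
        try:
            run = solve_model_III(geometry, diff, sched, "swollen_film", M0=M0, **kw)
        except Exception:
            return np.full_like(cp, 1e3)
        return (run.cp - cp) * wts

    rng = np.random.default_rng(seed)
    lo, hi = np.log10(bounds_DG[0]), np.log10(bounds_DG[1])
    starts = [[v] for v in np.linspace(lo + 0.3, hi - 0.3, n_starts) + rng.uniform(-0.1, 0.1, n_starts)]
    best, n_ev = _multistart(residual, starts, [lo], [hi])
    DG_hat = 10.0 ** best.x[0]
    flat = abs(best.x[0] - hi) < 1e-3 or abs(best.x[0] - lo) < 1e-3
    return FitResult(
        names=["DG"],
        estimates={"DG": DG_hat},
        units={"DG": "m^2/s"},
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        n_evals=n_ev,
        converged=bool(best.status > 0),
        message=(best.message + (" [estimate at a bound]" if flat else "")),
        seed=seed,
        bounds={"DG": bounds_DG},
        extras={"at_bound": flat},
    )


def fit_erosion_constant(
    t,
    Mt,
    apparatus: str,
    *,
    usp2_config: USP2Config | None = None,
    mftd_args: dict | None = None,
    bounds_C_um=(0.0, 1e3),
    n_starts: int = 3,
    seed: int = 0,
    relative_weights: bool = False,
    solver_kwargs: dict | None = None,
) -> FitResult:
    """Estimate the erosion constant C from a cumulative release curve.

    ``apparatus`` is ``usp2`` or ``mftd``.  For USP II pass ``usp2_config``
    (its swelling C entry is ignored); for the flow-through device pass
    ``mftd_args`` with keys ``swelling``, ``geometry``, ``DG``, ``D0``,
    ``c0``.  Reports the implied disentanglement rate at the equilibrium
    solvent fraction alongside C.
    """
    t = np.asarray(t, float)
    Mt = np.asarray(Mt, float)
    if t.shape != Mt.shape or len(t) < 4:
        raise ValueError("need matching 1D t and Mt arrays with >= 4 points")
    if apparatus not in ("usp2", "mftd"):
        raise ValueError("apparatus must be 'usp2' or 'mftd'")
    wts = _weights(Mt, relative_weights)
    kw = solver_kwargs or {}

    if apparatus == "usp2":
        if usp2_config is None:
            raise ValueError("usp2_config required")
        phieq = usp2_config.swelling.phieq

        def forward(C_um):
            cfg = replace(usp2_config, swelling=replace(usp2_config.swelling, C=C_um * 1e-6))
            tg = t if t[0] == 0.0 else np.concatenate([[0.0], t])
            rel = solve_usp2_release(cfg, tg, **kw)
            return np.interp(t, rel.t, rel.Mt)
    else:
        if mftd_args is None:
            raise ValueError("mftd_args required")
        from .mftd import solve_mftd_release  # local import: heavy module

        phieq = mftd_args["swelling"].phieq

        def forward(C_um):
            sw = replace(mftd_args["swelling"], C=C_um * 1e-6)
            rel = solve_mftd_release(sw, mftd_args["geometry"], mftd_args["DG"],
                                     mftd_args["D0"], mftd_args["c0"],
                                     t_end=float(t[-1]) * 1.02, **kw)
            return np.interp(t, rel.t, rel.Mt)

    def residual(x):
        try:
            pred = forward(x[0])
        except Exception:
            return np.full_like(Mt, 1e3 * max(np.max(np.abs(Mt)), 1.0))
        return (pred - Mt) * wts

    rng = np.random.default_rng(seed)
    lo, hi = bounds_C_um
    grid = np.geomspace(max(lo, 1.0), min(hi, 3e2), n_starts) * rng.uniform(0.9, 1.1, n_starts)
    starts = [[min(max(v, lo + 1e-9), hi - 1e-9)] for v in grid]
    best, n_ev = _multistart(residual, starts, [lo], [hi], xtol=1e-6, ftol=1e-8)
    C_um = float(best.x[0])
    return FitResult(
        names=["C"],
        estimates={"C": C_um * 1e-6},
        units={"C": "m/s"},
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        n_evals=n_ev,
        converged=bool(best.status > 0),
        message=best.message,
        seed=seed,
        bounds={"C_um_s": bounds_C_um},
        extras={"C_um_s": C_um, "Rdis_eq": disentanglement_rate(phieq, C_um * 1e-6),
                "Rdis_eq_um_s": disentanglement_rate(phieq, C_um)},
    )
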