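"""Closed-form physico-chemical calculations.

Phase-solubility analysis (Higuchi–Connors A_L type), Wilke–Chang diffusivity
estimation, swollen-film thickness, duct hydraulics and film mechanical
indices.  All functions are pure and operate in SI units unless the docstring
says otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseSolubilityResult",
    "phase_solubility_fit",
    "complexation_constant",
    "wilke_chang",
    "swollen_thickness",
    "hydraulic_diameter",
    "reynolds",
    "puncture_strength",
    "elongation_to_break",
]


@dataclass(frozen=True)
class PhaseSolubilityResult:
    """Result of a linear (A_L-type) phase-solubility fit.

    Attributes
    ----------
    alpha : float
        Intercept of the solubility line: intrinsic drug solubility (mol/L).
    beta : float
        Slope of the solubility line (dimensionless).  For a 1:1 inclusion
        complex the slope is below unity.
    K11 : float
        1:1 complexation equilibrium constant ``beta / (alpha * (1 - beta))``
        (L/mol).
    r2 : float
        Coefficient of determination of the fit.
    is_AL : bool
        True when 0 < beta < 1, i.e. the line admits the 1:1 interpretation.
    """

    alpha: float
    beta: float
    K11: float
    r2: float
    is_AL: bool


def complexation_constant(alpha: float, beta: float) -> float:
    """1:1 complexation constant K = beta / (alpha * (1 - beta)) in L/mol."""
    if alpha <= 0:
        raise ValueError("intercept alpha must be positive")
    if not beta < 1:
        raise ValueError("slope beta >= 1: not an A_L-type 1:1 system")
    return beta / (alpha * (1.0 - beta))


def phase_solubility_fit(cCD, cf) -> PhaseSolubilityResult:
    """Fit the phase-solubility line ``cf = alpha + beta * cCD``.

    Parameters
    ----------
    cCD : array-like
        Cyclodextrin (ligand) concentrations, mol/L, non-negative.
    cf : array-like
        Drug concentration at saturation for each ligand level, mol/L.

    Returns
    -------
    PhaseSolubilityResult
        Ordinary-least-squares estimates; ``K11`` is NaN when the slope does
        not admit the 1:1 interpretation (``is_AL`` False).
    """
    x = np.asarray(cCD, dtype=float)
    y = np.asarray(cf, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("cCD and cf must be 1D arrays of equal length")
    if x.size < 3:
        raise ValueError("at least 3 points are required")
    if np.any(x < 0):
        raise ValueError("ligand concentrations must be non-negative")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all ligand concentrations equal")
    beta, alpha = np.polyfit(x, y, 1)
    resid = y - (alpha + beta * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    is_AL = bool(0.0 < beta < 1.0)
    K11 = complexation_constant(alpha, beta) if is_AL and alpha > 0 else float("nan")
    return PhaseSolubilityResult(alpha=float(alpha), beta=float(beta), K11=K11, r2=r2, is_AL=is_AL)


def wilke_chang(psi_B: float, MW_B: float, T: float, eta_B: float, V_LB: float) -> float:
    """Wilke–Chang estimate of dilute-solution diffusivity, returned in m²/s.

    D [cm²/s] = 7.4e-8 * sqrt(psi_B * MW_B) * T / (eta_B * V_LB**0.6)

    Parameters
    ----------
    psi_B : float
        Solvent association factor (2.26 for water).
    MW_B : float
        Solvent molar mass, g/mol.
    T : float
        Absolute temperature, K.
    eta_B : float
        Solvent viscosity, cP.
    V_LB : float
        LeBas molar volume of the solute at the normal boiling point, cm³/mol
        (supplied as an input; e.g. 317.6 for furosemide).
    """
    for name, v in (("psi_B", psi_B), ("MW_B", MW_B), ("T", T), ("eta_B", eta_B), ("V_LB", V_LB)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    d_cm2_s = 7.4e-8 * np.sqrt(psi_B * MW_B) * T / (eta_B * V_LB**0.6)
    return float(d_cm2_s) * 1e-4


def swollen_thickness(
    L0: float,
    Wmax_ratio: float,
    W0_per_area: float,
    rho_s: float = 1000.0,
    *,
    mode: str = "strict",
) -> float:
    """Thickness of the fully swollen film, m.

    ``strict`` (default) evaluates Th = L0 + (Wmax/W0) * (W0/A) / rho_s, i.e.
    the water-uptake column is sized by the *total* maximum weight.  The
    ``physical`` mode uses the weight gained, (Wmax/W0 - 1) * (W0/A) / rho_s,
    which is the cleaner accounting of absorbed water.

    Parameters
    ----------
    L0 : float
        Dry-film thickness, m.
    Wmax_ratio : float
        Maximum swelling degree Wmax/W0 (dimensionless, >= 1 normally; 0 is
        accepted as the degenerate no-uptake input).
    W0_per_area : float
        Dry film weight per unit area W0/A, kg/m².
    rho_s : float
        Solvent density, kg/m³.
    """
    if mode not in ("strict", "physical"):
        raise ValueError("mode must be 'strict' or 'physical'")
    factor = Wmax_ratio if mode == "strict" else max(Wmax_ratio - 1.0, 0.0)
    return L0 + factor * W0_per_area / rho_s


def hydraulic_diameter(width: float, height: float) -> float:
    """Hydraulic diameter of a rectangular duct: 4*w*h / (2*(w+h)), m."""
    if width <= 0 or height <= 0:
        raise ValueError("duct dimensions must be positive")
    return 4.0 * width * height / (2.0 * (width + height))


def reynolds(rho: float, v_mean: float, de: float, mu: float) -> float:
    """Reynolds number rho * v * de / mu (dimensionless)."""
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    return rho * v_mean * de / mu


def puncture_strength(F_max: float, r_probe: float) -> float:
    """Puncture strength F / (pi r²); with F in N and r in mm this is N/mm²."""
    if r_probe <= 0:
        raise ValueError("probe radius must be positive")
    return F_max / (np.pi * r_probe**2)


def elongation_to_break(a: float, a_prime: float, b: float, r: float) -> float:
    """Percent elongation at rupture of a punctured circular film.

    ((sqrt(a'² + b²) + r) / a - 1) * 100, where ``a`` is the film radius in
    the holder opening, ``a_prime = a - r`` the initial length minus the probe
    radius, ``b`` the probe vertical displacement and ``r`` the probe radius.
    All lengths in consistent units.
    """
    if a <= 0 or r <= 0:
        raise ValueError("geometry must be positive")
    return ((np.hypot(a_prime, b) + r) / a - 1.0) * 100.0
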