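"""Moving-boundary swelling-erosion solver."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from erofilm import (
    SwellingParams,
    disentanglement_rate,
    solve_swelling,
    solvent_diffusivity,
    weight_ratio,
)
from erofilm.swelling import FrontCrossingError


class TestPointwiseLaws:
    def test_diffusivity_at_equilibrium_is_DGs(self, film_no_cd):
        assert solvent_diffusivity(film_no_cd.phieq, film_no_cd) == pytest.approx(
            film_no_cd.DGs
        )

    def test_diffusivity_constant_when_exponent_zero(self, film_no_cd):
        phis = np.linspace(film_no_cd.phi0, film_no_cd.phieq, 7)
        assert np.allclose(solvent_diffusivity(phis, film_no_cd), film_no_cd.DGs)

    def test_diffusivity_dry_film_value(self, film_no_cd):
        from dataclasses import replace

        p = replace(film_no_cd, beta_s=1.0)
        assert solvent_diffusivity(p.phi0, p) == pytest.approx(
            p.DGs * np.exp(-1.0), rel=1e-12
        )

    def test_diffusivity_domain_error(self, film_no_cd):
        with pytest.raises(ValueError):
            solvent_diffusivity(0.95, film_no_cd)

    @pytest.mark.parametrize(
        "phi,C_um,expect",
        [(0.89, 67.72, 1.87), (0.85, 84.37, 3.86)],
    )
    def test_disentanglement_printed_rates(self, phi, C_um, expect):
        assert disentanglement_rate(phi, C_um) == pytest.approx(expect, rel=5e-3)

    def test_disentanglement_no_erosion(self):
        assert disentanglement_rate(0.5, 0.0) == 0.0

    def test_disentanglement_pure_solvent_rejected(self):
        with pytest.raises(ValueError):
            disentanglement_rate(1.0, 10.0)


class TestConfig:
    def test_from_config_units(self):
        p = SwellingParams.from_config(
            dict(L0_um=87, phi0=0.21, phig=0.3, phieq=0.89, DGs_m2s=7.95e-9, C_um_s=67.72)
        )
        assert p.L0 == pytest.approx(87e-6)
        assert p.C == pytest.approx(67.72e-6)

    def test_fraction_ordering_enforced(self):
        with pytest.raises(ValueError):
            SwellingParams(L0=1e-4, phi0=0.3, phig=0.2, phieq=0.9, DGs=1e-9)


class TestTrajectory:
    def test_initial_state_and_monotone_profile(self, film_no_cd):
        tg = np.linspace(0.0, 120.0, 13)
        traj = solve_swelling(film_no_cd, tg)
        assert traj.weight_ratio[0] == pytest.approx(1.0)
        assert np.all(np.diff(traj.t) > 0)
        for k in range(1, len(tg)):
            if traj.S[k] > 0:
                assert np.all(np.diff(traj.phi[k]) >= -1e-6)

    def test_polymer_conserved_without_erosion(self, film_no_cd):
        from dataclasses import replace

        p = replace(film_no_cd, C=0.0)
        traj = solve_swelling(p, np.linspace(0, 800, 33))
        P = traj.polymer_inventory()
        assert np.ptp(P) / P[0] < 5e-3

    def test_equilibrium_swelling_ratio(self, film_no_cd):
        from dataclasses import replace

        p = replace(film_no_cd, C=0.0)
        traj = solve_swelling(p, t_end=2000.0)
        expect = (1 - p.phi0) / (1 - p.phieq)
        assert traj.dense_S[-1] / p.z_init == pytest.approx(expect, rel=5e-3)

    def test_grid_and_seed_self_convergence(self, film_no_cd):
        ref = solve_swelling(film_no_cd, t_end=400.0, n_nodes=61, seed_frac=1e-3)
        fine = solve_swelling(film_no_cd, t_end=400.0, n_nodes=121, seed_frac=5e-4)
        assert fine.max_weight_ratio == pytest.approx(ref.max_weight_ratio, rel=0.01)
        assert fine.t_dissolved == pytest.approx(ref.t_dissolved, rel=0.01)

    def test_erosion_accelerates_dissolution(self, film_no_cd):
        from dataclasses import replace

        results = []
        for scale in (1.0, 1.5, 2.25):
            p = replace(film_no_cd, C=film_no_cd.C * scale)
            traj = solve_swelling(p, t_end=400.0)
            results.append((traj.t_dissolved, traj.max_weight_ratio))
        t_diss, wmax = zip(*results)
        assert t_diss[0] > t_diss[1] > t_diss[2]
        assert wmax[0] > wmax[1] > wmax[2]

    def test_tau_rescaling_collapses_thickness(self, film_no_cd):
        """Without erosion, W(tau) is identical for films differing only in L0."""
        from dataclasses import replace

        p1 = replace(film_no_cd, C=0.0)
        p2 = replace(film_no_cd, C=0.0, L0=2 * film_no_cd.L0)
        t1 = solve_swelling(p1, t_end=300.0)
        t2 = solve_swelling(p2, t_end=1200.0)
        taus = np.linspace(0.5, 25.0, 20)
        w1 = np.interp(taus, t1.dense_t * p1.DGs / p1.L0**2, t1.dense_weight_ratio)
        w2 = np.interp(taus, t2.dense_t * p2.DGs / p2.L0**2, t2.dense_weight_ratio)
        assert np.allclose(w1, w2, rtol=0.01)

    def test_weight_ratio_recompute_matches_stored(self, film_no_cd):
        tg = np.linspace(0, 150, 16)
        traj = solve_swelling(film_no_cd, tg)
        assert np.allclose(weight_ratio(traj), traj.weight_ratio, rtol=1e-10)

    def test_extreme_erosion_dissolves_as_thin_gel_wave(self):
        """When erosion dominates, the solvent influx (∝ 1/h) balances the
        disentanglement rate and the film dissolves through a quasi-steady
        thin gel layer; the run must stay well posed (the front-crossing
        guard exists for genuinely degenerate numerics, see
        FrontCrossingError) and finish early with little swelling."""
        assert issubclass(FrontCrossingError, RuntimeError)
        p = SwellingParams(L0=87e-6, phi0=0.21, phig=0.3, phieq=0.89, DGs=1e-12, C=5e-4)
        traj = solve_swelling(p, t_end=60.0)
        assert traj.dissolved
        assert traj.max_weight_ratio < 1.5
        assert np.all(traj.dense_S - traj.dense_R > -1e-12)


def _similarity_fronts(p: SwellingParams):
    """Independent early-time oracle: similarity (eta = (z - z0)/sqrt(t))
    reduction of the two-front Stefan problem, solved by shooting."""

    def Dtilde(phi):
        return p.DGs * (1.0 - phi)

    def shoot(x):
        lamR, lamS = x
        fp0 = (p.phig - p.phi0) * lamR / (2.0 * Dtilde(p.phig))

        def rhs(eta, y):
            f, g = y  # g = Dtilde(f) * f'
            fp = g / Dtilde(f)
            return [fp, -0.5 * eta * fp]

        sol = solve_ivp(rhs, (-lamR, lamS), [p.phig, Dtilde(p.phig) * fp0],
                        rtol=1e-10, atol=1e-13)
        f_end, g_end = sol.y[:, -1]
        fp_end = g_end / Dtilde(min(f_end, 0.999))
        return [f_end - p.phieq, 0.5 * lamS - p.DGs * fp_end]

    scale = np.sqrt(p.DGs)
    sol = fsolve(shoot, [0.8 * scale, 0.3 * scale], full_output=True)
    x, info, ier, _ = sol
    assert ier == 1, "similarity shooting did not converge"
    return x  # lamR, lamS with fronts R = z0 - lamR sqrt(t), S = z0 + lamS sqrt(t)


def test_early_time_fronts_match_similarity_solution():
    """Before the glassy core is exhausted the fronts follow sqrt(t) with
    coefficients given by the similarity construction."""
    p = SwellingParams(L0=400e-6, phi0=0.2, phig=0.4, phieq=0.8, DGs=1e-9, C=0.0)
    lamR, lamS = _similarity_fronts(p)
    traj = solve_swelling(p, t_end=30.0, n_nodes=121, seed_frac=5e-4)
    t = traj.dense_t
    window = (traj.dense_R < 0.95 * p.z_init) & (traj.dense_R > 0.5 * p.z_init)
    assert window.sum() > 10
    kR = np.median((p.z_init - traj.dense_R[window]) / np.sqrt(t[window]))
    kS = np.median((traj.dense_S[window] - p.z_init) / np.sqrt(t[window]))
    assert kR == pytest.approx(lamR, rel=0.02)
    assert kS == pytest.approx(lamS, rel=0.03)
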