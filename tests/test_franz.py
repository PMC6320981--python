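"""Franz-cell model hierarchy."""
import numpy as np
import pytest

from erofilm import (
    DiffusivitySet,
    FranzGeometry,
    WithdrawalSchedule,
    donor_from_loading,
    integral_release_estimators,
    model_I_mt,
    solve_model_II,
    solve_model_III,
)


class TestClosedFormsAndTypes:
    def test_donor_loading(self):
        M0, dd = donor_from_loading(0.1e-6, 0.18, 1e-4)
        assert M0 == pytest.approx(18e-9, rel=1e-12)   # 18 μg
        assert dd == pytest.approx(1e-3, rel=1e-12)    # 1 mm

    def test_model_I_limits(self):
        M0, Dm, A, dm, Vd = 18e-9, 2.89e-10, 1e-4, 45e-6, 0.1e-6
        assert model_I_mt(0.0, M0, Dm, A, dm, Vd) == 0.0
        assert model_I_mt(1e9, M0, Dm, A, dm, Vd) == pytest.approx(M0)
        tau = dm * Vd / (Dm * A)
        assert model_I_mt(tau, M0, Dm, A, dm, Vd) == pytest.approx(
            M0 * (1 - np.exp(-1)), rel=1e-12
        )

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            WithdrawalSchedule(times=np.array([10.0, 5.0]))
        with pytest.raises(ValueError):
            WithdrawalSchedule(times=np.array([-1.0]))

    def test_geometry_volume_consistency_enforced(self):
        with pytest.raises(ValueError, match="sum to Vres"):
            FranzGeometry(Vcil=3e-6)  # far from Vres with default cone/arm

    def test_membrane_diffusivity_bounded(self):
        with pytest.raises(ValueError):
            DiffusivitySet(Dd=1e-10, Dm=2e-10, D0=1e-10)


class TestModelII:
    def test_sink_variant_approaches_uniform_donor_model(self, blank_franz):
        """With a fast donor and a thin quasi-steady membrane, the resolved
        model collapses onto the closed-form uniform-donor solution."""
        geom0, _, M0 = blank_franz
        geom = FranzGeometry(delta_d=1e-3, delta_m=10e-6)
        diff = DiffusivitySet(Dd=1e-6, Dm=5e-10, D0=1e-6)  # donor ~instantly mixed
        run = solve_model_II(geom, diff, M0, "sink", t_end=2000.0)
        expect = model_I_mt(run.t, M0, diff.Dm, geom.A, geom.delta_m,
                            geom.A * geom.delta_d)
        sel = run.t > 100.0
        assert np.max(np.abs(run.Mt[sel] - expect[sel])) / M0 < 0.01

    def test_finite_volume_equilibration(self, blank_franz):
        geom, diff, M0 = blank_franz
        run = solve_model_II(geom, diff, M0, "finite_volume", t_end=3e5)
        ceq = M0 / (geom.A * geom.delta_d + geom.Vres)
        assert run.Mt[-1] / geom.Vres == pytest.approx(ceq, rel=0.02)

    def test_withdrawals_conserve_mass(self, blank_franz, hourly_schedule):
        geom, diff, M0 = blank_franz
        run = solve_model_II(geom, diff, M0, "with_withdrawals",
                             WithdrawalSchedule(times=hourly_schedule))
        assert np.max(np.abs(run.mass_total - M0)) / M0 < 1e-6
        assert np.all(np.diff(run.mass_total) <= M0 * 1e-9)  # never increases


class TestModelIII:
    def test_mass_conserved_to_roundoff(self, blank_franz, hourly_schedule):
        geom, diff, M0 = blank_franz
        run = solve_model_III(geom, diff, WithdrawalSchedule(times=hourly_schedule),
                              M0=M0)
        assert np.max(np.abs(run.mass_total - M0)) / M0 < 1e-6

    def test_imperfect_mixing_orderings(self, blank_franz, hourly_schedule):
        """The cone average lags the stirred body, so withdrawal
        concentrations undershoot the perfect-mixing prediction and the
        experimental integral estimator undershoots the true release."""
        geom, diff, M0 = blank_franz
        sched = WithdrawalSchedule(times=hourly_schedule)
        run3 = solve_model_III(geom, diff, sched, M0=M0)
        run2 = solve_model_II(geom, diff, M0, "with_withdrawals", sched)
        assert np.all(run3.cp < run3.cbar_cil)
        assert np.all(run3.Mts <= run3.Mt_w * (1 + 1e-9))
        # perfect-mixing model overestimates the early withdrawal concentrations
        assert np.all(run3.cp[:3] < run2.cp[:3])

    def test_ordering_regime_boundary(self, blank_franz):
        """After a sampling gap much longer than the cone re-equilibration
        time (~3 h here) the cone refills to the stirred-body level while the
        arm still lags, and the perfect-mixing estimator overshoots: the
        Mts <= Mt ordering is a dense-sampling property."""
        geom, diff, M0 = blank_franz
        times = np.concatenate([np.arange(1, 11) * 3600.0, [24 * 3600.0]])
        run = solve_model_III(geom, diff, WithdrawalSchedule(times=times), M0=M0)
        assert np.all(run.Mts[:-1] <= run.Mt_w[:-1] * (1 + 1e-9))
        assert run.cp[-1] / run.cbar_cil[-1] > 0.9  # cone has re-equilibrated

    def test_full_mixing_limit_matches_model_IIc(self, blank_franz, hourly_schedule):
        geom, diff, M0 = blank_franz
        sched = WithdrawalSchedule(times=hourly_schedule)
        run3 = solve_model_III(geom, diff, sched, M0=M0, receptor_mixing="full")
        run2 = solve_model_II(geom, diff, M0, "with_withdrawals", sched)
        assert np.max(np.abs(run3.cp - run2.cp)) / np.max(run2.cp) < 0.02

    def test_mixing_factor_insensitivity(self, blank_franz, hourly_schedule):
        """cp must be flat across the admissible stirred-diffusivity decade."""
        _, diff, M0 = blank_franz
        sched = WithdrawalSchedule(times=hourly_schedule)
        cps = []
        for mf in (1e5, 1e6, 1e7):
            geom = FranzGeometry(delta_d=1e-3, mix_factor=mf)
            cps.append(solve_model_III(geom, diff, sched, M0=M0).cp)
        ref = np.max(cps[1])
        assert np.max(np.abs(cps[0] - cps[1])) / ref < 0.01
        assert np.max(np.abs(cps[2] - cps[1])) / ref < 0.01

    def test_quiescent_receptor_matches_cosine_series(self):
        """mix_factor -> 1 with uniform areas and diffusivities degenerates to
        pure diffusion in a single closed slab, which has an exact cosine
        eigenfunction solution."""
        delta_d, delta_m = 1e-3, 45e-6
        D = 5e-10
        geom = FranzGeometry(
            delta_d=delta_d, delta_m=delta_m, A=1e-4, A_cil=1e-4, A_arm=1e-4,
            Vcil=4e-6, Vtc=0.5e-6, Varm=1e-6, Vres=5.5e-6, mix_factor=1.0,
        )
        diff = DiffusivitySet(Dd=D, Dm=D, D0=D)
        M0 = 18e-9
        t_probe = 2e4
        run = solve_model_III(geom, diff, WithdrawalSchedule(times=np.array([t_probe])),
                              M0=M0, n_donor=40, n_cil=60, n_tc=12, n_arm=20)
        L = delta_d + delta_m + geom.L_cil + geom.L_tc + geom.L_arm
        c0 = M0 / (geom.A * delta_d)

        def series_mean(z1, z2, t, n_terms=400):
            # mean over [z1, z2] of the closed-slab cosine expansion
            n = np.arange(1, n_terms + 1)
            k = n * np.pi / L
            an = 2 * c0 * np.sin(k * delta_d) / (n * np.pi)
            decay = np.exp(-D * k**2 * t)
            integ = (np.sin(k * z2) - np.sin(k * z1)) / k
            return c0 * delta_d / L + np.dot(an * decay, integ) / (z2 - z1)

        z_tc0 = delta_d + delta_m + geom.L_cil
        expect_cp = series_mean(z_tc0, z_tc0 + geom.L_tc, t_probe)
        assert run.cp[0] == pytest.approx(expect_cp, rel=0.02)

    def test_withdrawal_of_nearly_clean_cone_changes_nothing(self, blank_franz):
        """A withdrawal that samples (essentially) pure solvent leaves the
        later estimators unchanged: removing a cp ≈ 0 aliquot neither adds a
        withdrawal-sum term nor perturbs the receptor."""
        geom, diff, M0 = blank_franz
        late = 3600.0
        with_early = solve_model_III(
            geom, diff, WithdrawalSchedule(times=np.array([300.0, late])), M0=M0)
        without = solve_model_III(
            geom, diff, WithdrawalSchedule(times=np.array([late])), M0=M0)
        assert with_early.cp[0] < 0.15 * with_early.cp[1]
        assert with_early.cp[1] == pytest.approx(without.cp[0], rel=0.01)
        assert with_early.Mts[1] == pytest.approx(without.Mts[0], rel=0.01)
        assert with_early.Mt_w[1] == pytest.approx(without.Mt_w[0], rel=0.01)

    def test_integral_estimators_recompute(self, blank_franz, hourly_schedule):
        geom, diff, M0 = blank_franz
        run = solve_model_III(geom, diff, WithdrawalSchedule(times=hourly_schedule),
                              M0=M0)
        Mt, Mts = integral_release_estimators(run, geom.Vres, geom.Vtc,
                                              geom.Vcil, geom.Vtc, geom.Varm)
        assert np.allclose(Mts, run.Mts, rtol=1e-10)
        assert np.allclose(Mt, run.Mt_w, rtol=1e-10)
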