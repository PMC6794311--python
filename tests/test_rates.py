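"""Rate kernels, pool averaging, detailed balance, field fits, profiles."""

import numpy as np
import pandas as pd
import pytest

from spinrelax import reference
from spinrelax.constants import K_DIPOLAR
from spinrelax.dipolar import SpectralDensity
from spinrelax.rates import (FieldSpec, UnitsError, auto_cross_pair_sum,
                             bin_profile, bpp_r1, cross_pool_rates,
                             effective_rates, estimate_diffusion,
                             exchange_total, fit_power_law, intra_pool_rates,
                             pool_average, r1_pair_sum, sheath_average,
                             windowed_profile)

B15 = FieldSpec(1.5)


class TestFieldSpec:
    def test_larmor_consistency(self):
        f = FieldSpec(3.0)
        assert f.omega_L == pytest.approx(2.6752218744e8 * 3.0)
        with pytest.raises(ValueError, match="omega_L"):
            FieldSpec(3.0, omega_L=1.0)
        with pytest.raises(ValueError):
            FieldSpec(-1.0)


class TestRateKernels:
    def test_units_are_enforced(self):
        J_nm = SpectralDensity(np.array([0.0]), np.array([1.0]),
                               units="nm^-6 ps")
        with pytest.raises(UnitsError):
            r1_pair_sum(J_nm, J_nm, B15)
        with pytest.raises(UnitsError):
            auto_cross_pair_sum([1.0], [1.0], [1.0], B15, units="nm^-6 ps")

    def test_zero_spectral_density_gives_zero_rate(self):
        assert r1_pair_sum([0.0], [0.0], B15) == 0.0

    def test_linearity_in_J(self):
        r1 = r1_pair_sum([1e-10, 2e-10], [3e-10], B15)
        r2 = r1_pair_sum([2e-10, 4e-10], [6e-10], B15)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_flat_J_cross_to_auto_ratio_is_two_sevenths(self):
        """Equal J0=J1=J2 gives auto ~ 28 J, cross ~ 8 J: ratio 2/7."""
        J = 1e-12
        auto, cross = auto_cross_pair_sum([J], [J], [J], B15)
        assert cross / auto == pytest.approx(2 / 7, rel=1e-12)
        assert auto == pytest.approx(K_DIPOLAR**2 / 16 * 28 * J, rel=1e-12)

    def test_slow_motion_cross_is_negative(self):
        auto, cross = auto_cross_pair_sum([1e-10], [1e-13], [1e-13], B15)
        assert cross < 0
        assert auto > 0

    def test_cross_cancellation_at_J0_equals_9J2(self):
        _, cross = auto_cross_pair_sum([9e-12], [5e-12], [1e-12], B15)
        assert cross == pytest.approx(0.0, abs=1e-30)

    def test_bpp_closed_form_extreme_narrowing_anchor(self):
        """Isolated pair, r = 0.158 nm, tau_c = 2.5 ps, 1.5 T: ~0.137 Hz."""
        assert bpp_r1(0.158, 2.5, 1.5) == pytest.approx(0.1373, rel=1e-3)

    def test_pipeline_matches_bpp_on_isotropic_rotors(self, iso_rotor_traj):
        """Trajectory -> harmonics -> G -> J -> R1 equals the closed form
        (small 16-pair ensemble: coarse 10% stochastic bound)."""
        df = intra_pool_rates(iso_rotor_traj, fields_T=(1.5,), cutoff_nm=1.0,
                              truncation_fraction=0.01)
        got = df["R1_1.5"].mean()
        expected = bpp_r1(0.158, 10.0, 1.5)
        assert got == pytest.approx(expected, rel=0.10)


class TestPoolAveraging:
    def test_constant_rates_average_exactly(self):
        df = pd.DataFrame({"R1_1.5": [0.3, 0.3, 0.3], "pool": "WP"})
        avg = pool_average(df)
        assert avg.loc["R1_1.5", "mean"] == pytest.approx(0.3)
        assert avg.loc["R1_1.5", "se"] == pytest.approx(0.0)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pool_average(pd.DataFrame())

    def test_subsample_recorded_and_deterministic(self):
        df = pd.DataFrame({"R1_1.5": np.arange(50.0)})
        a = pool_average(df, subsample=10, seed=4)
        b = pool_average(df, subsample=10, seed=4)
        assert a.loc["R1_1.5", "mean"] == b.loc["R1_1.5", "mean"]
        assert a.attrs["subsample"] == 10

    def test_detailed_balance_exact_on_shared_J_set(self, two_pool_traj):
        """N_WP <cross_WP> = N_MP <cross_MP> to machine precision when both
        averages derive from one pairwise spectral-density set."""
        df_wp, df_mp = cross_pool_rates(two_pool_traj, fields_T=(1.5, 7.0),
                                        truncation_fraction=0.5)
        for B in ("1.5", "7"):
            lhs = len(df_wp) * df_wp[f"R1_cross_{B}"].mean()
            rhs = len(df_mp) * df_mp[f"R1_cross_{B}"].mean()
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_detailed_balance_of_published_cross_rates(self):
        """The printed averaged cross rates obey the balance to within their
        print rounding (1.5% at 1.5 T, 2% across fields)."""
        t = reference.TABLE1
        ratio = (reference.N_WP_PARTNERS * t["R1_WP_cross"]
                 / (reference.N_MP * t["R1_MP_cross"]))
        assert abs(ratio.loc[1.5] - 1.0) < 0.015
        assert np.all(np.abs(ratio - 1.0) < 0.02)


class TestEffectiveRatesAndFits:
    def test_effective_rates_from_published_table(self):
        eff = effective_rates(reference.TABLE1)
        assert eff.loc[1.5, "R1_WP_ef"] == pytest.approx(1.34)
        assert eff.loc[7.0, "R1_WP_ef"] == pytest.approx(0.813)

    def test_zero_auto_leaves_rate_unchanged(self):
        t = pd.DataFrame({"R1_WP": [1.0, 2.0], "R1_WP_auto": [0.0, 0.0]},
                         index=[1.5, 3.0])
        eff = effective_rates(t)
        np.testing.assert_array_equal(eff["R1_WP_ef"], eff["R1_WP"])

    def test_exact_power_law_recovered(self):
        B = np.array([1.5, 3.0, 7.0])
        fit = fit_power_law(B, 2.0 * B**-0.5)
        assert fit.n0 == pytest.approx(2.0, rel=1e-8)
        assert fit.n1 == pytest.approx(-0.5, rel=1e-8)

    def test_two_points_interpolated_exactly(self):
        fit = fit_power_law([1.0, 4.0], [3.0, 1.5])
        assert fit.residual == pytest.approx(0.0, abs=1e-20)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_power_law([1.5, 3.0], [1.0, -0.1])

    def test_published_water_pool_field_dependence(self):
        """Effective WP rates from the table fit to ~1.53 B0^-0.31."""
        eff = effective_rates(reference.TABLE1)
        fit = fit_power_law(eff.index, eff["R1_WP_ef"], pool="WP")
        assert fit.n0 == pytest.approx(1.53, abs=0.02)
        assert fit.n1 == pytest.approx(-0.31, abs=0.02)

    def test_sheath_average_bracketed_and_weighted(self):
        from spinrelax.rates import PowerLawFit
        wp = PowerLawFit(**reference.PUBLISHED_POWER_LAW["WP"], pool="WP")
        mp = PowerLawFit(**reference.PUBLISHED_POWER_LAW["MP"], pool="MP")
        ms = sheath_average(wp, mp, reference.N_WP, reference.N_MP, 7.0)
        assert ms.R1_MS == pytest.approx(1.8, abs=0.05)
        assert wp(7.0) <= ms.R1_MS <= mp(7.0)
        only_mp = sheath_average(wp, mp, 0, reference.N_MP, 7.0)
        assert only_mp.R1_MS == pytest.approx(mp(7.0))
        same = sheath_average(wp, wp, 100, 100, 3.0)
        assert same.R1_MS == pytest.approx(wp(3.0))

    def test_exchange_total(self):
        est = exchange_total(0.061, 11.94)
        assert est.k_WP == pytest.approx(12.0, abs=0.01)
        assert not est.negative_cross
        est0 = exchange_total(0.05, 0.0)
        assert est0.k_WP == pytest.approx(0.05)
        neg = exchange_total(-0.01, 1.0)
        assert neg.negative_cross


class TestProfiles:
    def test_window_longer_than_trajectory_rejected(self, slab_traj_flat):
        with pytest.raises(ValueError, match="exceeds"):
            windowed_profile(slab_traj_flat, window_ps=1e9, n_windows=1)

    def test_single_full_window_equals_full_analysis(self, iso_rotor_traj):
        rec = windowed_profile(iso_rotor_traj,
                               window_ps=iso_rotor_traj.duration,
                               n_windows=1, field_T=1.5, seed=0,
                               truncation_fraction=0.03)
        full = intra_pool_rates(iso_rotor_traj, fields_T=(1.5,),
                                cutoff_nm=1.0, truncation_fraction=0.03)
        # the window picked one molecule; compare against that pair's rate
        assert np.any(np.isclose(full["R1_1.5"], rec["R1"].iloc[0],
                                 rtol=1e-9))

    def test_flat_mobility_gives_flat_profile(self, slab_traj_flat):
        rec = windowed_profile(slab_traj_flat, window_ps=500.0, n_windows=250,
                               field_T=1.5, seed=11)
        prof = bin_profile(rec, np.linspace(0, 4.0, 6)).dropna()
        grand = rec["R1"].mean()
        assert np.all(np.abs(prof["mean"] - grand) < 3 * prof["se"])

    def test_wall_slowed_slab_has_elevated_wall_R1(self, slab_traj_wall_slowed):
        """Parabola-like profile: wall bins above centre bins (>3 SE)."""
        rec = windowed_profile(slab_traj_wall_slowed, window_ps=500.0,
                               n_windows=300, field_T=1.5, seed=11)
        prof = bin_profile(rec, np.linspace(0, 4.0, 9)).dropna()
        wall = prof.iloc[[0, -1]]
        centre = prof.iloc[[len(prof) // 2 - 1, len(prof) // 2]]
        gap = wall["mean"].mean() - centre["mean"].mean()
        se = np.sqrt(wall["se"].max() ** 2 + centre["se"].max() ** 2)
        assert gap > 3 * se

    def test_diffusion_estimator_on_uniform_slab(self, slab_traj_flat):
        pos = slab_traj_flat.positions
        centres = 0.5 * (pos[:, 0::2] + pos[:, 1::2])
        xy = centres.copy()
        xy[:, :, 2] = 0.0
        D = estimate_diffusion(xy, slab_traj_flat.dt) * 3.0 / 2.0
        assert D == pytest.approx(2e-5, rel=0.10)
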