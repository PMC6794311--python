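"""Generators: determinism, analytic decay oracles, boundary contracts."""

import numpy as np
import pytest

from spinrelax.dipolar import (autocorrelate, harmonics_from_displacements,
                               pair_displacements)
from spinrelax.rates import estimate_diffusion, msd
from spinrelax.synthetic import (MobilityProfile, MotionSpec,
                                 cone_half_angle_for_S2, generate,
                                 generate_cone_restricted_rotor,
                                 generate_isotropic_rotor,
                                 generate_translational_brownian,
                                 generate_water_slab)


def _mean_normalized_G(traj, q=2, truncation=0.3):
    Gs = []
    n_pairs = traj.n_atoms // 2
    for p in range(n_pairs):
        h = harmonics_from_displacements(
            pair_displacements(traj, 2 * p, 2 * p + 1), traj.dt)
        Gs.append(autocorrelate(h, truncation).G)
    G = np.mean(Gs, axis=0)
    return G[q] / G[q, 0], np.arange(G.shape[1]) * traj.dt, G


class TestSpecValidation:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            MotionSpec(kind="ballistic")

    @pytest.mark.parametrize("kw", [
        dict(kind="isotropic_rotor", tau_c=-1.0),
        dict(kind="isotropic_rotor", tau_c=None),
        dict(kind="cone_restricted_rotor", S2_target=0.0, tau_M=100.0, tau_i=1.0),
        dict(kind="cone_restricted_rotor", S2_target=1.2, tau_M=100.0, tau_i=1.0),
        dict(kind="cone_restricted_rotor", S2_target=0.5, tau_M=10.0, tau_i=50.0),
        dict(kind="translational_brownian", D=-1e-5),
        dict(kind="water_slab", slab_width=-1.0),
    ])
    def test_invalid_motion_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            MotionSpec(**kw)

    def test_coarse_rotational_step_refused(self):
        spec = MotionSpec(kind="isotropic_rotor", tau_c=1.0, dt=1.0, n_steps=10)
        with pytest.raises(ValueError, match="step variance"):
            generate_isotropic_rotor(spec)

    def test_nonpositive_mobility_profile_refused(self):
        spec = MotionSpec(
            kind="water_slab", slab_width=2.0,
            mobility_profile=MobilityProfile(
                tau_c=lambda z: np.asarray(z) - 1.0,  # negative for z < 1
                D=lambda z: np.full_like(np.asarray(z, float), 1e-5)),
            n_pairs=2, dt=0.1, n_steps=10)
        with pytest.raises(ValueError, match="positive"):
            generate_water_slab(spec)


class TestDeterminism:
    @pytest.mark.parametrize("kind,extra", [
        ("isotropic_rotor", dict(tau_c=10.0)),
        ("cone_restricted_rotor", dict(S2_target=0.5, tau_M=100.0, tau_i=5.0)),
        ("translational_brownian", dict(D=2e-5)),
    ])
    def test_same_seed_bitwise_identical(self, kind, extra):
        spec = dict(kind=kind, dt=0.5, n_steps=200, n_pairs=3, seed=9, **extra)
        a = generate(MotionSpec(**spec))
        b = generate(MotionSpec(**spec))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_different_seeds_differ(self):
        base = dict(kind="isotropic_rotor", tau_c=10.0, dt=0.5, n_steps=200,
                    n_pairs=3)
        a = generate(MotionSpec(seed=1, **base))
        b = generate(MotionSpec(seed=2, **base))
        assert not np.array_equal(a.positions, b.positions)


class TestIsotropicRotor:
    def test_single_frame_has_exact_pair_distance(self):
        spec = MotionSpec(kind="isotropic_rotor", tau_c=5.0, n_steps=1,
                          n_pairs=4, pair_distance=0.2)
        traj = generate_isotropic_rotor(spec)
        assert traj.n_frames == 1
        d = np.linalg.norm(traj.positions[0, 0::2] - traj.positions[0, 1::2],
                           axis=1)
        np.testing.assert_allclose(d, 0.2, rtol=1e-12)

    def test_pair_distance_constant_over_time(self, iso_rotor_traj):
        d = np.linalg.norm(
            iso_rotor_traj.positions[:, 0] - iso_rotor_traj.positions[:, 1],
            axis=1)
        np.testing.assert_allclose(d, 0.158, rtol=1e-9)

    def test_rank2_correlation_decays_exponentially(self, iso_rotor_traj):
        """G2hat(tau) ~ exp(-tau/tau_c) for rotational diffusion, tau_c=10 ps."""
        ghat, lags, _ = _mean_normalized_G(iso_rotor_traj, truncation=0.01)
        mask = (lags > 0) & (lags <= 30.0)
        expected = np.exp(-lags[mask] / 10.0)
        np.testing.assert_allclose(ghat[mask], expected, atol=0.05)
        # fitted correlation time within 5% (log fit over the first 2 tau_c,
        # where the estimate is not yet dominated by tail noise)
        fitmask = (lags > 0) & (lags <= 20.0)
        tau_fit = -1.0 / np.polyfit(lags[fitmask], np.log(ghat[fitmask]), 1)[0]
        assert abs(tau_fit / 10.0 - 1.0) < 0.05

    def test_harmonic_magnitudes_match_uniform_sphere_moments(self, iso_rotor_traj):
        """A0 : A1 : A2 converge to 12 : 2 : 8 (in units of r^-6 / 15)."""
        r6 = 0.158 ** -6
        expected = np.array([4 / 5, 2 / 15, 8 / 15]) * r6
        n_pairs = iso_rotor_traj.n_atoms // 2
        A = np.array([
            autocorrelate(harmonics_from_displacements(
                pair_displacements(iso_rotor_traj, 2 * p, 2 * p + 1),
                iso_rotor_traj.dt), 0.01).G[:, 0]
            for p in range(n_pairs)])
        mean, se = A.mean(axis=0), A.std(axis=0, ddof=1) / np.sqrt(n_pairs)
        assert np.all(np.abs(mean - expected) < 3 * se + 0.02 * expected)


class TestConeRestrictedRotor:
    def test_cone_angle_mapping_inverts_order_parameter(self):
        for s2 in (0.1, 0.36, 0.64, 0.81, 0.99):
            beta = cone_half_angle_for_S2(s2)
            c = np.cos(beta)
            assert np.isclose((c * (1 + c) / 2) ** 2, s2, rtol=1e-12)

    def test_rigid_limit_is_single_exponential(self):
        spec = MotionSpec(kind="cone_restricted_rotor", S2_target=1.0,
                          tau_M=20.0, dt=0.5, n_steps=30_000, n_pairs=8,
                          seed=21)
        traj = generate_cone_restricted_rotor(spec)
        assert traj.metadata["S2"] == 1.0
        ghat, lags, _ = _mean_normalized_G(traj, truncation=0.01)
        mask = (lags > 0) & (lags <= 60.0)
        tau_fit = -1.0 / np.polyfit(lags[mask], np.log(np.clip(ghat[mask],
                                                               1e-12, None)),
                                    1)[0]
        assert abs(tau_fit / 20.0 - 1.0) < 0.1

    def test_normalized_correlation_starts_at_one(self):
        spec = MotionSpec(kind="cone_restricted_rotor", S2_target=0.64,
                          tau_M=500.0, tau_i=5.0, dt=1.0, n_steps=2000,
                          n_pairs=4, seed=2)
        traj = generate_cone_restricted_rotor(spec)
        ghat, _, _ = _mean_normalized_G(traj)
        assert ghat[0] == pytest.approx(1.0)

    def test_ground_truth_recorded_in_metadata(self):
        spec = MotionSpec(kind="cone_restricted_rotor", S2_target=0.49,
                          tau_M=300.0, tau_i=6.0, dt=1.0, n_steps=100,
                          n_pairs=2, seed=4)
        meta = generate_cone_restricted_rotor(spec).metadata
        assert meta["S2"] == 0.49
        assert meta["tau_M"] == 300.0


class TestTranslationalBrownian:
    def test_msd_slope_recovers_D(self):
        """Einstein relation: MSD = 6 D t; estimator within 5% of truth."""
        spec = MotionSpec(kind="translational_brownian", D=2e-5, dt=0.5,
                          n_steps=10_000, n_pairs=100, seed=3)
        traj = generate_translational_brownian(spec)
        centres = 0.5 * (traj.positions[:, 0::2] + traj.positions[:, 1::2])
        D = estimate_diffusion(centres, traj.dt)
        assert abs(D / 2e-5 - 1.0) < 0.05

    def test_zero_diffusion_freezes_all_frames(self):
        spec = MotionSpec(kind="translational_brownian", D=0.0, dt=0.5,
                          n_steps=50, n_pairs=3, seed=1)
        traj = generate_translational_brownian(spec)
        assert np.all(traj.positions == traj.positions[0])

    def test_msd_nonnegative_and_zero_at_origin(self):
        spec = MotionSpec(kind="translational_brownian", D=1e-5, dt=0.5,
                          n_steps=300, n_pairs=5, seed=8)
        traj = generate_translational_brownian(spec)
        m = msd(0.5 * (traj.positions[:, 0::2] + traj.positions[:, 1::2]))
        assert m[0] == 0.0
        assert np.all(m >= -1e-12)


class TestWaterSlab:
    def test_positions_confined_to_slab(self, slab_traj_wall_slowed):
        z = slab_traj_wall_slowed.positions[:, :, 2]
        W = slab_traj_wall_slowed.metadata["slab_width"]
        assert z.min() >= 0.0 and z.max() <= W

    def test_flat_profile_recovers_uniform_D(self, slab_traj_flat):
        pos = slab_traj_flat.positions
        centres = 0.5 * (pos[:, 0::2] + pos[:, 1::2])
        # z is reflected; use the free x, y axes for the MSD estimate
        xy = centres.copy()
        xy[:, :, 2] = 0.0
        m = msd(xy)
        n = m.size
        lo, hi = max(1, int(0.002 * n)), int(0.02 * n)
        slope = np.polyfit(np.arange(lo, hi) * slab_traj_flat.dt, m[lo:hi], 1)[0]
        D = slope / 4.0 * 1e-2  # two free axes
        assert abs(D / 2e-5 - 1.0) < 0.10

    def test_profile_stored_in_metadata(self, slab_traj_wall_slowed):
        meta = slab_traj_wall_slowed.metadata
        tau = np.asarray(meta["profile_tau_c"])
        assert tau[0] > tau[len(tau) // 2]  # slower at the wall
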