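import numpy as np
import pytest

from spinrelax.synthetic import (MobilityProfile, MotionSpec,
                                 generate_isotropic_rotor, generate_water_slab)


@pytest.fixture(scope="session")
def iso_rotor_traj():
    """Isotropic rotors, tau_c = 10 ps: oracle for exponential rank-2 decay."""
    spec = MotionSpec(kind="isotropic_rotor", tau_c=10.0, dt=0.1,
                      n_steps=100_000, n_pairs=16, seed=42)
    return generate_isotropic_rotor(spec)


@pytest.fixture(scope="session")
def slab_traj_wall_slowed():
    """Water slab with tau_c 10x larger at the walls than in the centre."""
    W = 4.0

    def tau_c(z):
        x = 2.0 * np.asarray(z) / W - 1.0
        return 2.0 + 18.0 * x**2

    def D(z):
        x = 2.0 * np.asarray(z) / W - 1.0
        return 2e-5 * (1.0 - 0.8 * x**2)

    spec = MotionSpec(kind="water_slab", slab_width=W,
                      mobility_profile=MobilityProfile(tau_c=tau_c, D=D),
                      n_pairs=150, dt=0.5, n_steps=8000, seed=5)
    return generate_water_slab(spec)


@pytest.fixture(scope="session")
def slab_traj_flat():
    """Degenerate slab: uniform mobility everywhere."""
    spec = MotionSpec(
        kind="water_slab", slab_width=4.0,
        mobility_profile=MobilityProfile(
            tau_c=lambda z: np.full_like(np.asarray(z, float), 5.0),
            D=lambda z: np.full_like(np.asarray(z, float), 2e-5)),
        n_pairs=120, dt=0.5, n_steps=6000, seed=17)
    return generate_water_slab(spec)


@pytest.fixture
def two_pool_traj():
    """Tiny mixed WP/MP random-walk system for cross-pool rate checks."""
    rng = np.random.default_rng(3)
    n_frames, n_atoms = 200, 5
    positions = np.cumsum(rng.standard_normal((n_frames, n_atoms, 3)) * 0.02,
                          axis=0)
    positions += rng.uniform(0, 1.0, size=(1, n_atoms, 3))
    from spinrelax.trajectory import SpinTrajectory
    return SpinTrajectory(
        positions=positions, dt=1.0,
        molecule_id=np.array([0, 0, 1, 1, 1]),
        pool=np.array(["WP", "WP", "MP", "MP", "MP"]),
        species=np.array(["SOL", "SOL", "LIP", "LIP", "LIP"]))
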