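"""Synthetic hydrogen-pair trajectories with known motional ground truth.

Every generator produces a :class:`~spinrelax.trajectory.SpinTrajectory`
whose motional parameters are prescribed and recorded in the trajectory
metadata, so each downstream stage (correlation, model-free fit, rates,
profiles) has an analytic or recorded oracle:

* ``isotropic_rotor`` — rigid H-H pairs tumbling by rotational Brownian
  motion with correlation time tau_c; the rank-2 orientational correlation
  decays as exp(-tau/tau_c) = exp(-6 D_r tau).
* ``cone_restricted_rotor`` — wobbling-in-a-cone internal motion (order
  parameter S^2, timescale tau_i) superimposed on global isotropic tumbling
  (tau_M); the normalized correlation approaches the two-exponential
  model-free form.
* ``translational_brownian`` — free 3D Brownian paths with diffusion
  coefficient D (Einstein relation MSD = 6 D t).
* ``water_slab`` — rigid pairs diffusing between reflecting walls with a
  position-dependent mobility (slower tau_c and D near the walls), emulating
  water confined between membrane surfaces.

These are statistically controlled motions, not physics-grade molecular
dynamics: no forces, no interactions between molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .trajectory import SpinTrajectory

__all__ = [
    "MotionSpec",
    "MobilityProfile",
    "generate",
    "generate_isotropic_rotor",
    "generate_cone_restricted_rotor",
    "generate_translational_brownian",
    "generate_water_slab",
    "cone_half_angle_for_S2",
]

_KINDS = ("isotropic_rotor", "cone_restricted_rotor",
          "translational_brownian", "water_slab")

#: spacing between molecule centres (nm); with r^-6 coupling and sub-nm pair
#: distances, inter-molecular dipolar terms at this spacing are ~1e-16 of the
#: intra-pair term, so isolated-pair oracles apply even under all-pair sums
_CENTRE_SPACING = 50.0

#: refuse rotational steps whose per-axis angular variance exceeds this
_MAX_STEP_VARIANCE = 0.1  # rad^2


@dataclass
class MobilityProfile:
    """Maps slab coordinate z (nm) to local tau_c (ps) and D (cm^2/s)."""

    tau_c: Callable[[np.ndarray], np.ndarray]
    D: Callable[[np.ndarray], np.ndarray]


@dataclass
class MotionSpec:
    """Parameters of one synthetic motion; units: nm, ps, cm^2/s for D."""

    kind: str
    tau_c: float | None = None        # ps (isotropic_rotor)
    S2_target: float | None = None    # dimensionless (cone)
    tau_M: float | None = None        # ps (cone)
    tau_i: float | None = None        # ps (cone)
    D: float | None = None            # cm^2/s (brownian, slab)
    pair_distance: float = 0.158      # nm
    slab_width: float | None = None   # nm (slab)
    mobility_profile: MobilityProfile | None = None
    n_pairs: int = 1
    dt: float = 1.0                   # ps
    n_steps: int = 1000
    seed: int = 0
    pool: str = "WP"

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.pair_distance <= 0:
            raise ValueError("pair_distance must be positive")
        if self.n_steps < 1 or self.n_pairs < 1:
            raise ValueError("n_steps and n_pairs must be >= 1")
        if self.kind == "isotropic_rotor":
            if self.tau_c is None or self.tau_c <= 0:
                raise ValueError("isotropic_rotor requires tau_c > 0")
        elif self.kind == "cone_restricted_rotor":
            if self.S2_target is None or not 0 < self.S2_target <= 1:
                raise ValueError(
                    "cone_restricted_rotor requires S2_target in (0, 1] "
                    "(use isotropic_rotor for the S2 = 0 limit)")
            if self.tau_M is None or self.tau_M <= 0:
                raise ValueError("cone_restricted_rotor requires tau_M > 0")
            if self.S2_target < 1:
                if self.tau_i is None or self.tau_i <= 0:
                    raise ValueError("cone_restricted_rotor requires tau_i > 0")
                if not self.tau_i < self.tau_M:
                    raise ValueError("timescale separation requires tau_i < tau_M")
        elif self.kind == "translational_brownian":
            if self.D is None or self.D < 0:
                raise ValueError("translational_brownian requires D >= 0")
        elif self.kind == "water_slab":
            if self.slab_width is None or self.slab_width <= 0:
                raise ValueError("water_slab requires slab_width > 0")
            if self.mobility_profile is None:
                raise ValueError("water_slab requires a mobility_profile")

    @property
    def n_molecules(self) -> int:
        return self.n_pairs


def _rng(spec: MotionSpec) -> np.random.Generator:
    # counter-based stream: one master key, reproducible and parallel-safe
    return np.random.Generator(np.random.Philox(key=spec.seed))


def _random_unit_vectors(rng, n) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _apply_rotvec(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rotate unit vectors u by rotation vectors w (Rodrigues), rowwise."""
    angle = np.linalg.norm(w, axis=1, keepdims=True)
    small = angle[:, 0] < 1e-12
    axis = np.where(small[:, None], 0.0, w / np.where(angle == 0, 1.0, angle))
    c = np.cos(angle)
    s = np.sin(angle)
    cross = np.cross(axis, u)
    dot = np.sum(axis * u, axis=1, keepdims=True)
    out = u * c + cross * s + axis * dot * (1.0 - c)
    out[small] = u[small]
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _centres(n: int) -> np.ndarray:
    """Widely spaced static molecule centres on a cubic grid."""
    side = int(np.ceil(n ** (1 / 3)))
    idx = np.arange(n)
    grid = np.stack([idx % side, (idx // side) % side, idx // side**2], axis=1)
    return grid.astype(float) * _CENTRE_SPACING


def _pair_positions(centres: np.ndarray, u: np.ndarray, d: float) -> np.ndarray:
    """(n_pairs, 3) centres and orientations -> (2*n_pairs, 3) H positions."""
    half = 0.5 * d * u
    pos = np.empty((2 * centres.shape[0], 3))
    pos[0::2] = centres + half
    pos[1::2] = centres - half
    return pos


def _pair_trajectory(spec, positions, metadata) -> SpinTrajectory:
    n = spec.n_pairs
    mol = np.repeat(np.arange(n), 2)
    pool = np.full(2 * n, spec.pool, dtype="U2")
    species = np.full(2 * n, "SYN", dtype="U16")
    return SpinTrajectory(positions, spec.dt, mol, pool, species=species,
                          box=None, metadata=metadata)


def _check_rotation_step(tau_c: float, dt: float) -> float:
    D_r = 1.0 / (6.0 * tau_c)
    var = 2.0 * D_r * dt
    if var > _MAX_STEP_VARIANCE:
        raise ValueError(
            f"rotational step variance 2*D_r*dt = {var:.3g} rad^2 exceeds "
            f"{_MAX_STEP_VARIANCE}; decrease dt relative to tau_c "
            "(coarse steps bias the orientational decay)")
    return var


def generate_isotropic_rotor(spec: MotionSpec) -> SpinTrajectory:
    """Rigid pairs whose orientation performs free rotational Brownian motion.

    D_r = 1/(6 tau_c); each step applies a random rotation with per-axis
    angular variance 2 D_r dt. The stationary orientation distribution is
    uniform on the sphere and <P2(u(0).u(tau))> = exp(-tau/tau_c).
    """
    if spec.kind != "isotropic_rotor":
        raise ValueError("spec.kind must be 'isotropic_rotor'")
    rng = _rng(spec)
    n = spec.n_pairs
    u = _random_unit_vectors(rng, n)
    centres = _centres(n)
    us = np.empty((spec.n_steps, n, 3))
    us[0] = u
    if spec.n_steps > 1:
        sigma = np.sqrt(_check_rotation_step(spec.tau_c, spec.dt))
        t = 1
        chunk = 20_000  # bounds the precomputed rotation-matrix block
        while t < spec.n_steps:
            m = min(chunk, spec.n_steps - t)
            w = rng.standard_normal((m, n, 3)) * sigma
            M = _rotmat_from_rotvec(w.reshape(-1, 3)).reshape(m, n, 3, 3)
            for k in range(m):
                u = np.einsum("nij,nj->ni", M[k], u)
                us[t + k] = u
            t += m
    half = 0.5 * spec.pair_distance * us
    positions = np.empty((spec.n_steps, 2 * n, 3))
    positions[:, 0::2, :] = centres[None, :, :] + half
    positions[:, 1::2, :] = centres[None, :, :] - half
    meta = {"kind": spec.kind, "tau_c": spec.tau_c,
            "pair_distance": spec.pair_distance, "dt": spec.dt,
            "seed": spec.seed}
    return _pair_trajectory(spec, positions, meta)


def cone_half_angle_for_S2(S2: float) -> float:
    """Cone half-angle beta such that [cos(beta)(1+cos(beta))/2]^2 = S2.

    The standard order parameter of a vector uniformly distributed inside a
    cone; solving the quadratic in cos(beta) gives
    cos(beta) = (-1 + sqrt(1 + 8 sqrt(S2))) / 2.
    """
    if not 0 < S2 <= 1:
        raise ValueError("S2 must be in (0, 1]")
    c = (-1.0 + np.sqrt(1.0 + 8.0 * np.sqrt(S2))) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _rotmat_from_rotvec(w: np.ndarray) -> np.ndarray:
    """Rotation matrices (n,3,3) from rotation vectors (n,3)."""
    n = w.shape[0]
    angle = np.linalg.norm(w, axis=1)
    axis = np.where(angle[:, None] < 1e-15, 0.0,
                    w / np.where(angle[:, None] == 0, 1.0, angle[:, None]))
    K = np.zeros((n, 3, 3))
    K[:, 0, 1] = -axis[:, 2]
    K[:, 0, 2] = axis[:, 1]
    K[:, 1, 0] = axis[:, 2]
    K[:, 1, 2] = -axis[:, 0]
    K[:, 2, 0] = -axis[:, 1]
    K[:, 2, 1] = axis[:, 0]
    eye = np.broadcast_to(np.eye(3), (n, 3, 3))
    s = np.sin(angle)[:, None, None]
    c = np.cos(angle)[:, None, None]
    return eye + s * K + (1.0 - c) * (K @ K)


def generate_cone_restricted_rotor(spec: MotionSpec) -> SpinTrajectory:
    """Wobble-in-a-cone internal motion on top of global isotropic tumbling.

    The internal H-H vector diffuses on the unit sphere restricted (by
    reflection) to a cone whose half-angle is chosen so that the uniform-cone
    order parameter equals ``S2_target``; the cone frame itself tumbles
    isotropically with correlation time ``tau_M``. The resulting rank-2
    correlation approximates S^2 exp(-tau/tau_M) + (1-S^2) exp(-tau/tau_eff).
    Ground truth (S^2, tau_M, tau_i) is recorded in the metadata.
    """
    if spec.kind != "cone_restricted_rotor":
        raise ValueError("spec.kind must be 'cone_restricted_rotor'")
    if spec.S2_target == 1.0:
        # rigid limit: pure global rotor
        sub = MotionSpec(kind="isotropic_rotor", tau_c=spec.tau_M,
                         pair_distance=spec.pair_distance, n_pairs=spec.n_pairs,
                         dt=spec.dt, n_steps=spec.n_steps, seed=spec.seed,
                         pool=spec.pool)
        traj = generate_isotropic_rotor(sub)
        traj.metadata.update({"kind": spec.kind, "S2": 1.0, "tau_M": spec.tau_M,
                              "tau_i": spec.tau_i})
        return traj
    rng = _rng(spec)
    n = spec.n_pairs
    beta = cone_half_angle_for_S2(spec.S2_target)
    cos_beta = np.cos(beta)

    # initial internal vectors: uniform inside the cone (molecular frame)
    cpsi = rng.uniform(cos_beta, 1.0, size=n)
    spsi = np.sqrt(1.0 - cpsi**2)
    az = rng.uniform(-np.pi, np.pi, size=n)
    v = np.stack([spsi * np.cos(az), spsi * np.sin(az), cpsi], axis=1)

    # initial global frames: uniform random rotations
    R = _rotmat_from_rotvec(rng.standard_normal((n, 3)))
    w0 = _random_unit_vectors(rng, n) * rng.uniform(0, np.pi, size=(n, 1))
    R = _rotmat_from_rotvec(w0) @ R

    sig_M = np.sqrt(_check_rotation_step(spec.tau_M, spec.dt))
    sig_i = np.sqrt(_check_rotation_step(spec.tau_i, spec.dt))

    centres = _centres(n)
    positions = np.empty((spec.n_steps, 2 * n, 3))
    u = np.einsum("nij,nj->ni", R, v)
    positions[0] = _pair_positions(centres, u, spec.pair_distance)
    for t in range(1, spec.n_steps):
        # internal wobble, reflected at the cone boundary
        v = _apply_rotvec(v, rng.standard_normal((n, 3)) * sig_i)
        psi = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
        out = psi > beta
        if np.any(out):
            psi_new = np.clip(2.0 * beta - psi[out], 0.0, beta)
            phi = np.arctan2(v[out, 1], v[out, 0])
            v[out, 0] = np.sin(psi_new) * np.cos(phi)
            v[out, 1] = np.sin(psi_new) * np.sin(phi)
            v[out, 2] = np.cos(psi_new)
        # global tumbling
        R = _rotmat_from_rotvec(rng.standard_normal((n, 3)) * sig_M) @ R
        u = np.einsum("nij,nj->ni", R, v)
        positions[t] = _pair_positions(centres, u, spec.pair_distance)
    meta = {"kind": spec.kind, "S2": spec.S2_target, "tau_M": spec.tau_M,
            "tau_i": spec.tau_i, "cone_half_angle": beta,
            "pair_distance": spec.pair_distance, "dt": spec.dt,
            "seed": spec.seed}
    return _pair_trajectory(spec, positions, meta)


def generate_translational_brownian(spec: MotionSpec) -> SpinTrajectory:
    """Free 3D Brownian paths: per-step displacement variance 2 D dt per axis.

    Each molecule carries a rigid H-H pair with a fixed random orientation;
    the centre follows the Brownian path (MSD = 6 D t).
    """
    if spec.kind != "translational_brownian":
        raise ValueError("spec.kind must be 'translational_brownian'")
    rng = _rng(spec)
    n = spec.n_pairs
    D_nm = spec.D * 1e2  # cm^2/s -> nm^2/ps
    sigma = np.sqrt(2.0 * D_nm * spec.dt)
    steps = rng.standard_normal((spec.n_steps - 1, n, 3)) * sigma \
        if spec.n_steps > 1 else np.zeros((0, n, 3))
    centres = _centres(n)[None, :, :] + np.concatenate(
        [np.zeros((1, n, 3)), np.cumsum(steps, axis=0)], axis=0)
    u = _random_unit_vectors(rng, n)
    half = 0.5 * spec.pair_distance * u
    positions = np.empty((spec.n_steps, 2 * n, 3))
    positions[:, 0::2, :] = centres + half
    positions[:, 1::2, :] = centres - half
    meta = {"kind": spec.kind, "D": spec.D, "dt": spec.dt, "seed": spec.seed,
            "pair_distance": spec.pair_distance}
    return _pair_trajectory(spec, positions, meta)


def _reflect(z: np.ndarray, width: float) -> np.ndarray:
    """Reflecting boundaries at 0 and width (triangle-wave fold)."""
    m = np.mod(z, 2.0 * width)
    return np.where(m <= width, m, 2.0 * width - m)


def generate_water_slab(spec: MotionSpec) -> SpinTrajectory:
    """Rigid pairs in a slab with position-dependent mobility.

    Centres perform Brownian motion with local D(z) between reflecting walls
    at z = 0 and z = slab_width (x, y unbounded); pair orientations tumble
    with local tau_c(z). A wall-slowed profile (larger tau_c, smaller D near
    the walls) emulates water confined between membrane surfaces. The profile
    is sampled on a grid into the metadata for recovery tests.
    """
    if spec.kind != "water_slab":
        raise ValueError("spec.kind must be 'water_slab'")
    prof = spec.mobility_profile
    W = spec.slab_width
    zgrid = np.linspace(0.0, W, 33)
    tau_grid = np.asarray(prof.tau_c(zgrid), dtype=float)
    D_grid = np.asarray(prof.D(zgrid), dtype=float)
    if np.any(tau_grid <= 0) or np.any(D_grid <= 0):
        raise ValueError("mobility profile must be strictly positive")
    _check_rotation_step(float(tau_grid.min()), spec.dt)

    rng = _rng(spec)
    n = spec.n_pairs
    # centres stay half a pair length clear of the walls so no hydrogen
    # ever leaves [0, slab_width] in z
    zlo = 0.5 * spec.pair_distance
    if W <= 2 * zlo:
        raise ValueError("slab_width must exceed the pair distance")
    centres = np.empty((n, 3))
    centres[:, 0] = rng.uniform(0, W, n)
    centres[:, 1] = rng.uniform(0, W, n)
    centres[:, 2] = rng.uniform(zlo, W - zlo, n)
    u = _random_unit_vectors(rng, n)

    positions = np.empty((spec.n_steps, 2 * n, 3))
    positions[0] = _pair_positions(centres, u, spec.pair_distance)
    for t in range(1, spec.n_steps):
        z = centres[:, 2]
        D_nm = np.asarray(prof.D(z), dtype=float) * 1e2  # cm^2/s -> nm^2/ps
        sigma_t = np.sqrt(2.0 * D_nm * spec.dt)
        centres = centres + rng.standard_normal((n, 3)) * sigma_t[:, None]
        centres[:, 2] = zlo + _reflect(centres[:, 2] - zlo, W - 2 * zlo)
        tau_local = np.asarray(prof.tau_c(centres[:, 2]), dtype=float)
        sig_rot = np.sqrt(spec.dt / (3.0 * tau_local))  # sqrt(2 D_r dt)
        u = _apply_rotvec(u, rng.standard_normal((n, 3)) * sig_rot[:, None])
        positions[t] = _pair_positions(centres, u, spec.pair_distance)
    meta = {"kind": spec.kind, "slab_width": W, "dt": spec.dt,
            "seed": spec.seed, "pair_distance": spec.pair_distance,
            "profile_z": zgrid, "profile_tau_c": tau_grid,
            "profile_D": D_grid}
    return _pair_trajectory(spec, positions, meta)


_GENERATORS = {
    "isotropic_rotor": generate_isotropic_rotor,
    "cone_restricted_rotor": generate_cone_restricted_rotor,
    "translational_brownian": generate_translational_brownian,
    "water_slab": generate_water_slab,
}


def generate(spec: MotionSpec) -> SpinTrajectory:
    """Dispatch to the generator matching ``spec.kind``."""
    return _GENERATORS[spec.kind](spec)
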