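"""Hydrogen-nucleus trajectories: container, I/O, pool assignment, recomposition.

The central container is :class:`SpinTrajectory`: a time-ordered block of 3D
hydrogen positions (nm) sampled at a constant interval ``dt`` (ps), with a
molecule grouping, an optional orthorhombic periodic box and a per-nucleus
pool label (``"WP"`` for the water pool, ``"MP"`` for the macromolecular
pool). The main magnetic field B0 is taken along +z.

Two input routes exist: an internal plain-text columnar format (written by
the synthetic generators, round-trips float64 exactly) and standard MD
formats (GRO/PDB topology plus XTC/TRR/DCD coordinates) read through
MDAnalysis with a hydrogen-selection rule.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpinTrajectory",
    "PoolAssignment",
    "read_trajectory",
    "write_trajectory",
    "assign_pools",
    "recompose_molecules",
    "mass_composition_report",
    "minimum_image",
    "parse_formula",
    "molecular_mass",
]

_MAGIC = "SPINTRAJ 1"

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "Na": 22.990, "Cl": 35.45, "K": 39.098,
}

WATER_FORMULA = "H2O"


@dataclass
class SpinTrajectory:
    """Time-ordered hydrogen positions with pool labels.

    Parameters
    ----------
    positions : (n_frames, n_atoms, 3) float array, nm
    dt : sampling interval, ps
    molecule_id : (n_atoms,) int array grouping nuclei into molecules
    pool : (n_atoms,) unicode array, each ``"WP"``, ``"MP"`` or ``""``
    species : (n_atoms,) unicode array of molecule species names (optional)
    box : (3,) orthorhombic box edge lengths in nm, or None (non-periodic)
    metadata : free-form dict; synthetic generators record ground truth here
    """

    positions: np.ndarray
    dt: float
    molecule_id: np.ndarray
    pool: np.ndarray
    species: np.ndarray | None = None
    box: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.pool = np.asarray(self.pool, dtype="U2")
        if self.species is not None:
            self.species = np.asarray(self.species, dtype="U16")
            if self.species.shape != (self.n_atoms,):
                raise ValueError("species length mismatch")
        if self.molecule_id.shape != (self.n_atoms,):
            raise ValueError("molecule_id length mismatch")
        if self.pool.shape != (self.n_atoms,):
            raise ValueError("pool length mismatch")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box edges must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Time span (n_frames - 1) * dt in ps."""
        return (self.n_frames - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def pool_indices(self, pool: str) -> np.ndarray:
        return np.flatnonzero(self.pool == pool)

    def pool_counts(self) -> dict:
        labels, counts = np.unique(self.pool, return_counts=True)
        return {l: int(c) for l, c in zip(labels, counts) if l}


@dataclass
class PoolAssignment:
    """Species -> pool mapping with resulting per-pool hydrogen counts."""

    rule: dict
    counts: dict = field(default_factory=dict)


def minimum_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image displacement for an orthorhombic box (no-op if box is None)."""
    if box is None:
        return d
    return d - box * np.round(d / box)


# ---------------------------------------------------------------------------
# internal plain-text format
# ---------------------------------------------------------------------------

def write_trajectory(traj: SpinTrajectory, path) -> None:
    """Write the internal columnar text format.

    Layout: a small header (atom count, frame count, dt, box, JSON metadata),
    an atom table (index, molecule, species, pool), then per-frame coordinate
    blocks written with %.17g so float64 values round-trip exactly.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"{_MAGIC}\n")
    buf.write(f"natoms {traj.n_atoms}\n")
    buf.write(f"nframes {traj.n_frames}\n")
    buf.write(f"dt {traj.dt:.17g}\n")
    if traj.box is None:
        buf.write("box none\n")
    else:
        buf.write("box " + " ".join(f"{x:.17g}" for x in traj.box) + "\n")
    buf.write("meta " + json.dumps(traj.metadata, default=_json_default) + "\n")
    buf.write("atoms\n")
    species = traj.species if traj.species is not None else [""] * traj.n_atoms
    for i in range(traj.n_atoms):
        buf.write(f"{i} {traj.molecule_id[i]} {species[i] or '-'} {traj.pool[i] or '-'}\n")
    buf.write("frames\n")
    for f in range(traj.n_frames):
        np.savetxt(buf, traj.positions[f], fmt="%.17g")
    path.write_text(buf.getvalue())


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _read_internal(path: Path) -> SpinTrajectory:
    lines = path.read_text().splitlines()
    if not lines or lines[0] != _MAGIC:
        raise ValueError(f"{path}: not an internal spinrelax trajectory")
    header = {}
    i = 1
    while not lines[i].startswith("atoms"):
        key, _, val = lines[i].partition(" ")
        header[key] = val
        i += 1
    n_atoms = int(header["natoms"])
    n_frames = int(header["nframes"])
    dt = float(header["dt"])
    box = None if header["box"] == "none" else np.array(
        [float(x) for x in header["box"].split()])
    metadata = json.loads(header.get("meta", "{}"))
    i += 1
    mol = np.empty(n_atoms, dtype=np.int64)
    species = np.empty(n_atoms, dtype="U16")
    pool = np.empty(n_atoms, dtype="U2")
    for a in range(n_atoms):
        idx, m, sp, pl = lines[i + a].split()
        mol[int(idx)] = int(m)
        species[int(idx)] = "" if sp == "-" else sp
        pool[int(idx)] = "" if pl == "-" else pl
    i += n_atoms
    if lines[i] != "frames":
        raise ValueError(f"{path}: malformed atom table (line {i + 1})")
    i += 1
    coords = np.loadtxt(lines[i:], dtype=np.float64)
    if coords.size != n_frames * n_atoms * 3:
        raise ValueError(
            f"{path}: expected {n_frames * n_atoms} coordinate rows, "
            f"got {coords.size // 3}")
    positions = coords.reshape(n_frames, n_atoms, 3)
    return SpinTrajectory(positions, dt, mol, pool, species=species, box=box,
                          metadata=metadata)


# ---------------------------------------------------------------------------
# MD formats via MDAnalysis
# ---------------------------------------------------------------------------

def _read_md(topology, coordinates, hydrogen_selection) -> SpinTrajectory:
    import MDAnalysis as mda

    u = mda.Universe(str(topology), *(str(c) for c in coordinates))
    if hydrogen_selection is None:
        # element field when the topology has one, name prefix otherwise
        try:
            hyd = u.select_atoms("element H")
        except Exception:
            hyd = u.select_atoms("name H*")
    else:
        try:
            hyd = u.select_atoms(hydrogen_selection)
        except Exception as exc:
            raise ValueError(
                f"hydrogen selection {hydrogen_selection!r} failed: {exc}")
    if len(hyd) == 0:
        raise ValueError("hydrogen selection matched no atoms")
    n_frames = len(u.trajectory)
    positions = np.empty((n_frames, len(hyd), 3))
    times = np.empty(n_frames)
    box = None
    for k, ts in enumerate(u.trajectory):
        positions[k] = hyd.positions * 0.1  # Angstrom -> nm
        times[k] = ts.time
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = np.asarray(ts.dimensions[:3], dtype=float) * 0.1
    if n_frames > 1:
        steps = np.diff(times)
        dt = steps[0]
        bad = np.flatnonzero(~np.isclose(steps, dt, rtol=1e-6, atol=1e-9))
        if bad.size:
            raise ValueError(
                f"inconsistent frame timestamps: step {bad[0] + 1} "
                f"(t={times[bad[0] + 1]} ps) differs from dt={dt} ps")
        if dt <= 0:
            dt = 1.0  # formats without time information default to 1 ps
    else:
        dt = 1.0
    species = np.array([getattr(a, "resname", "") for a in hyd], dtype="U16")
    mol = np.asarray(hyd.resids, dtype=np.int64)
    pool = np.full(len(hyd), "", dtype="U2")
    return SpinTrajectory(positions, dt, mol, pool, species=species, box=box)


def read_trajectory(path, fmt: str = "internal", coordinates=None,
                    hydrogen_selection: str | None = None):
    """Read a trajectory, keeping only hydrogen nuclei.

    Parameters
    ----------
    path : topology file (GRO/PDB) or internal-format file
    fmt : "internal" or "md"
    coordinates : for fmt="md", one or more coordinate files (XTC/TRR/DCD);
        omit to use coordinates from the topology file itself
    hydrogen_selection : MDAnalysis selection string identifying hydrogens;
        defaults to the element field, falling back to the "H" name prefix
        for topologies (like GRO) that carry no element information
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    if fmt == "internal":
        return _read_internal(path)
    if fmt == "md":
        coords = coordinates if coordinates is not None else []
        if isinstance(coords, (str, Path)):
            coords = [coords]
        return _read_md(path, coords, hydrogen_selection)
    raise ValueError(f"unknown trajectory format: {fmt!r}")


# ---------------------------------------------------------------------------
# pools, recomposition, composition report
# ---------------------------------------------------------------------------

def assign_pools(traj: SpinTrajectory, rule: PoolAssignment | dict) -> SpinTrajectory:
    """Populate pool labels from a species -> pool rule; returns traj (mutated).

    Every species present must be covered; each nucleus lands in exactly one
    pool, so the pool sizes always partition the hydrogen count.
    """
    mapping = rule.rule if isinstance(rule, PoolAssignment) else rule
    if traj.species is None:
        raise ValueError("trajectory has no species information to assign pools by")
    present = set(np.unique(traj.species)) - {""}
    unknown = sorted(present - set(mapping))
    if unknown:
        raise ValueError(f"species without pool assignment: {', '.join(unknown)}")
    for sp in present:
        traj.pool[traj.species == sp] = mapping[sp]
    counts = traj.pool_counts()
    if isinstance(rule, PoolAssignment):
        rule.counts = counts
    return traj


def recompose_molecules(traj: SpinTrajectory) -> SpinTrajectory:
    """Make molecules whole across periodic boundaries.

    Within each molecule every atom is shifted by integer box vectors so that
    it sits within half a box length of the molecule's first atom, frame by
    frame. Idempotent; a non-periodic trajectory is returned unchanged.
    Minimum-image pair distances are invariant under these shifts.
    """
    if traj.box is None:
        return traj
    import warnings
    pos = traj.positions
    for m in np.unique(traj.molecule_id):
        idx = np.flatnonzero(traj.molecule_id == m)
        if idx.size < 2:
            continue
        ref = pos[:, idx[0], :]
        d = pos[:, idx, :] - ref[:, None, :]
        pos[:, idx, :] = ref[:, None, :] + minimum_image(d, traj.box)
        extent = np.abs(minimum_image(d, traj.box)).max()
        if extent > traj.box.min() / 2 * 0.999:
            warnings.warn(
                f"molecule {m}: extent {extent:.3g} nm close to half the box; "
                "recomposition may be ambiguous")
    return traj


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict:
    """Parse a molecular formula like ``C40H80NO8P`` into element counts."""
    counts: dict = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        if not m.group(0):
            break
        el, n = m.group(1), m.group(2)
        if el not in ATOMIC_MASSES:
            raise ValueError(f"unknown element {el!r} in {formula!r}")
        counts[el] = counts.get(el, 0) + (int(n) if n else 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def molecular_mass(formula: str) -> float:
    """Molecular mass in g/mol from a formula string."""
    return sum(ATOMIC_MASSES[el] * n for el, n in parse_formula(formula).items())


def mass_composition_report(species_formulas: dict, species_counts: dict,
                            n_waters: int, ion_formulas: dict | None = None) -> dict:
    """Water mass fraction of a solvated membrane system.

    ``species_formulas`` maps species name -> formula, ``species_counts`` the
    total copy number of each; ``ion_formulas`` maps ion formula -> count.
    Returns a dict with per-component masses (g/mol of system) and
    ``water_mass_fraction`` = m_water / (m_water + m_macro + m_ions).
    """
    m_water = n_waters * molecular_mass(WATER_FORMULA)
    m_macro = sum(molecular_mass(species_formulas[sp]) * n
                  for sp, n in species_counts.items())
    m_ions = sum(molecular_mass(f) * n for f, n in (ion_formulas or {}).items())
    total = m_water + m_macro + m_ions
    return {
        "water_mass": m_water,
        "macromolecule_mass": m_macro,
        "ion_mass": m_ions,
        "water_mass_fraction": m_water / total if total > 0 else 0.0,
    }
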