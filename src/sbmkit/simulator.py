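"""Energy/force evaluation and Langevin dynamics in reduced units.

Units: length Angstrom, energy eps, mass 1 per atom, time sqrt(m A^2 / eps),
temperature in eps/k_B.  The integrator is the BAOAB splitting of Langevin
dynamics; with friction = 0 it reduces exactly to velocity Verlet, which is
used for energy-conservation checks.  Trajectories are bit-reproducible for a
fixed seed, configuration and force field.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .builder import ForceField, _pair_key

logger = logging.getLogger(__name__)

ENERGY_BLOWUP_THRESHOLD = 1.0e8  # eps
MIN_PAIR_DISTANCE = 1.0e-6       # A

TERM_NAMES = (
    "bonds", "angles", "impropers", "planars", "dihedrals",
    "contacts", "noncontacts", "restraints",
)


@dataclasses.dataclass
class SimConfig:
    """Langevin run configuration (reduced units)."""

    temperature: float = 0.5   # eps/k_B
    timestep: float = 0.002    # reduced time
    friction: float = 1.0      # 1/reduced time
    n_steps: int = 1000
    save_interval: int = 100
    seed: int = 0
    restraints_active: bool = True

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.n_steps < 0 or self.save_interval <= 0:
            raise ValueError("invalid n_steps/save_interval")


@dataclasses.dataclass
class State:
    coordinates: np.ndarray
    velocities: np.ndarray | None = None
    step: int = 0


@dataclasses.dataclass
class Trajectory:
    """Saved coordinate frames plus the energy log of the producing run."""

    frames: np.ndarray           # (n_frames, n_atoms, 3)
    config: SimConfig
    ff_hash: str = ""
    energies: pd.DataFrame | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def to_dcd(self, path: str) -> None:
        """Write frames as a DCD file (coordinates in Angstrom)."""
        import MDAnalysis as mda

        n_atoms = self.frames.shape[1]
        u = mda.Universe.empty(n_atoms, trajectory=True)
        with mda.Writer(path, n_atoms) as w:
            for frame in self.frames:
                u.atoms.positions = frame
                w.write(u.atoms)


# ---------------------------------------------------------------------------------
# pairwise neighbor list for the non-contact repulsion
# ---------------------------------------------------------------------------------

class NeighborList:
    """Verlet list for the truncated non-contact repulsion.

    Candidate pairs within ``cutoff + skin`` are cached and refreshed once any
    atom has moved more than ``skin / 2`` since the last build.  Excluded
    pairs (bonded 1-2/1-3/1-4 and native contacts) never appear.
    """

    def __init__(self, ff: ForceField, skin: float = 0.5):
        self.cutoff = ff.nc_cutoff
        self.skin = skin
        n = ff.n_atoms
        self._n = n
        self._excl_keys = (
            _pair_key(ff.exclusions, n) if len(ff.exclusions) else np.empty(0, np.int64)
        )
        self._ref_coord: np.ndarray | None = None
        self.pairs = np.empty((0, 2), dtype=int)

    def update(self, coord: np.ndarray) -> np.ndarray:
        if self._ref_coord is not None:
            disp = np.max(np.linalg.norm(coord - self._ref_coord, axis=1))
            if disp <= self.skin / 2.0:
                return self.pairs
        tree = cKDTree(coord)
        pairs = tree.query_pairs(self.cutoff + self.skin, output_type="ndarray")
        if len(pairs):
            pairs = np.sort(pairs, axis=1)
            if len(self._excl_keys):
                keep = ~np.isin(_pair_key(pairs, self._n), self._excl_keys)
                pairs = pairs[keep]
        self.pairs = pairs.astype(int)
        self._ref_coord = coord.copy()
        return self.pairs


# ---------------------------------------------------------------------------------
# energy and analytic forces
# ---------------------------------------------------------------------------------

def _wrap_angle(x: np.ndarray) -> np.ndarray:
    return (x + np.pi) % (2.0 * np.pi) - np.pi


def _pair_terms(coord, idx, forces, dU_dr_fn, label):
    """Accumulate a generic distance-dependent pair term; returns energy."""
    if len(idx) == 0:
        return 0.0
    u = coord[idx[:, 0]] - coord[idx[:, 1]]
    r = np.linalg.norm(u, axis=1)
    if np.any(r < MIN_PAIR_DISTANCE):
        bad = idx[np.argmin(r)]
        raise ValueError(
            f"overlapping atoms in {label} term: pair {tuple(int(x) for x in bad)}"
        )
    energy, dU_dr = dU_dr_fn(r)
    f = (-dU_dr / r)[:, None] * u
    np.add.at(forces, idx[:, 0], f)
    np.add.at(forces, idx[:, 1], -f)
    return float(np.sum(energy))


def _angle_terms(coord, idx, theta0, w, forces):
    if len(idx) == 0:
        return 0.0
    i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
    u = coord[i] - coord[j]
    v = coord[k] - coord[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
    dU = w * (theta - theta0)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    dth_di = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
    dth_dk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
    fi = -dU[:, None] * dth_di
    fk = -dU[:, None] * dth_dk
    np.add.at(forces, i, fi)
    np.add.at(forces, k, fk)
    np.add.at(forces, j, -(fi + fk))
    return float(np.sum(0.5 * w * (theta - theta0) ** 2))


def _dihedral_angle_and_grads(coord, idx):
    """Dihedral angles and gradients w.r.t. the four atom positions."""
    i, j, k, l = idx[:, 0], idx[:, 1], idx[:, 2], idx[:, 3]
    b1 = coord[j] - coord[i]
    b2 = coord[k] - coord[j]
    b3 = coord[l] - coord[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / nb2[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = np.arctan2(y, x)
    n1_sq = np.einsum("ij,ij->i", n1, n1)
    n2_sq = np.einsum("ij,ij->i", n2, n2)
    dphi_di = (nb2 / n1_sq)[:, None] * n1
    dphi_dl = -(nb2 / n2_sq)[:, None] * n2
    c12 = (np.einsum("ij,ij->i", b1, b2) / nb2**2)[:, None]
    c32 = (np.einsum("ij,ij->i", b3, b2) / nb2**2)[:, None]
    dphi_dj = -(1.0 + c12) * dphi_di + c32 * dphi_dl
    dphi_dk = c12 * dphi_di - (1.0 + c32) * dphi_dl
    return phi, dphi_di, dphi_dj, dphi_dk, dphi_dl


def _torsion_terms(coord, idx, forces, energy_and_deriv):
    if len(idx) == 0:
        return 0.0
    phi, g_i, g_j, g_k, g_l = _dihedral_angle_and_grads(coord, idx)
    energy, dU_dphi = energy_and_deriv(phi)
    np.add.at(forces, idx[:, 0], -dU_dphi[:, None] * g_i)
    np.add.at(forces, idx[:, 1], -dU_dphi[:, None] * g_j)
    np.add.at(forces, idx[:, 2], -dU_dphi[:, None] * g_k)
    np.add.at(forces, idx[:, 3], -dU_dphi[:, None] * g_l)
    return float(np.sum(energy))


def dihedral_well(delta: np.ndarray) -> np.ndarray:
    """The proper-dihedral well F(x) = [1 - cos x] + 1/2 [1 - cos 3x]."""
    return (1.0 - np.cos(delta)) + 0.5 * (1.0 - np.cos(3.0 * delta))


def potential_energy_and_forces(
    ff: ForceField,
    coord: np.ndarray,
    include_restraints: bool = True,
    nc_pairs: np.ndarray | None = None,
):
    """Total potential energy, analytic forces, and a per-term breakdown.

    The breakdown dict (bonds/angles/impropers/planars/dihedrals/contacts/
    noncontacts/restraints) sums exactly to the returned total.  If
    ``nc_pairs`` is None the non-contact pair list is computed fresh.
    """
    coord = np.asarray(coord, dtype=float)
    if coord.shape != (ff.n_atoms, 3):
        raise ValueError(f"coordinates must have shape ({ff.n_atoms}, 3)")
    if not np.all(np.isfinite(coord)):
        raise ValueError("non-finite coordinates")

    forces = np.zeros_like(coord)
    b = ff.bonded
    breakdown: dict[str, float] = {}

    def harmonic_pair(w, r0):
        def fn(r):
            return 0.5 * w * (r - r0) ** 2, w * (r - r0)
        return fn

    breakdown["bonds"] = _pair_terms(
        coord, b.bonds_idx, forces, harmonic_pair(ff.bonds_w, b.bonds_r0), "bond"
    )
    breakdown["angles"] = _angle_terms(
        coord, b.angles_idx, b.angles_theta0, ff.angles_w, forces
    )

    def improper_fn(chi):
        d = _wrap_angle(chi - b.impropers_chi0)
        return 0.5 * ff.impropers_w * d**2, ff.impropers_w * d

    breakdown["impropers"] = _torsion_terms(coord, b.impropers_idx, forces, improper_fn)

    def planar_fn(chi):
        return ff.planars_w * (1.0 - np.cos(2.0 * chi)), 2.0 * ff.planars_w * np.sin(2.0 * chi)

    breakdown["planars"] = _torsion_terms(coord, b.planars_idx, forces, planar_fn)

    def proper_fn(phi):
        d = phi - b.dihedrals_phi0
        e = ff.dihedrals_w * dihedral_well(d)
        dU = ff.dihedrals_w * (np.sin(d) + 1.5 * np.sin(3.0 * d))
        return e, dU

    breakdown["dihedrals"] = _torsion_terms(coord, b.dihedrals_idx, forces, proper_fn)

    def contact_fn(r):
        s6 = (ff.contacts_sigma / r) ** 6
        e = ff.contacts_w * (s6**2 - 2.0 * s6)
        dU = -12.0 * ff.contacts_w * (s6**2 - s6) / r
        return e, dU

    breakdown["contacts"] = _pair_terms(coord, ff.contacts_idx, forces, contact_fn, "contact")

    if nc_pairs is None:
        nl = NeighborList(ff)
        nc_pairs = nl.update(coord)
    if len(nc_pairs):
        u = coord[nc_pairs[:, 0]] - coord[nc_pairs[:, 1]]
        r = np.linalg.norm(u, axis=1)
        if np.any(r < MIN_PAIR_DISTANCE):
            bad = nc_pairs[np.argmin(r)]
            raise ValueError(
                f"overlapping atoms in non-contact term: pair "
                f"{tuple(int(x) for x in bad)}"
            )
        inside = r < ff.nc_cutoff
        s12 = np.zeros_like(r)
        s12[inside] = (ff.sigma_nc / r[inside]) ** 12
        e = ff.eps_nc * s12
        dU_dr = np.where(inside, -12.0 * e / np.where(inside, r, 1.0), 0.0)
        f = (-dU_dr / r)[:, None] * u
        np.add.at(forces, nc_pairs[:, 0], f)
        np.add.at(forces, nc_pairs[:, 1], -f)
        breakdown["noncontacts"] = float(np.sum(e))
    else:
        breakdown["noncontacts"] = 0.0

    breakdown["restraints"] = 0.0
    if include_restraints and ff.restraints:
        idx = np.array([[r.i, r.j] for r in ff.restraints], dtype=int)
        r_min = np.array([r.r_min for r in ff.restraints])
        k = np.array([r.k for r in ff.restraints])
        breakdown["restraints"] = _pair_terms(
            coord, idx, forces, harmonic_pair(k, r_min), "restraint"
        )

    total = float(sum(breakdown.values()))
    return total, forces, breakdown


# ---------------------------------------------------------------------------------
# Langevin integration (BAOAB)
# ---------------------------------------------------------------------------------

def maxwell_boltzmann_velocities(
    n_atoms: int, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(max(temperature, 0.0)), size=(n_atoms, 3))


def kinetic_energy(velocities: np.ndarray) -> float:
    return 0.5 * float(np.sum(velocities**2))


def run_langevin(ff: ForceField, start: State, config: SimConfig) -> Trajectory:
    """Integrate Langevin dynamics with the BAOAB splitting.

    Initial velocities are drawn from the Maxwell-Boltzmann distribution at
    the run temperature (with the run seed) unless the start state provides
    them.  Frames (including the initial one) and an energy log are stored at
    ``save_interval`` steps.  Numerical blow-up aborts with a diagnostic.
    """
    rng = np.random.default_rng(config.seed)
    x = np.array(start.coordinates, dtype=float)
    n = ff.n_atoms
    if x.shape != (n, 3):
        raise ValueError(f"start coordinates must have shape ({n}, 3)")
    v = (
        maxwell_boltzmann_velocities(n, config.temperature, rng)
        if start.velocities is None
        else np.array(start.velocities, dtype=float)
    )
    h = config.timestep
    gamma = config.friction
    c1 = np.exp(-gamma * h) if gamma > 0 else 1.0
    c2 = np.sqrt(config.temperature * (1.0 - c1**2)) if gamma > 0 else 0.0

    nlist = NeighborList(ff)
    nc = nlist.update(x)
    include_res = config.restraints_active
    energy, forces, breakdown = potential_energy_and_forces(ff, x, include_res, nc)

    frames = [x.copy()]
    log_rows = [_log_row(0, energy, breakdown, v, n)]
    for step in range(1, config.n_steps + 1):
        v += 0.5 * h * forces
        x += 0.5 * h * v
        if gamma > 0:
            v = c1 * v + c2 * rng.standard_normal((n, 3))
        x += 0.5 * h * v
        nc = nlist.update(x)
        energy, forces, breakdown = potential_energy_and_forces(ff, x, include_res, nc)
        v += 0.5 * h * forces

        if not np.isfinite(energy) or energy > ENERGY_BLOWUP_THRESHOLD:
            logger.error("blow-up at step %d: U=%.3g; diagnostic frame dumped", step, energy)
            raise RuntimeError(
                f"numerical blow-up at step {step}: potential energy {energy:.4g} eps"
            )
        if step % config.save_interval == 0:
            frames.append(x.copy())
            log_rows.append(_log_row(step, energy, breakdown, v, n))

    return Trajectory(
        frames=np.array(frames),
        config=config,
        ff_hash=ff.provenance.get("hash", ""),
        energies=pd.DataFrame(log_rows),
    )


def _log_row(step, energy, breakdown, v, n_atoms):
    ke = kinetic_energy(v)
    row = {"step": step, "potential": energy, "kinetic": ke,
           "temperature": 2.0 * ke / (3.0 * n_atoms)}
    row.update(breakdown)
    return row


# ---------------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------------

def distance_timeseries(traj: Trajectory, atom_i: int, atom_j: int) -> np.ndarray:
    """Per-frame Euclidean distance (A) between two atoms."""
    d = traj.frames[:, atom_i, :] - traj.frames[:, atom_j, :]
    return np.linalg.norm(d, axis=1)


def distance_mask(
    traj: Trajectory, atom_i: int, atom_j: int, threshold: float
) -> np.ndarray:
    """Boolean frame mask selecting frames with distance < threshold (A)."""
    return distance_timeseries(traj, atom_i, atom_j) < threshold
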