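"""Single-basin all-atom structure-based force-field construction.

The reference structure is defined as the global minimum of the potential

    U = sum_bonds     eps_r/2     (r - r0)^2
      + sum_angles    eps_theta/2 (theta - theta0)^2
      + sum_impropers eps_imp/2   (chi - chi0)^2
      + sum_planars   eps_planar  [1 - cos(2 chi)]
      + sum_bb_dih    eps_bb F(phi - phi0) + sum_sc_dih eps_sc F(phi - phi0)
      + sum_contacts  eps_c [(sigma/r)^12 - 2 (sigma/r)^6]
      + sum_noncontacts eps_nc (sigma_nc / r)^12
      + restraints    k/2 (r - r_min)^2

with F(x) = [1 - cos x] + 1/2 [1 - cos 3x].  Internal units: length in
Angstrom, energy in the reduced unit eps, mass 1 per atom.  Native contacts
come from a Shadow Contact Map (cutoff 6 A, shadowing radius 1 A); contact
minima sit at 0.96 x the native distance to avoid artificial expansion.
Dihedral and contact weights are normalized so the total stabilizing energy
equals n_atoms * eps with a 2:1 contact:dihedral split and a 2:1
backbone:sidechain per-term dihedral ratio.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .structure import Structure
from .templates import (
    DEFAULT_TEMPLATES,
    ResidueTemplate,
    lookup_angle_deg,
    lookup_bond_length,
)

logger = logging.getLogger(__name__)

# fixed energy-scale weights (reduced units; lengths in Angstrom, angles in rad)
EPS_R = 100.0          # eps/A^2
EPS_THETA = 80.0       # eps/rad^2
EPS_CHI_IMP = 10.0     # eps/rad^2
EPS_PLANAR = 40.0      # eps (dimensionless cosine well)
EPS_NC = 0.1           # eps
SIGMA_NC = 2.5         # A
CONTACT_SIGMA_SCALE = 0.96
SCM_CUTOFF = 6.0       # A
SCM_RADIUS = 1.0       # A
DEFAULT_NC_CUTOFF = 4.0  # A; discarded tail (2.5/4)^12 * 0.1 ~ 3.6e-5 eps per pair

# per-contact energy at the native distance (sigma = 0.96 r_native)
CONTACT_NATIVE_ENERGY = CONTACT_SIGMA_SCALE**12 - 2.0 * CONTACT_SIGMA_SCALE**6


def spring_constant_per_A2(k_per_nm2: float) -> float:
    """Convert a spring constant quoted in eps/nm^2 to internal eps/A^2."""
    return k_per_nm2 * 0.01


# ---------------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------------

def measure_angle(coord: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Angle (rad) at the middle atom of each (i, j, k) triple."""
    idx = np.atleast_2d(idx)
    u = coord[idx[:, 0]] - coord[idx[:, 1]]
    v = coord[idx[:, 2]] - coord[idx[:, 1]]
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def measure_dihedral(coord: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Signed dihedral (rad, in (-pi, pi]) for each (i, j, k, l) quadruple."""
    idx = np.atleast_2d(idx)
    b1 = coord[idx[:, 1]] - coord[idx[:, 0]]
    b2 = coord[idx[:, 2]] - coord[idx[:, 1]]
    b3 = coord[idx[:, 3]] - coord[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


# ---------------------------------------------------------------------------------
# term containers
# ---------------------------------------------------------------------------------

@dataclasses.dataclass
class BondedTerms:
    """Index arrays plus equilibria for every bonded interaction class."""

    bonds_idx: np.ndarray        # (nb, 2) int
    bonds_r0: np.ndarray         # (nb,) A
    angles_idx: np.ndarray       # (na, 3)
    angles_theta0: np.ndarray    # (na,) rad
    impropers_idx: np.ndarray    # (ni, 4)
    impropers_chi0: np.ndarray   # (ni,) rad
    planars_idx: np.ndarray      # (np, 4)
    dihedrals_idx: np.ndarray    # (nd, 4)
    dihedrals_phi0: np.ndarray   # (nd,) rad
    dihedrals_backbone: np.ndarray  # (nd,) bool

    @property
    def n_dihedrals(self) -> int:
        return len(self.dihedrals_idx)

    def adjacency(self, n_atoms: int) -> sparse.csr_matrix:
        i, j = self.bonds_idx.T if len(self.bonds_idx) else (np.array([], int),) * 2
        data = np.ones(2 * len(i), dtype=bool)
        return sparse.csr_matrix(
            (data, (np.r_[i, j], np.r_[j, i])), shape=(n_atoms, n_atoms)
        )


@dataclasses.dataclass
class DistanceRestraint:
    """Harmonic pair restraint U = k/2 (r - r_min)^2 (k in eps/A^2)."""

    i: int
    j: int
    r_min: float
    k: float


@dataclasses.dataclass
class DisorderSpec:
    """Residue ranges (chain, start, end), inclusive, to treat as disordered."""

    ranges: tuple = ()

    def __bool__(self) -> bool:
        return len(self.ranges) > 0


@dataclasses.dataclass
class ForceField:
    """The fully parameterized potential for one reference structure."""

    n_atoms: int
    ref_coord: np.ndarray
    bonded: BondedTerms
    bonds_w: np.ndarray
    angles_w: np.ndarray
    impropers_w: np.ndarray
    planars_w: np.ndarray
    dihedrals_w: np.ndarray
    contacts_idx: np.ndarray      # (nc, 2)
    contacts_sigma: np.ndarray    # (nc,) A
    contacts_w: np.ndarray        # (nc,) eps
    exclusions: np.ndarray        # (ne, 2) pairs excluded from the nc repulsion
    sigma_nc: float = SIGMA_NC
    eps_nc: float = EPS_NC
    nc_cutoff: float = DEFAULT_NC_CUTOFF
    restraints: list = dataclasses.field(default_factory=list)
    chain_id: np.ndarray | None = None
    res_id: np.ndarray | None = None
    res_name: np.ndarray | None = None
    atom_name: np.ndarray | None = None
    provenance: dict = dataclasses.field(default_factory=dict)

    def copy(self) -> "ForceField":
        new = dataclasses.replace(self)
        new.restraints = list(self.restraints)
        new.provenance = dict(self.provenance)
        return new

    def hash(self) -> str:
        """Seed-free deterministic content hash of all parameter arrays."""
        h = hashlib.sha256()
        b = self.bonded
        for arr in (
            self.ref_coord, b.bonds_idx, b.bonds_r0, b.angles_idx, b.angles_theta0,
            b.impropers_idx, b.impropers_chi0, b.planars_idx, b.dihedrals_idx,
            b.dihedrals_phi0, b.dihedrals_backbone, self.bonds_w, self.angles_w,
            self.impropers_w, self.planars_w, self.dihedrals_w, self.contacts_idx,
            self.contacts_sigma, self.contacts_w, self.exclusions,
        ):
            h.update(np.ascontiguousarray(arr).tobytes())
        for r in self.restraints:
            h.update(f"{r.i},{r.j},{r.r_min},{r.k};".encode())
        h.update(f"{self.sigma_nc},{self.eps_nc},{self.nc_cutoff}".encode())
        return h.hexdigest()

    @property
    def total_contact_energy(self) -> float:
        return float(np.sum(self.contacts_w))

    @property
    def total_dihedral_energy(self) -> float:
        return float(np.sum(self.dihedrals_w))


# ---------------------------------------------------------------------------------
# bonded-term extraction
# ---------------------------------------------------------------------------------

def _resolve_quadruple(names, res_maps, r):
    """Resolve template atom names (with +/- prefixes) for residue index r."""
    out = []
    for nm in names:
        if nm.startswith("+"):
            ridx, nm = r + 1, nm[1:]
        elif nm.startswith("-"):
            ridx, nm = r - 1, nm[1:]
        else:
            ridx = r
        if ridx < 0 or ridx >= len(res_maps) or res_maps[ridx] is None:
            return None
        idx = res_maps[ridx].get(nm)
        if idx is None:
            return None
        out.append(idx)
    return tuple(out)


def extract_bonded_terms(
    structure: Structure,
    templates: dict[str, ResidueTemplate] | None = None,
) -> BondedTerms:
    """Build bond/angle/improper/planar/proper-dihedral term lists.

    Bond and angle equilibria are looked up in the bundled reference table
    where available and otherwise measured from the input coordinates (logged).
    Improper and proper dihedral equilibria are always measured from the input
    coordinates.  Proper dihedrals are generated one per rotatable central
    bond (lowest-index flanking atoms), skipping bonds at the center of a
    designated planar group and near-collinear geometries.  A dihedral is
    "backbone" iff all four atoms carry backbone atom names for their residue.
    """
    templates = DEFAULT_TEMPLATES if templates is None else templates
    coord = structure.coord
    res_index = structure.residue_index()
    n_res = int(res_index[-1]) + 1 if structure.n_atoms else 0

    res_atoms = [np.flatnonzero(res_index == r) for r in range(n_res)]
    res_names = [str(structure.res_name[a[0]]) for a in res_atoms]
    res_chains = [str(structure.chain_id[a[0]]) for a in res_atoms]
    res_ids = [int(structure.res_id[a[0]]) for a in res_atoms]

    missing_templates = sorted(
        {nm for nm in res_names if nm not in templates}
    )
    if missing_templates:
        raise KeyError(
            "no residue template for: " + ", ".join(missing_templates)
        )

    # name -> atom index map per residue; log atoms missing relative to template
    res_maps: list[dict[str, int] | None] = []
    for r in range(n_res):
        tmpl = templates[res_names[r]]
        amap = {str(structure.name[a]): int(a) for a in res_atoms[r]}
        missing = [nm for nm in tmpl.atoms if nm not in amap]
        if missing:
            logger.info(
                "residue %s %s%d missing atoms %s; affected terms skipped",
                res_names[r], res_chains[r], res_ids[r], missing,
            )
        res_maps.append(amap)

    backbone_atom = np.zeros(structure.n_atoms, dtype=bool)
    for r in range(n_res):
        tmpl = templates[res_names[r]]
        for nm, a in res_maps[r].items():
            backbone_atom[a] = nm in tmpl.backbone

    bonds: list[tuple[int, int]] = []
    bond_res: list[int] = []  # owning residue (for table lookup)
    for r in range(n_res):
        tmpl = templates[res_names[r]]
        for a, b in tmpl.bonds:
            ia, ib = res_maps[r].get(a), res_maps[r].get(b)
            if ia is None or ib is None:
                continue
            bonds.append((min(ia, ib), max(ia, ib)))
            bond_res.append(r)
        # polymer link to the next residue: same chain, consecutive author ids
        if r + 1 < n_res and tmpl.link_next is not None:
            tnext = templates[res_names[r + 1]]
            if (
                res_chains[r + 1] == res_chains[r]
                and res_ids[r + 1] == res_ids[r] + 1
                and tnext.link_prev is not None
            ):
                ia = res_maps[r].get(tmpl.link_next)
                ib = res_maps[r + 1].get(tnext.link_prev)
                if ia is not None and ib is not None:
                    bonds.append((min(ia, ib), max(ia, ib)))
                    bond_res.append(r)

    bonds_idx = np.array(sorted(set(bonds)), dtype=int).reshape(-1, 2)
    bond_res_map = {p: r for p, r in zip(bonds, bond_res)}

    # equilibrium bond lengths: table first, fallback measured
    bonds_r0 = np.empty(len(bonds_idx))
    n_fallback = 0
    for n, (i, j) in enumerate(bonds_idx):
        rname = res_names[res_index[i]]
        val = lookup_bond_length(rname, str(structure.name[i]), str(structure.name[j]))
        if val is None:
            val = float(np.linalg.norm(coord[i] - coord[j]))
            n_fallback += 1
        bonds_r0[n] = val
    if n_fallback:
        logger.debug("%d/%d bond equilibria measured from input coordinates",
                     n_fallback, len(bonds_idx))

    # adjacency for angle/dihedral generation
    neighbors: dict[int, list[int]] = {}
    for i, j in bonds_idx:
        neighbors.setdefault(int(i), []).append(int(j))
        neighbors.setdefault(int(j), []).append(int(i))
    for v in neighbors.values():
        v.sort()

    angles = []
    for j in sorted(neighbors):
        nb = neighbors[j]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    angles_idx = np.array(angles, dtype=int).reshape(-1, 3)
    angles_theta0 = np.empty(len(angles_idx))
    for n, (i, j, k) in enumerate(angles_idx):
        rname = res_names[res_index[j]]
        names = (str(structure.name[i]), str(structure.name[j]), str(structure.name[k]))
        val = lookup_angle_deg(rname, names)
        if val is not None:
            angles_theta0[n] = np.deg2rad(val)
        else:
            angles_theta0[n] = measure_angle(coord, np.array([[i, j, k]]))[0]

    # impropers and planars from template quadruple lists
    impropers, planars = [], []
    for r in range(n_res):
        tmpl = templates[res_names[r]]
        for quad in tmpl.impropers:
            q = _resolve_quadruple(quad, res_maps, r)
            if q is not None:
                impropers.append(q)
        for quad in tmpl.planars:
            q = _resolve_quadruple(quad, res_maps, r)
            if q is not None:
                # planar quadruple spanning a chain break is dropped
                if res_index[q[0]] != res_index[q[-1]]:
                    ra, rb = res_index[q[0]], res_index[q[-1]]
                    if res_chains[ra] != res_chains[rb] or res_ids[rb] != res_ids[ra] + 1:
                        continue
                planars.append(q)
    impropers_idx = np.array(impropers, dtype=int).reshape(-1, 4)
    impropers_chi0 = (
        measure_dihedral(coord, impropers_idx) if len(impropers_idx) else np.empty(0)
    )
    planars_idx = np.array(planars, dtype=int).reshape(-1, 4)
    planar_central = {
        (min(q[1], q[2]), max(q[1], q[2])) for q in planars
    }

    # one proper dihedral per rotatable central bond
    dihedrals, backbone_flags = [], []
    for i, j in bonds_idx:
        i, j = int(i), int(j)
        if (i, j) in planar_central:
            continue
        ni = [a for a in neighbors[i] if a != j]
        nj = [a for a in neighbors[j] if a != i]
        if not ni or not nj:
            continue
        a, l = ni[0], nj[0]
        if a == l:
            continue  # three-membered ring degenerate
        ang1 = measure_angle(coord, np.array([[a, i, j]]))[0]
        ang2 = measure_angle(coord, np.array([[i, j, l]]))[0]
        if min(np.sin(ang1), np.sin(ang2)) < 1e-3:
            logger.info("skipping near-collinear dihedral (%d,%d,%d,%d)", a, i, j, l)
            continue
        dihedrals.append((a, i, j, l))
        backbone_flags.append(bool(np.all(backbone_atom[[a, i, j, l]])))
    dihedrals_idx = np.array(dihedrals, dtype=int).reshape(-1, 4)
    dihedrals_phi0 = (
        measure_dihedral(coord, dihedrals_idx) if len(dihedrals_idx) else np.empty(0)
    )

    return BondedTerms(
        bonds_idx=bonds_idx,
        bonds_r0=bonds_r0,
        angles_idx=angles_idx,
        angles_theta0=angles_theta0,
        impropers_idx=impropers_idx,
        impropers_chi0=impropers_chi0,
        planars_idx=planars_idx,
        dihedrals_idx=dihedrals_idx,
        dihedrals_phi0=dihedrals_phi0,
        dihedrals_backbone=np.array(backbone_flags, dtype=bool),
    )


# ---------------------------------------------------------------------------------
# Shadow Contact Map
# ---------------------------------------------------------------------------------

def bonded_exclusion_pairs(bonded: BondedTerms, n_atoms: int) -> np.ndarray:
    """Pairs within 1-2/1-3/1-4 bonded relationships, as a sorted (m, 2) array."""
    adj = bonded.adjacency(n_atoms)
    reach = adj + adj @ adj + adj @ adj @ adj
    reach = sparse.triu(reach.tocoo(), k=1)
    pairs = np.column_stack([reach.row, reach.col])
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def _pair_key(pairs: np.ndarray, n_atoms: int) -> np.ndarray:
    return pairs[:, 0].astype(np.int64) * n_atoms + pairs[:, 1]


def shadow_contact_map(
    structure: Structure,
    bonded: BondedTerms | None = None,
    cutoff: float = SCM_CUTOFF,
    shadow_radius: float = SCM_RADIUS,
) -> np.ndarray:
    """Native contacts by the Shadow Contact Map criterion.

    A pair (i, j) is a contact iff its native distance is <= ``cutoff``, the
    atoms belong to different residues and are not in a 1-2/1-3/1-4 bonded
    relationship, and no third atom of radius ``shadow_radius`` occludes the
    line of sight: atom k shadows the pair if it projects onto the open
    segment i->j within ``shadow_radius`` of the line and lies within the
    cutoff sphere of i or of j.  The result is symmetric (stored as i < j)
    and invariant to atom input ordering.
    """
    if cutoff <= 0 or shadow_radius < 0:
        raise ValueError("cutoff must be > 0 and shadow_radius >= 0")
    coord = structure.coord
    if not np.all(np.isfinite(coord)):
        raise ValueError("non-finite coordinates")
    n = structure.n_atoms
    res_index = structure.residue_index()

    tree = cKDTree(coord)
    cand = tree.query_pairs(cutoff, output_type="ndarray")
    if len(cand) == 0:
        return np.empty((0, 2), dtype=int)
    cand = np.sort(cand, axis=1)

    keep = res_index[cand[:, 0]] != res_index[cand[:, 1]]
    if bonded is not None:
        excl = bonded_exclusion_pairs(bonded, n)
        if len(excl):
            keep &= ~np.isin(_pair_key(cand, n), _pair_key(excl, n))
    cand = cand[keep]

    balls = tree.query_ball_point(coord, cutoff)
    contacts = []
    r2 = shadow_radius**2
    for i, j in cand:
        ks = np.array(sorted(set(balls[i]) | set(balls[j]) - {i, j}), dtype=int)
        ks = ks[(ks != i) & (ks != j)]
        if len(ks) == 0:
            contacts.append((i, j))
            continue
        d = coord[j] - coord[i]
        dd = float(d @ d)
        p = coord[ks] - coord[i]
        t = (p @ d) / dd
        perp2 = np.einsum("ij,ij->i", p, p) - t**2 * dd
        shadowed = np.any((t > 0.0) & (t < 1.0) & (perp2 < r2))
        if not shadowed:
            contacts.append((i, j))
    out = np.array(contacts, dtype=int).reshape(-1, 2)
    return out[np.lexsort((out[:, 1], out[:, 0]))] if len(out) else out


# ---------------------------------------------------------------------------------
# energy-scale normalization and assembly
# ---------------------------------------------------------------------------------

def assign_energy_scales(
    structure: Structure,
    bonded: BondedTerms,
    contacts_idx: np.ndarray,
    nc_cutoff: float = DEFAULT_NC_CUTOFF,
) -> ForceField:
    """Assemble the force field and normalize stabilizing energy weights.

    Constraints (applied exactly): total stabilizing energy
    sum(eps_c) + sum(eps_dihedral) = n_atoms * eps; contact:dihedral total
    ratio 2:1; per-term backbone:sidechain dihedral weight ratio 2:1 with
    uniform weights within each class.  Fixed weights (eps_r, eps_theta,
    eps_imp, eps_planar, eps_nc) take the printed reference values.
    """
    n_atoms = structure.n_atoms
    n_c = len(contacts_idx)
    n_bb = int(np.sum(bonded.dihedrals_backbone))
    n_sc = int(len(bonded.dihedrals_idx) - n_bb)
    if n_c == 0 or (n_bb + n_sc) == 0:
        raise ValueError(
            f"normalization requires >=1 contact and >=1 dihedral "
            f"(got {n_c} contacts, {n_bb + n_sc} dihedrals)"
        )
    total = float(n_atoms)              # in eps
    contact_total = 2.0 * total / 3.0
    dihedral_total = total / 3.0
    eps_c = contact_total / n_c
    eps_sc = dihedral_total / (2.0 * n_bb + n_sc)
    eps_bb = 2.0 * eps_sc

    coord = structure.coord
    native_d = np.linalg.norm(
        coord[contacts_idx[:, 0]] - coord[contacts_idx[:, 1]], axis=1
    )
    sigma = CONTACT_SIGMA_SCALE * native_d

    dihedrals_w = np.where(bonded.dihedrals_backbone, eps_bb, eps_sc)

    excl = bonded_exclusion_pairs(bonded, n_atoms)
    exclusions = np.vstack([excl, contacts_idx]) if len(contacts_idx) else excl
    exclusions = np.unique(exclusions, axis=0)

    ff = ForceField(
        n_atoms=n_atoms,
        ref_coord=coord.copy(),
        bonded=bonded,
        bonds_w=np.full(len(bonded.bonds_idx), EPS_R),
        angles_w=np.full(len(bonded.angles_idx), EPS_THETA),
        impropers_w=np.full(len(bonded.impropers_idx), EPS_CHI_IMP),
        planars_w=np.full(len(bonded.planars_idx), EPS_PLANAR),
        dihedrals_w=dihedrals_w,
        contacts_idx=np.asarray(contacts_idx, dtype=int),
        contacts_sigma=sigma,
        contacts_w=np.full(n_c, eps_c),
        exclusions=exclusions,
        nc_cutoff=nc_cutoff,
        chain_id=structure.chain_id.copy(),
        res_id=structure.res_id.copy(),
        res_name=structure.res_name.copy(),
        atom_name=structure.name.copy(),
        provenance={
            "source": structure.source,
            "n_atoms": n_atoms,
            "n_bonds": len(bonded.bonds_idx),
            "n_angles": len(bonded.angles_idx),
            "n_impropers": len(bonded.impropers_idx),
            "n_planars": len(bonded.planars_idx),
            "n_dihedrals_backbone": n_bb,
            "n_dihedrals_sidechain": n_sc,
            "n_contacts": n_c,
            "eps_c": eps_c,
            "eps_bb": eps_bb,
            "eps_sc": eps_sc,
        },
    )
    return ff


def apply_disorder_mask(ff: ForceField, spec: DisorderSpec) -> ForceField:
    """Remove stabilizing contacts and proper dihedrals of disordered residues.

    Bonds, angles, impropers and planar terms are retained, so chain
    connectivity and local stereochemistry survive; only the terms that pin
    the region to its modelled conformation are removed.  Contacts removed
    from the contact set regain the generic non-contact repulsion.
    """
    if not spec:
        return ff.copy()
    if ff.chain_id is None:
        raise ValueError("force field lacks residue metadata; cannot mask")
    masked = np.zeros(ff.n_atoms, dtype=bool)
    for chain, start, end in spec.ranges:
        sel = (ff.chain_id == chain) & (ff.res_id >= start) & (ff.res_id <= end)
        if not np.any(sel):
            raise ValueError(
                f"disorder range {chain}:{start}-{end} resolves to zero residues"
            )
        masked |= sel

    keep_c = ~(masked[ff.contacts_idx[:, 0]] | masked[ff.contacts_idx[:, 1]])
    removed_contacts = ff.contacts_idx[~keep_c]
    d_idx = ff.bonded.dihedrals_idx
    keep_d = ~np.any(masked[d_idx], axis=1) if len(d_idx) else np.ones(0, bool)

    new = ff.copy()
    new.contacts_idx = ff.contacts_idx[keep_c]
    new.contacts_sigma = ff.contacts_sigma[keep_c]
    new.contacts_w = ff.contacts_w[keep_c]
    new.bonded = dataclasses.replace(
        ff.bonded,
        dihedrals_idx=d_idx[keep_d],
        dihedrals_phi0=ff.bonded.dihedrals_phi0[keep_d],
        dihedrals_backbone=ff.bonded.dihedrals_backbone[keep_d],
    )
    new.dihedrals_w = ff.dihedrals_w[keep_d]
    # removed contacts regain nc repulsion: rebuild exclusions
    excl = bonded_exclusion_pairs(ff.bonded, ff.n_atoms)
    exclusions = (
        np.vstack([excl, new.contacts_idx]) if len(new.contacts_idx) else excl
    )
    new.exclusions = np.unique(exclusions, axis=0)
    n_rm_c = int(np.sum(~keep_c))
    n_rm_d = int(np.sum(~keep_d))
    new.provenance["disorder_removed_contacts"] = n_rm_c
    new.provenance["disorder_removed_dihedrals"] = n_rm_d
    logger.info(
        "disorder mask removed %d contacts and %d dihedrals (%d atoms masked)",
        n_rm_c, n_rm_d, int(np.sum(masked)),
    )
    del removed_contacts
    return new


def add_distance_restraint(
    ff: ForceField, atom_i: int, atom_j: int, r_min: float, k: float
) -> ForceField:
    """Add a harmonic pair restraint U = k/2 (r - r_min)^2 (k in eps/A^2)."""
    if atom_i == atom_j:
        raise ValueError("restraint atoms must be distinct")
    if not (0 <= atom_i < ff.n_atoms and 0 <= atom_j < ff.n_atoms):
        raise IndexError("restraint atom index out of range")
    if k < 0:
        raise ValueError("spring constant must be >= 0")
    new = ff.copy()
    new.restraints.append(DistanceRestraint(int(atom_i), int(atom_j), float(r_min), float(k)))
    return new


def build_force_field(
    structure: Structure,
    templates: dict[str, ResidueTemplate] | None = None,
    disorder: DisorderSpec | None = None,
    cutoff: float = SCM_CUTOFF,
    shadow_radius: float = SCM_RADIUS,
    nc_cutoff: float = DEFAULT_NC_CUTOFF,
) -> ForceField:
    """Convenience: bonded terms -> Shadow Contact Map -> normalization -> mask."""
    bonded = extract_bonded_terms(structure, templates)
    contacts = shadow_contact_map(structure, bonded, cutoff, shadow_radius)
    ff = assign_energy_scales(structure, bonded, contacts, nc_cutoff=nc_cutoff)
    if disorder is not None and disorder:
        ff = apply_disorder_mask(ff, disorder)
    ff.provenance["hash"] = ff.hash()
    return ff
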