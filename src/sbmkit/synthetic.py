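"""Seedable synthetic two-domain all-atom systems for exercising the pipeline.

The generator emulates, at toy scale, the geometry the analysis assumes: a
large "body" (the ribosomal small subunit stand-in), a smaller domain (the
methyltransferase stand-in) connected through a flexible hinge linker, a
pseudo-cofactor atom bound in the domain, a methylation-target atom on the
body, and optionally a nucleic-like flexible tail standing in for disordered
rRNA.  The native ("post-catalytic") conformation is the reference state;
rotated "pre-catalytic" conformations are constructed by rigidly rotating the
domain about an axis through the hinge.

Design constraints baked into the geometry:

* Toy residues (TPR protein-like, TLK backbone-only linker, TNU nucleic-like)
  use a reduced alphabet that still exercises every force-field term type.
* Every atom pair outside the bonded 1-2/1-3/1-4 exclusions is at least
  MIN_NONBONDED_DISTANCE (4.2 A) apart in the native state, which puts all
  non-contact pairs beyond the repulsion cutoff: the native potential energy
  is then exactly the closed-form contact minimum.
* Planar-group quadruples are exactly planar natively (the backbone path and
  its in-plane decorations live in one plane), so planar terms are exactly
  zero at the reference coordinates.
* The domain points away from the body and can tilt by well over 15 degrees
  without steric overlap.

Geometry is deterministic; the seed is recorded in the metadata and keeps the
generator interface uniform with the stochastic stages downstream.
"""
from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

from .builder import DisorderSpec, bonded_exclusion_pairs, extract_bonded_terms
from .structure import Structure

logger = logging.getLogger(__name__)

MIN_NONBONDED_DISTANCE = 4.2   # A, native, for all pairs outside 1-2/1-3/1-4
BACKBONE_SPACING = 1.45        # A along the path per backbone atom
ZIGZAG = 0.195                 # A in-plane alternating offset
ARC_RADIUS = 6.0               # A hinge-turn radius
CB_DROP = 2.2                  # A first sidechain bond (out of plane)
CG_BOND = 2.2                  # A second sidechain bond
CG_TILT_DEG = 10.0             # tilt of CB->CG off the -y direction
N1_BOND = 2.0                  # A nucleic branch bond
TAIL_OFFSET = 5.2              # A body-to-tail lateral offset


@dataclasses.dataclass
class ToySpec:
    """Parameters of the synthetic two-domain system."""

    n_residues_body: int = 14
    n_residues_domain: int = 10
    linker_length: int = 3
    disorder_tail_length: int = 6
    seed: int = 0

    def __post_init__(self):
        if min(self.n_residues_body, self.n_residues_domain, self.linker_length) < 1:
            raise ValueError("all residue counts must be >= 1")
        if self.disorder_tail_length < 0:
            raise ValueError("tail length must be >= 0")


# ---------------------------------------------------------------------------------
# path machinery (all in the global xz-plane; y is the out-of-plane direction)
# ---------------------------------------------------------------------------------

def _path_point(s: float, l1: float, rho: float):
    """Position, tangent and in-plane normal at arc length s along the
    body(+z) -> quarter-turn -> domain(+x) path."""
    arc = 0.5 * np.pi * rho
    if s < l1:
        pos = np.array([0.0, s])
        tan = np.array([0.0, 1.0])
    elif s < l1 + arc:
        phi = (s - l1) / rho
        pos = np.array([rho - rho * np.cos(phi), l1 + rho * np.sin(phi)])
        tan = np.array([np.sin(phi), np.cos(phi)])
    else:
        pos = np.array([rho + (s - l1 - arc), l1 + rho])
        tan = np.array([1.0, 0.0])
    nrm = np.array([tan[1], -tan[0]])
    return pos, tan, nrm


class _AtomBuffer:
    def __init__(self):
        self.rows = []  # (name, element, res_name, chain, resid, xyz, hetero)

    def add(self, name, element, res_name, chain, resid, xyz, hetero=False):
        self.rows.append((name, element, res_name, chain, resid, np.asarray(xyz, float), hetero))

    def to_structure(self, source: str) -> Structure:
        n = len(self.rows)
        return Structure(
            serial=np.arange(1, n + 1),
            name=np.array([r[0] for r in self.rows]),
            element=np.array([r[1] for r in self.rows]),
            res_name=np.array([r[2] for r in self.rows]),
            chain_id=np.array([r[3] for r in self.rows]),
            res_id=np.array([r[4] for r in self.rows]),
            icode=np.array([""] * n),
            coord=np.array([r[5] for r in self.rows]),
            hetero=np.array([r[6] for r in self.rows]),
            source=source,
        )


def _xz(pos2, y=0.0):
    return np.array([pos2[0], y, pos2[1]])


def _build_chain_a(spec: ToySpec, buf: _AtomBuffer) -> dict:
    """Body + linker + domain polymer along the turning path."""
    nb, nl, nd = spec.n_residues_body, spec.linker_length, spec.n_residues_domain
    res_types = ["TPR"] * nb + ["TLK"] * nl + ["TPR"] * nd
    l1 = nb * 3 * BACKBONE_SPACING
    tilt = np.deg2rad(CG_TILT_DEG)
    hinge_ca = None
    domain_first_backbone = None
    m = 0  # global backbone atom counter
    for r, rtype in enumerate(res_types):
        resid = r + 1
        bb_names = ("N", "CA", "C") if rtype != "TNU" else ()
        positions = {}
        for nm in bb_names:
            s = m * BACKBONE_SPACING
            pos2, tan2, nrm2 = _path_point(s, l1, ARC_RADIUS)
            pos2 = pos2 + ((-1) ** m) * ZIGZAG * nrm2
            xyz = _xz(pos2)
            positions[nm] = (xyz, np.array([tan2[0], 0.0, tan2[1]]))
            m += 1
        for nm in bb_names:
            buf.add(nm, "N" if nm == "N" else "C", rtype, "A", resid, positions[nm][0])
        if rtype == "TPR":
            ca, tan3 = positions["CA"]
            cb = ca + np.array([0.0, -CB_DROP, 0.0])
            cg = cb + CG_BOND * (-np.cos(tilt) * np.array([0.0, 1.0, 0.0])
                                 + np.sin(tilt) * tan3)
            buf.add("CB", "C", rtype, "A", resid, cb)
            buf.add("CG", "C", rtype, "A", resid, cg)
        if r == nb and hinge_ca is None:  # first linker residue
            hinge_ca = positions["CA"][0]
        if r == nb + nl and domain_first_backbone is None:
            domain_first_backbone = positions["N"][0]
    return {
        "hinge_resid": nb + 1,
        "hinge_ca": hinge_ca,
        "body_resid_range": (1, nb),
        "linker_resid_range": (nb + 1, nb + nl),
        "domain_resid_range": (nb + nl + 1, nb + nl + nd),
        "l1": l1,
    }


def make_toy_two_domain_system(spec: ToySpec | None = None):
    """Build the native ("post-catalytic") toy system.

    Returns ``(structure, metadata)`` where metadata records the ground truth
    needed by downstream tests: ligand/target atom identities and native
    distance, hinge residue, selection expressions and atom counts.
    Raises if the requested geometry violates the clash-free contract.
    """
    spec = ToySpec() if spec is None else spec
    buf = _AtomBuffer()
    info = _build_chain_a(spec, buf)

    nb, nl, nd = spec.n_residues_body, spec.linker_length, spec.n_residues_domain
    l1 = info["l1"]
    z_top = l1 + ARC_RADIUS          # z level of the domain strand
    dom_x0 = ARC_RADIUS              # x where the domain strand starts

    # pseudo-cofactor: bound on the +y face of the domain, near the hinge end
    lig_xyz = np.array([dom_x0 + 4.9, 5.0, z_top])
    buf.add("S1", "S", "LIG", "L", 1, lig_xyz, hetero=True)
    # methylation-target atom: on the body flank, below the domain
    trg_xyz = np.array([5.0, 0.0, l1 - 2.0])
    buf.add("C1", "C", "TRG", "T", 1, trg_xyz, hetero=True)

    structure = buf.to_structure(source=f"sbmkit-toy(seed={spec.seed})")
    validate_clash_free(structure)

    d0, d1 = info["domain_resid_range"]
    lig_idx = structure.atom_index("L", 1, "S1")
    trg_idx = structure.atom_index("T", 1, "C1")
    metadata = {
        "seed": spec.seed,
        "n_atoms": structure.n_atoms,
        "ligand_atom": {"chain": "L", "resid": 1, "name": "S1", "index": lig_idx},
        "target_atom": {"chain": "T", "resid": 1, "name": "C1", "index": trg_idx},
        "native_ligand_target_distance": float(
            np.linalg.norm(lig_xyz - trg_xyz)
        ),
        "hinge": {"chain": "A", "resid": info["hinge_resid"], "name": "CA"},
        "body_residues": info["body_resid_range"],
        "linker_residues": info["linker_resid_range"],
        "domain_residues": info["domain_resid_range"],
        "domain_selection": f"(chain A and resid {d0}:{d1}) or chain L",
        "body_selection": f"not ((chain A and resid {d0}:{d1}) or chain L)",
        "er_axis_hint": [0.0, 1.0, 0.0],
        "spec": dataclasses.asdict(spec),
    }
    return structure, metadata


def validate_clash_free(structure: Structure, min_dist: float = MIN_NONBONDED_DISTANCE):
    """Assert every pair outside the bonded 1-2/1-3/1-4 set is >= min_dist apart."""
    bonded = extract_bonded_terms(structure)
    n = structure.n_atoms
    excl = bonded_exclusion_pairs(bonded, n)
    excl_keys = set(int(i) * n + int(j) for i, j in excl)
    coord = structure.coord
    from scipy.spatial import cKDTree

    tree = cKDTree(coord)
    close = tree.query_pairs(min_dist, output_type="ndarray")
    for i, j in np.sort(close, axis=1):
        if int(i) * n + int(j) not in excl_keys:
            d = float(np.linalg.norm(coord[i] - coord[j]))
            raise ValueError(
                f"clash: atoms {i} ({structure.name[i]} {structure.res_name[i]}"
                f"{structure.res_id[i]}) and {j} ({structure.name[j]} "
                f"{structure.res_name[j]}{structure.res_id[j]}) at {d:.2f} A "
                f"< {min_dist} A"
            )


def make_rotated_conformation(
    native: Structure,
    axis: np.ndarray,
    angle_deg: float,
    hinge: tuple[str, int],
    domain_indices: np.ndarray,
) -> Structure:
    """Rigidly rotate the domain about ``axis`` through the hinge CA.

    Produces the constructed "pre-catalytic" end state used to define the
    Euler-Rodrigues axis.  The body is untouched.
    """
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-8:
        raise ValueError("axis must be a unit vector")
    chain, resid = hinge
    pivot = native.coord[native.atom_index(chain, resid, "CA")]
    rot = _ScipyRotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
    out = native.copy()
    idx = np.asarray(domain_indices, dtype=int)
    out.coord[idx] = (out.coord[idx] - pivot) @ rot.T + pivot
    return out


def make_disordered_tail(structure: Structure, spec: ToySpec):
    """Append a nucleic-like flexible tail (chain B) alongside the body.

    The tail lies parallel to the body strand at a contact-forming offset, so
    that unmasked it is stabilized by native contacts; the returned
    :class:`DisorderSpec` covers exactly the tail residues.  Tail length 0
    returns the structure unchanged with an empty spec.
    """
    n_tail = spec.disorder_tail_length
    if n_tail == 0:
        return structure.copy(), DisorderSpec(())
    buf = _AtomBuffer()
    for i in range(structure.n_atoms):
        a = structure[i]
        buf.add(a.name, a.element, a.residue_name, a.chain_id, a.residue_number,
                a.coordinates, a.hetero)
    bb_names = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")
    m = 0
    for r in range(n_tail):
        resid = r + 1
        pos_by_name = {}
        for nm in bb_names:
            z = 1.0 + m * BACKBONE_SPACING
            x = ((-1) ** m) * ZIGZAG
            pos_by_name[nm] = np.array([x, TAIL_OFFSET, z])
            m += 1
        for nm in bb_names:
            elem = nm[0]
            buf.add(nm, elem, "TNU", "B", resid, pos_by_name[nm])
        n1 = pos_by_name["C5'"] + np.array([0.0, N1_BOND, 0.0])
        buf.add("N1", "N", "TNU", "B", resid, n1)
    out = buf.to_structure(source=structure.source + "+tail")
    validate_clash_free(out)
    return out, DisorderSpec((("B", 1, n_tail),))


def write_ground_truth(metadata: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2)
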