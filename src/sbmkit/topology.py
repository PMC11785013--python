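"""Plain-text topology export/import (GROMACS-dialect subset).

The writer emits a ``.top``-style file with the familiar section layout
(``[ atoms ]``, ``[ bonds ]``, ``[ angles ]``, ``[ dihedrals ]``,
``[ pairs ]``, ``[ exclusions ]``) plus three custom sections needed to make
the file a lossless dump of the force field: ``[ restraints ]``,
``[ nonbonded ]`` and ``[ coordinates ]`` (reference coordinates at full
precision; a standard fixed-precision ``.gro`` is written alongside for
interoperability).  All values are in internal units: Angstrom, eps, radian.
Atom indices are 1-based in the file, as in GROMACS.

Dihedral function codes: 1 = proper (F-well, columns phi0, weight,
backbone-flag), 2 = harmonic improper (chi0, weight), 3 = planar cosine well
(weight).
"""
from __future__ import annotations

import dataclasses
import os

import numpy as np

from .builder import BondedTerms, DistanceRestraint, ForceField

_FMT = "%.12g"


def export_topology(ff: ForceField, path: str | os.PathLike) -> None:
    """Write the force field as a documented plain-text topology (+ .gro)."""
    path = os.fspath(path)
    b = ff.bonded
    lines: list[str] = ["; sbmkit structure-based topology (A / eps / rad; 1-based indices)"]

    lines.append("[ atoms ]")
    lines.append(";  nr  name  resnr  resname  chain")
    for i in range(ff.n_atoms):
        nm = ff.atom_name[i] if ff.atom_name is not None else "X"
        rn = ff.res_name[i] if ff.res_name is not None else "UNK"
        ri = ff.res_id[i] if ff.res_id is not None else 0
        ch = ff.chain_id[i] if ff.chain_id is not None else "A"
        lines.append(f"{i + 1:6d}  {nm:<6s} {ri:6d}  {rn:<6s} {ch}")

    lines.append("[ bonds ]")
    lines.append(";  i  j  func  r0  weight")
    for (i, j), r0, w in zip(b.bonds_idx, b.bonds_r0, ff.bonds_w):
        lines.append(f"{i + 1:6d} {j + 1:6d}  1  {_FMT % r0}  {_FMT % w}")

    lines.append("[ angles ]")
    lines.append(";  i  j  k  func  theta0  weight")
    for (i, j, k), t0, w in zip(b.angles_idx, b.angles_theta0, ff.angles_w):
        lines.append(f"{i + 1:6d} {j + 1:6d} {k + 1:6d}  1  {_FMT % t0}  {_FMT % w}")

    lines.append("[ dihedrals ]")
    lines.append(";  i  j  k  l  func  params (1: phi0 w bb; 2: chi0 w; 3: w)")
    for (i, j, k, l), p0, w, bb in zip(
        b.dihedrals_idx, b.dihedrals_phi0, ff.dihedrals_w, b.dihedrals_backbone
    ):
        lines.append(
            f"{i + 1:6d} {j + 1:6d} {k + 1:6d} {l + 1:6d}  1  "
            f"{_FMT % p0}  {_FMT % w}  {int(bb)}"
        )
    for (i, j, k, l), c0, w in zip(b.impropers_idx, b.impropers_chi0, ff.impropers_w):
        lines.append(
            f"{i + 1:6d} {j + 1:6d} {k + 1:6d} {l + 1:6d}  2  {_FMT % c0}  {_FMT % w}"
        )
    for (i, j, k, l), w in zip(b.planars_idx, ff.planars_w):
        lines.append(f"{i + 1:6d} {j + 1:6d} {k + 1:6d} {l + 1:6d}  3  {_FMT % w}")

    lines.append("[ pairs ]")
    lines.append(";  i  j  func  sigma  weight")
    for (i, j), s, w in zip(ff.contacts_idx, ff.contacts_sigma, ff.contacts_w):
        lines.append(f"{i + 1:6d} {j + 1:6d}  1  {_FMT % s}  {_FMT % w}")

    lines.append("[ exclusions ]")
    for i, j in ff.exclusions:
        lines.append(f"{i + 1:6d} {j + 1:6d}")

    lines.append("[ restraints ]")
    lines.append(";  i  j  r_min  k")
    for r in ff.restraints:
        lines.append(f"{r.i + 1:6d} {r.j + 1:6d}  {_FMT % r.r_min}  {_FMT % r.k}")

    lines.append("[ nonbonded ]")
    lines.append(";  sigma_nc  eps_nc  cutoff")
    lines.append(f"{_FMT % ff.sigma_nc}  {_FMT % ff.eps_nc}  {_FMT % ff.nc_cutoff}")

    lines.append("[ coordinates ]")
    for x, y, z in ff.ref_coord:
        lines.append(f"{float(x)!r} {float(y)!r} {float(z)!r}")

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    _write_gro(ff, os.path.splitext(path)[0] + ".gro")


def _write_gro(ff: ForceField, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sbmkit reference coordinates\n")
        fh.write(f"{ff.n_atoms:5d}\n")
        for i in range(ff.n_atoms):
            rn = ff.res_name[i] if ff.res_name is not None else "UNK"
            ri = int(ff.res_id[i]) if ff.res_id is not None else 1
            nm = ff.atom_name[i] if ff.atom_name is not None else "X"
            x, y, z = ff.ref_coord[i] / 10.0  # nm
            fh.write(f"{ri % 100000:5d}{rn:<5s}{nm:>5s}{(i + 1) % 100000:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
        span = np.ptp(ff.ref_coord, axis=0) / 10.0 + 2.0
        fh.write(f"{span[0]:10.5f}{span[1]:10.5f}{span[2]:10.5f}\n")


def import_topology(path: str | os.PathLike) -> ForceField:
    """Read a topology written by :func:`export_topology` back to a ForceField."""
    sections: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split(";")[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line.strip("[] ").strip()
                sections[current] = []
            elif current is not None:
                sections[current].append(line)

    atoms = [ln.split() for ln in sections.get("atoms", [])]
    n_atoms = len(atoms)
    atom_name = np.array([a[1] for a in atoms])
    res_id = np.array([int(a[2]) for a in atoms])
    res_name = np.array([a[3] for a in atoms])
    chain_id = np.array([a[4] for a in atoms])

    def parse(section, n_idx):
        idx, params = [], []
        for ln in sections.get(section, []):
            f = ln.split()
            idx.append([int(x) - 1 for x in f[:n_idx]])
            params.append(f[n_idx:])
        return idx, params

    b_idx, b_par = parse("bonds", 2)
    a_idx, a_par = parse("angles", 3)
    d_idx, d_par = parse("dihedrals", 4)
    p_idx, p_par = parse("pairs", 2)

    prop_i, prop_p0, prop_w, prop_bb = [], [], [], []
    imp_i, imp_c0, imp_w = [], [], []
    pla_i, pla_w = [], []
    for q, par in zip(d_idx, d_par):
        func = int(par[0])
        if func == 1:
            prop_i.append(q)
            prop_p0.append(float(par[1]))
            prop_w.append(float(par[2]))
            prop_bb.append(bool(int(par[3])))
        elif func == 2:
            imp_i.append(q)
            imp_c0.append(float(par[1]))
            imp_w.append(float(par[2]))
        elif func == 3:
            pla_i.append(q)
            pla_w.append(float(par[1]))
        else:
            raise ValueError(f"unknown dihedral function code {func}")

    bonded = BondedTerms(
        bonds_idx=np.array(b_idx, dtype=int).reshape(-1, 2),
        bonds_r0=np.array([float(p[1]) for p in b_par]),
        angles_idx=np.array(a_idx, dtype=int).reshape(-1, 3),
        angles_theta0=np.array([float(p[1]) for p in a_par]),
        impropers_idx=np.array(imp_i, dtype=int).reshape(-1, 4),
        impropers_chi0=np.array(imp_c0),
        planars_idx=np.array(pla_i, dtype=int).reshape(-1, 4),
        dihedrals_idx=np.array(prop_i, dtype=int).reshape(-1, 4),
        dihedrals_phi0=np.array(prop_p0),
        dihedrals_backbone=np.array(prop_bb, dtype=bool),
    )
    sig, eps, cut = (float(x) for x in sections["nonbonded"][0].split())
    coord = np.array(
        [[float(v) for v in ln.split()] for ln in sections.get("coordinates", [])]
    ).reshape(-1, 3)
    restraints = [
        DistanceRestraint(int(f[0]) - 1, int(f[1]) - 1, float(f[2]), float(f[3]))
        for f in (ln.split() for ln in sections.get("restraints", []))
    ]
    exclusions = np.array(
        [[int(x) - 1 for x in ln.split()] for ln in sections.get("exclusions", [])],
        dtype=int,
    ).reshape(-1, 2)

    ff = ForceField(
        n_atoms=n_atoms,
        ref_coord=coord,
        bonded=bonded,
        bonds_w=np.array([float(p[2]) for p in b_par]),
        angles_w=np.array([float(p[2]) for p in a_par]),
        impropers_w=np.array(imp_w),
        planars_w=np.array(pla_w),
        dihedrals_w=np.array(prop_w),
        contacts_idx=np.array(p_idx, dtype=int).reshape(-1, 2),
        contacts_sigma=np.array([float(p[1]) for p in p_par]),
        contacts_w=np.array([float(p[2]) for p in p_par]),
        exclusions=exclusions,
        sigma_nc=sig,
        eps_nc=eps,
        nc_cutoff=cut,
        restraints=restraints,
        chain_id=chain_id,
        res_id=res_id,
        res_name=res_name,
        atom_name=atom_name,
        provenance={"source": os.fspath(path)},
    )
    ff.provenance["hash"] = ff.hash()
    return ff
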