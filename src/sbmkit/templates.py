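"""Residue topology templates and reference bond/angle equilibrium values.

A template lists, per residue type: atom names, intra-residue covalent bonds,
the polymer link (the atom that bonds to the next residue and the atom that
receives the bond from the previous one), the backbone atom-name set, improper
quadruples (chirality / branch centers, harmonic about the native value) and
planar quadruples (kept flat by a cos(2x) well with minima at 0 and 180 deg).
Quadruple entries may reference the next residue with a ``+`` prefix
(e.g. ``+N``) or the previous one with ``-``.

The reference table of bond/angle equilibrium values mirrors the idea of
taking these from a published protein force field's parameter set; entries are
keyed by atom-name pairs/triples.  Residues absent from the table fall back to
the value measured in the input structure (logged by the builder).  The toy
residue types used by the synthetic generator (TPR/TLK/TNU) rely entirely on
that fallback, so their native geometry is exactly the energy minimum.
"""
from __future__ import annotations

import dataclasses


@dataclasses.dataclass(frozen=True)
class ResidueTemplate:
    name: str
    atoms: tuple[str, ...]
    bonds: tuple[tuple[str, str], ...]
    link_prev: str | None  # atom that bonds to the previous residue's link_next
    link_next: str | None  # atom that bonds to the next residue's link_prev
    backbone: frozenset
    impropers: tuple[tuple[str, str, str, str], ...] = ()
    planars: tuple[tuple[str, str, str, str], ...] = ()


PROTEIN_BACKBONE = frozenset({"N", "CA", "C", "O"})
NUCLEIC_BACKBONE = frozenset({"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"})

# -- toy residues used by the synthetic generator --------------------------------

TPR = ResidueTemplate(
    name="TPR",
    atoms=("N", "CA", "C", "CB", "CG"),
    bonds=(("N", "CA"), ("CA", "C"), ("CA", "CB"), ("CB", "CG")),
    link_prev="N",
    link_next="C",
    backbone=PROTEIN_BACKBONE,
    impropers=(("N", "C", "CA", "CB"),),       # chirality-like center at CA
    planars=(("CA", "C", "+N", "+CA"),),       # peptide-bond-like plane
)

# backbone-only flexible linker residue (no branches, no planars/impropers)
TLK = ResidueTemplate(
    name="TLK",
    atoms=("N", "CA", "C"),
    bonds=(("N", "CA"), ("CA", "C")),
    link_prev="N",
    link_next="C",
    backbone=PROTEIN_BACKBONE,
)

# nucleic-like residue for the disordered-tail stand-in
TNU = ResidueTemplate(
    name="TNU",
    atoms=("P", "O5'", "C5'", "C4'", "C3'", "O3'", "N1"),
    bonds=(
        ("P", "O5'"), ("O5'", "C5'"), ("C5'", "C4'"),
        ("C4'", "C3'"), ("C3'", "O3'"), ("C5'", "N1"),
    ),
    link_prev="P",
    link_next="O3'",
    backbone=NUCLEIC_BACKBONE,
    impropers=(("O5'", "C4'", "C5'", "N1"),),  # branch center at C5'
)

# single-atom pseudo-residues: bound cofactor stand-in and methylation target
LIG = ResidueTemplate("LIG", ("S1",), (), None, None, frozenset())
TRG = ResidueTemplate("TRG", ("C1",), (), None, None, frozenset())

# -- standard amino acids (minimal demo set) -------------------------------------

ALA = ResidueTemplate(
    name="ALA",
    atoms=("N", "CA", "C", "O", "CB"),
    bonds=(("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")),
    link_prev="N",
    link_next="C",
    backbone=PROTEIN_BACKBONE,
    impropers=(("N", "C", "CA", "CB"),),
    planars=(("O", "C", "+N", "+CA"),),
)

GLY = ResidueTemplate(
    name="GLY",
    atoms=("N", "CA", "C", "O"),
    bonds=(("N", "CA"), ("CA", "C"), ("C", "O")),
    link_prev="N",
    link_next="C",
    backbone=PROTEIN_BACKBONE,
    planars=(("O", "C", "+N", "+CA"),),
)

DEFAULT_TEMPLATES: dict[str, ResidueTemplate] = {
    t.name: t for t in (TPR, TLK, TNU, LIG, TRG, ALA, GLY)
}

# -- reference equilibrium values (Angstrom / degrees), standard residues only ---
# Keys are frozensets of atom names (bonds) or (end, center, end) name triples
# (angles); applies to the standard amino-acid templates above.

REFERENCE_BOND_LENGTHS: dict[frozenset, float] = {
    frozenset({"N", "CA"}): 1.449,
    frozenset({"CA", "C"}): 1.522,
    frozenset({"C", "O"}): 1.229,
    frozenset({"CA", "CB"}): 1.526,
    # peptide link C(i)-N(i+1)
    frozenset({"C", "N"}): 1.335,
}

REFERENCE_ANGLES_DEG: dict[tuple, float] = {
    ("N", "CA", "C"): 110.1,
    ("CA", "C", "O"): 120.8,
    ("CA", "C", "N"): 116.6,
    ("C", "N", "CA"): 121.9,
    ("N", "CA", "CB"): 109.7,
    ("C", "CA", "CB"): 110.1,
}

REFERENCE_RESIDUES = {"ALA", "GLY"}


def lookup_bond_length(res_name: str, name_i: str, name_j: str) -> float | None:
    if res_name not in REFERENCE_RESIDUES:
        return None
    return REFERENCE_BOND_LENGTHS.get(frozenset({name_i, name_j}))


def lookup_angle_deg(res_name: str, names: tuple[str, str, str]) -> float | None:
    if res_name not in REFERENCE_RESIDUES:
        return None
    val = REFERENCE_ANGLES_DEG.get(names)
    if val is None:
        val = REFERENCE_ANGLES_DEG.get(names[::-1])
    return val
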