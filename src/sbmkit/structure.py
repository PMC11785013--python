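"""All-atom structure container, PDB/mmCIF input/output and a small selection language.

The container keeps author chain/residue numbering so that selections match the
conventions used by PDB viewers (``chain P and resid 274``).  Hydrogens and
waters are always stripped on read: the downstream force field is built over
non-hydrogen atoms only.
"""
from __future__ import annotations

import dataclasses
import logging
import os
import re
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io import pdb as bpdb
from biotite.structure.io import pdbx as bpdbx

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP3"}
HYDROGEN_ELEMENTS = {"H", "D", "T"}


@dataclasses.dataclass(frozen=True)
class Atom:
    """A single atom record (author numbering, coordinates in Angstrom)."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    coordinates: np.ndarray
    occupancy: float
    b_factor: float
    hetero: bool = False


class Structure:
    """An ordered all-atom coordinate set backed by parallel numpy arrays."""

    def __init__(
        self,
        serial: np.ndarray,
        name: np.ndarray,
        element: np.ndarray,
        res_name: np.ndarray,
        chain_id: np.ndarray,
        res_id: np.ndarray,
        icode: np.ndarray,
        coord: np.ndarray,
        occupancy: np.ndarray | None = None,
        b_factor: np.ndarray | None = None,
        hetero: np.ndarray | None = None,
        source: str = "",
        model_number: int = 1,
    ):
        n = len(name)
        self.serial = np.asarray(serial, dtype=int)
        self.name = np.asarray(name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.res_name = np.asarray(res_name, dtype="U5")
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.res_id = np.asarray(res_id, dtype=int)
        self.icode = np.asarray(icode, dtype="U1")
        self.coord = np.asarray(coord, dtype=float).reshape(n, 3)
        self.occupancy = (
            np.ones(n) if occupancy is None else np.asarray(occupancy, dtype=float)
        )
        self.b_factor = (
            np.zeros(n) if b_factor is None else np.asarray(b_factor, dtype=float)
        )
        self.hetero = (
            np.zeros(n, dtype=bool) if hetero is None else np.asarray(hetero, dtype=bool)
        )
        self.source = source
        self.model_number = model_number
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates in structure")

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.name)

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    def __getitem__(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            element=str(self.element[i]),
            residue_name=str(self.res_name[i]),
            chain_id=str(self.chain_id[i]),
            residue_number=int(self.res_id[i]),
            insertion_code=str(self.icode[i]),
            coordinates=self.coord[i].copy(),
            occupancy=float(self.occupancy[i]),
            b_factor=float(self.b_factor[i]),
            hetero=bool(self.hetero[i]),
        )

    def subset(self, indices: Sequence[int]) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            self.serial[idx], self.name[idx], self.element[idx], self.res_name[idx],
            self.chain_id[idx], self.res_id[idx], self.icode[idx], self.coord[idx],
            self.occupancy[idx], self.b_factor[idx], self.hetero[idx],
            source=self.source, model_number=self.model_number,
        )

    def copy(self) -> "Structure":
        return self.subset(np.arange(self.n_atoms))

    # -- residue bookkeeping ------------------------------------------------------
    def residue_keys(self) -> np.ndarray:
        """Per-atom (chain, resid, icode) key as a structured view for grouping."""
        return np.array(
            list(zip(self.chain_id, self.res_id, self.icode)),
            dtype=[("chain", "U4"), ("resid", int), ("icode", "U1")],
        )

    def residue_index(self) -> np.ndarray:
        """Integer residue index per atom, grouped by (chain, resid, icode).

        Atoms sharing a residue key map to one index even if scattered, so
        residue grouping is invariant to atom ordering.
        """
        keys = self.residue_keys()
        _, inverse = np.unique(keys, return_inverse=True)
        return inverse

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        mask = (self.chain_id == chain) & (self.res_id == resid) & (self.name == name)
        hits = np.flatnonzero(mask)
        if len(hits) != 1:
            raise KeyError(f"atom {chain}/{resid}/{name}: {len(hits)} matches")
        return int(hits[0])

    # -- biotite bridge -----------------------------------------------------------
    @classmethod
    def from_biotite(cls, arr: bst.AtomArray, source: str = "", model_number: int = 1):
        occ = arr.get_annotation("occupancy") if "occupancy" in arr.get_annotation_categories() else None
        bf = arr.get_annotation("b_factor") if "b_factor" in arr.get_annotation_categories() else None
        ic = arr.ins_code if "ins_code" in arr.get_annotation_categories() else np.full(arr.array_length(), "")
        serial = (
            arr.get_annotation("atom_id")
            if "atom_id" in arr.get_annotation_categories()
            else np.arange(1, arr.array_length() + 1)
        )
        return cls(
            serial, arr.atom_name, arr.element, arr.res_name, arr.chain_id,
            arr.res_id, ic, arr.coord, occ, bf, arr.hetero,
            source=source, model_number=model_number,
        )

    def to_biotite(self) -> bst.AtomArray:
        arr = bst.AtomArray(self.n_atoms)
        arr.coord = self.coord.astype(np.float32)
        arr.atom_name = self.name
        arr.element = self.element
        arr.res_name = self.res_name
        arr.chain_id = self.chain_id
        arr.res_id = self.res_id
        arr.ins_code = self.icode.astype("U1")
        arr.hetero = self.hetero
        arr.set_annotation("occupancy", self.occupancy)
        arr.set_annotation("b_factor", self.b_factor)
        arr.set_annotation("atom_id", self.serial)
        return arr


# ---------------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------------

def read_structure(
    path: str | os.PathLike,
    model: int = 1,
    altloc_policy: str = "occupancy",
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Hydrogens and waters are dropped; alternate locations are resolved by the
    given policy (``"occupancy"``: keep the highest-occupancy conformer, ties
    resolve to the first listed, conventionally 'A'; ``"first"``: keep the
    first conformer).  Author chain ids and residue numbers are preserved.
    """
    if altloc_policy not in ("occupancy", "first"):
        raise ValueError(f"unknown altloc policy: {altloc_policy!r}")
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".cif", ".mmcif", ".pdbx"):
            cif = bpdbx.CIFFile.read(path)
            arr = bpdbx.get_structure(
                cif, model=model, altloc=altloc_policy,
                extra_fields=["occupancy", "b_factor", "atom_id"],
            )
        else:
            pdbf = bpdb.PDBFile.read(path)
            n_models = pdbf.get_model_count()
            if model > n_models:
                raise KeyError(f"model {model} not found ({n_models} models in {path})")
            arr = pdbf.get_structure(
                model=model, altloc=altloc_policy,
                extra_fields=["occupancy", "b_factor", "atom_id"],
            )
    except KeyError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc

    keep = ~np.isin(arr.element, list(HYDROGEN_ELEMENTS)) & ~np.isin(
        arr.res_name, list(WATER_NAMES)
    )
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("dropped %d hydrogen/water atoms from %s", n_dropped, path)
    arr = arr[keep]
    struct = Structure.from_biotite(arr, source=path, model_number=model)
    _check_unique(struct)
    return struct


def _check_unique(struct: Structure) -> None:
    keys = list(zip(struct.chain_id, struct.res_id, struct.icode, struct.name))
    if len(set(keys)) != len(keys):
        logger.warning("duplicate (chain, resid, name) atom keys after altloc resolution")


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a structure as standard PDB records (coordinates to 3 decimals).

    Structures above 99,999 atoms fall back to hybrid-36 serial numbers so the
    file stays re-readable.
    """
    if structure.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    arr = structure.to_biotite()
    # PDB serials must be contiguous & valid; reassign in structure order
    arr.set_annotation("atom_id", np.arange(1, structure.n_atoms + 1))
    pdbf = bpdb.PDBFile()
    pdbf.set_structure(arr, hybrid36=structure.n_atoms > 99999)
    pdbf.write(os.fspath(path))


# ---------------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or", "not", "(", ")"}


@dataclasses.dataclass(frozen=True)
class Selection:
    """A declarative atom filter.

    Grammar (``or`` binds loosest, then ``and``, then ``not``)::

        expr      := and_expr ('or' and_expr)*
        and_expr  := unary ('and' unary)*
        unary     := 'not' unary | '(' expr ')' | primitive
        primitive := 'all' | 'none' | 'hetero'
                   | 'chain'   id[,id...]
                   | 'name'    nm[,nm...]
                   | 'resname' nm[,nm...]
                   | 'element' el[,el...]
                   | 'resid'   n | a:b  [,...]

    Examples: ``"chain A and name CA"``, ``"not (chain M)"``, ``"resid 5:8"``.
    """

    expression: str

    def __str__(self) -> str:
        return self.expression


def select_atoms(structure: Structure, selection: Selection | str) -> np.ndarray:
    """Resolve a selection to a sorted array of atom indices (structure order)."""
    expr = selection.expression if isinstance(selection, Selection) else selection
    mask = _eval_selection(structure, expr)
    return np.flatnonzero(mask)


def _eval_selection(structure: Structure, expr: str) -> np.ndarray:
    tokens = _TOKEN_RE.findall(expr)
    if not tokens:
        raise ValueError("empty selection expression")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"unexpected end of selection expression {expr!r}")
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        mask = parse_and()
        while peek() == "or":
            take()
            mask = mask | parse_and()
        return mask

    def parse_and():
        mask = parse_unary()
        while peek() == "and":
            take()
            mask = mask & parse_unary()
        return mask

    def parse_unary():
        tok = peek()
        if tok == "not":
            take()
            return ~parse_unary()
        if tok == "(":
            take()
            mask = parse_or()
            if take() != ")":
                raise ValueError(f"unbalanced parentheses in selection {expr!r}")
            return mask
        return parse_primitive()

    def parse_values():
        vals: list[str] = []
        while peek() is not None and peek() not in _KEYWORDS:
            vals.extend(v for v in take().split(",") if v)
            # stop after a comma-free single token unless next token continues a list
            if peek() is None or peek() in _KEYWORDS:
                break
        if not vals:
            raise ValueError(f"selection keyword without values in {expr!r}")
        return vals

    def parse_primitive():
        tok = take()
        n = structure.n_atoms
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "none":
            return np.zeros(n, dtype=bool)
        if tok == "hetero":
            return structure.hetero.copy()
        if tok == "chain":
            vals = parse_values()
            for v in vals:
                if v not in structure.chain_id:
                    logger.warning("selection references nonexistent chain %r", v)
            return np.isin(structure.chain_id, vals)
        if tok == "name":
            return np.isin(structure.name, parse_values())
        if tok == "resname":
            return np.isin(structure.res_name, parse_values())
        if tok == "element":
            return np.isin(structure.element, parse_values())
        if tok == "resid":
            mask = np.zeros(n, dtype=bool)
            for v in parse_values():
                if ":" in v:
                    a, b = v.split(":")
                    mask |= (structure.res_id >= int(a)) & (structure.res_id <= int(b))
                else:
                    mask |= structure.res_id == int(v)
            return mask
        raise ValueError(f"unknown selection token {tok!r} in {expr!r}")

    mask = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in selection {expr!r}")
    return mask
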