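"""Force-field construction: bonded terms, normalization, disorder mask, restraints."""
import dataclasses

import numpy as np
import pytest

import sbmkit
from sbmkit.builder import (
    CONTACT_SIGMA_SCALE,
    EPS_CHI_IMP,
    EPS_NC,
    EPS_PLANAR,
    EPS_R,
    EPS_THETA,
    measure_dihedral,
    spring_constant_per_A2,
)
from sbmkit.templates import DEFAULT_TEMPLATES

from conftest import make_bonded


def _ala_dipeptide():
    """Two ALA residues in a bent conformation (no template-table geometry)."""
    names = ["N", "CA", "C", "O", "CB"] * 2
    coord = np.array([
        [0.0, 0.0, 0.0], [1.4, 0.3, 0.0], [2.1, -0.4, 1.1], [1.8, -1.5, 1.5],
        [2.2, 1.6, -0.4],
        [3.2, 0.3, 1.6], [4.0, -0.2, 2.7], [5.4, 0.4, 2.8], [5.8, 1.4, 2.2],
        [4.2, -1.8, 2.6],
    ])
    n = len(names)
    return sbmkit.Structure(
        serial=np.arange(1, n + 1), name=np.array(names),
        element=np.array([nm[0] for nm in names]),
        res_name=np.full(n, "ALA"), chain_id=np.full(n, "A"),
        res_id=np.repeat([1, 2], 5), icode=np.full(n, ""), coord=coord,
    )


class TestBondedTerms:
    def test_ala_dipeptide_term_counts_match_templates(self):
        s = _ala_dipeptide()
        b = sbmkit.extract_bonded_terms(s)
        tmpl = DEFAULT_TEMPLATES["ALA"]
        # independent count: intra bonds per residue + one peptide link
        assert len(b.bonds_idx) == 2 * len(tmpl.bonds) + 1
        assert len(b.impropers_idx) == 2 * len(tmpl.impropers)
        # the second residue's planar group has no +N partner
        assert len(b.planars_idx) == 1

    def test_dihedral_equilibria_measured_from_input(self, toy):
        structure, _ = toy
        b = sbmkit.extract_bonded_terms(structure)
        measured = measure_dihedral(structure.coord, b.dihedrals_idx)
        np.testing.assert_allclose(b.dihedrals_phi0, measured, atol=1e-6)

    def test_chain_break_gets_no_bond(self):
        s = _ala_dipeptide()
        s.res_id = np.repeat([1, 3], 5)  # gap in author numbering
        b = sbmkit.extract_bonded_terms(s)
        tmpl = DEFAULT_TEMPLATES["ALA"]
        assert len(b.bonds_idx) == 2 * len(tmpl.bonds)  # no peptide link

    def test_unknown_residue_raises_with_name(self, toy):
        structure, _ = toy
        bad = structure.copy()
        bad.res_name = bad.res_name.copy()
        bad.res_name[bad.res_name == "TPR"] = "XXX"
        with pytest.raises(KeyError, match="XXX"):
            sbmkit.extract_bonded_terms(bad)

    def test_backbone_classification_uses_template_backbone_sets(self, toy):
        structure, _ = toy
        b = sbmkit.extract_bonded_terms(structure)
        sidechain = b.dihedrals_idx[~b.dihedrals_backbone]
        assert len(sidechain) > 0
        # every sidechain dihedral touches at least one CB/CG/N1 atom
        branch = np.isin(structure.name, ["CB", "CG", "N1"])
        assert np.all(np.any(branch[sidechain], axis=1))


class TestNormalization:
    def test_worked_example_weights(self):
        """100 atoms, 40 contacts, 20 backbone + 10 sidechain dihedrals.

        Solving: sum(eps_c) + sum(eps_dih) = 100, contacts:dihedrals = 2:1,
        eps_bb = 2 eps_sc uniform -> sum(eps_c) = 200/3, eps_sc = (100/3)/50.
        """
        rng = np.random.default_rng(5)
        coord = rng.uniform(0, 50, (100, 3))
        s = sbmkit.Structure(
            serial=np.arange(1, 101), name=np.full(100, "C"),
            element=np.full(100, "C"), res_name=np.full(100, "UNK"),
            chain_id=np.full(100, "A"), res_id=np.arange(1, 101),
            icode=np.full(100, ""), coord=coord,
        )
        quad = np.arange(4) + np.arange(30)[:, None]
        bonded = make_bonded(
            dihedrals_idx=quad,
            dihedrals_phi0=np.zeros(30),
            dihedrals_backbone=np.array([True] * 20 + [False] * 10),
        )
        contacts = np.column_stack([np.arange(40), np.arange(40) + 50])
        ff = sbmkit.assign_energy_scales(s, bonded, contacts)
        assert ff.total_contact_energy == pytest.approx(200.0 / 3.0)
        assert ff.dihedrals_w[0] == pytest.approx(4.0 / 3.0)   # backbone
        assert ff.dihedrals_w[-1] == pytest.approx(2.0 / 3.0)  # sidechain
        # constraint identities
        assert ff.total_contact_energy / ff.total_dihedral_energy == pytest.approx(2.0)
        assert ff.total_contact_energy + ff.total_dihedral_energy == pytest.approx(100.0)

    def test_fixed_weights_take_reference_values(self, toy_ff):
        assert np.all(toy_ff.bonds_w == EPS_R)
        assert np.all(toy_ff.angles_w == EPS_THETA)
        assert np.all(toy_ff.impropers_w == EPS_CHI_IMP)
        assert np.all(toy_ff.planars_w == EPS_PLANAR)
        assert toy_ff.eps_nc == EPS_NC

    def test_contact_sigma_is_scaled_native_distance(self, toy, toy_ff):
        structure, _ = toy
        d = np.linalg.norm(
            structure.coord[toy_ff.contacts_idx[:, 0]]
            - structure.coord[toy_ff.contacts_idx[:, 1]], axis=1,
        )
        np.testing.assert_allclose(toy_ff.contacts_sigma, CONTACT_SIGMA_SCALE * d)
        assert np.all(d <= 6.0 + 1e-9)

    def test_doubling_atoms_doubles_stabilizing_weights(self, toy):
        structure, _ = toy
        b = sbmkit.extract_bonded_terms(structure)
        contacts = sbmkit.shadow_contact_map(structure, b)
        ff1 = sbmkit.assign_energy_scales(structure, b, contacts)
        n = structure.n_atoms
        # same term lists on a structure with twice the atoms (copy placed far away)
        far = structure.coord + np.array([500.0, 0.0, 0.0])
        doubled = sbmkit.Structure(
            serial=np.arange(1, 2 * n + 1),
            name=np.r_[structure.name, structure.name],
            element=np.r_[structure.element, structure.element],
            res_name=np.r_[structure.res_name, structure.res_name],
            chain_id=np.r_[structure.chain_id, np.full(n, "Z")],
            res_id=np.r_[structure.res_id, structure.res_id],
            icode=np.r_[structure.icode, structure.icode],
            coord=np.vstack([structure.coord, far]),
        )
        ff2 = sbmkit.assign_energy_scales(doubled, b, contacts)
        np.testing.assert_allclose(ff2.contacts_w, 2.0 * ff1.contacts_w)
        np.testing.assert_allclose(ff2.dihedrals_w, 2.0 * ff1.dihedrals_w)

    def test_zero_contacts_or_dihedrals_is_an_error(self, toy):
        structure, _ = toy
        b = sbmkit.extract_bonded_terms(structure)
        with pytest.raises(ValueError):
            sbmkit.assign_energy_scales(structure, b, np.empty((0, 2), int))


class TestDisorderMask:
    def test_empty_spec_is_identity(self, toy_tail_ff):
        masked = sbmkit.apply_disorder_mask(toy_tail_ff, sbmkit.DisorderSpec(()))
        assert len(masked.contacts_idx) == len(toy_tail_ff.contacts_idx)
        assert len(masked.bonded.dihedrals_idx) == len(toy_tail_ff.bonded.dihedrals_idx)

    def test_exact_removal_counts(self, toy_tail, toy_tail_ff):
        structure, disorder, _ = toy_tail
        tail_atoms = structure.chain_id == "B"
        touches = (
            tail_atoms[toy_tail_ff.contacts_idx[:, 0]]
            | tail_atoms[toy_tail_ff.contacts_idx[:, 1]]
        )
        masked = sbmkit.apply_disorder_mask(toy_tail_ff, disorder)
        assert masked.provenance["disorder_removed_contacts"] == int(touches.sum())
        assert len(masked.contacts_idx) == len(toy_tail_ff.contacts_idx) - int(touches.sum())
        # no remaining contact touches a masked residue
        rem = masked.contacts_idx
        assert not np.any(tail_atoms[rem[:, 0]] | tail_atoms[rem[:, 1]])

    def test_masked_chain_keeps_polymer_connectivity(self, toy_tail, toy_tail_ff_masked):
        structure, _, _ = toy_tail
        tail_idx = np.flatnonzero(structure.chain_id == "B")
        bonds = toy_tail_ff_masked.bonded.bonds_idx
        tail_bonds = bonds[np.all(np.isin(bonds, tail_idx), axis=1)]
        # the tail bond graph spans all tail atoms
        import networkx as nx
        g = nx.Graph(tail_bonds.tolist())
        g.add_nodes_from(tail_idx.tolist())
        assert nx.number_connected_components(g) == 1

    def test_unresolvable_range_raises(self, toy_tail_ff):
        with pytest.raises(ValueError):
            sbmkit.apply_disorder_mask(
                toy_tail_ff, sbmkit.DisorderSpec((("Q", 1, 5),))
            )


class TestRestraints:
    def test_unit_conversion_from_per_nm2(self):
        assert spring_constant_per_A2(150.0) == pytest.approx(1.5)

    @pytest.mark.parametrize(
        "r,expected", [(5.0, 0.0), (7.0, 3.0), (3.0, 3.0)],
        ids=["at-minimum", "stretched-2A", "compressed-2A"],
    )
    def test_restraint_energy_values(self, r, expected):
        from conftest import make_ff
        ff = make_ff(2)
        ff = sbmkit.add_distance_restraint(ff, 0, 1, 5.0, 1.5)
        coord = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        _, _, bd = sbmkit.potential_energy_and_forces(ff, coord)
        assert bd["restraints"] == pytest.approx(expected)

    def test_zero_spring_constant_changes_nothing(self, toy, toy_ff):
        structure, meta = toy
        ff0 = sbmkit.add_distance_restraint(
            toy_ff, meta["ligand_atom"]["index"], meta["target_atom"]["index"], 5.0, 0.0
        )
        rng = np.random.default_rng(2)
        x = structure.coord + rng.normal(0, 0.1, structure.coord.shape)
        e0, f0, _ = sbmkit.potential_energy_and_forces(toy_ff, x)
        e1, f1, _ = sbmkit.potential_energy_and_forces(ff0, x)
        assert e1 == pytest.approx(e0)
        np.testing.assert_array_equal(f0, f1)

    def test_identical_atoms_rejected(self, toy_ff):
        with pytest.raises(ValueError):
            sbmkit.add_distance_restraint(toy_ff, 3, 3, 5.0, 1.5)
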