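"""Shared fixtures: toy systems and force fields built once per session."""
import numpy as np
import pytest

import sbmkit


@pytest.fixture(scope="session")
def toy():
    """Default native two-domain toy system (no tail) plus ground truth."""
    return sbmkit.make_toy_two_domain_system()


@pytest.fixture(scope="session")
def toy_tail():
    """Toy system with the disordered nucleic tail appended."""
    structure, meta = sbmkit.make_toy_two_domain_system()
    tailed, disorder = sbmkit.make_disordered_tail(structure, sbmkit.ToySpec())
    return tailed, disorder, meta


@pytest.fixture(scope="session")
def toy_ff(toy):
    structure, _ = toy
    return sbmkit.build_force_field(structure)


@pytest.fixture(scope="session")
def toy_tail_ff(toy_tail):
    """Unmasked force field over the tailed structure."""
    structure, _, _ = toy_tail
    return sbmkit.build_force_field(structure)


@pytest.fixture(scope="session")
def toy_tail_ff_masked(toy_tail):
    structure, disorder, _ = toy_tail
    return sbmkit.build_force_field(structure, disorder=disorder)


def make_bonded(**kw):
    """Minimal BondedTerms with empty defaults, overridable per term."""
    d = dict(
        bonds_idx=np.empty((0, 2), int), bonds_r0=np.empty(0),
        angles_idx=np.empty((0, 3), int), angles_theta0=np.empty(0),
        impropers_idx=np.empty((0, 4), int), impropers_chi0=np.empty(0),
        planars_idx=np.empty((0, 4), int),
        dihedrals_idx=np.empty((0, 4), int), dihedrals_phi0=np.empty(0),
        dihedrals_backbone=np.empty(0, bool),
    )
    d.update(kw)
    return sbmkit.BondedTerms(**d)


def all_pairs(n):
    """Every i<j pair — used to switch off the nc background in term tests."""
    return np.array([(i, j) for i in range(n) for j in range(i + 1, n)], dtype=int)


def make_ff(n_atoms, bonded=None, **kw):
    """Hand-assembled ForceField for single-term unit tests."""
    bonded = bonded if bonded is not None else make_bonded()
    d = dict(
        n_atoms=n_atoms, ref_coord=np.zeros((n_atoms, 3)), bonded=bonded,
        bonds_w=np.full(len(bonded.bonds_idx), 7.0),
        angles_w=np.full(len(bonded.angles_idx), 5.0),
        impropers_w=np.full(len(bonded.impropers_idx), 3.0),
        planars_w=np.full(len(bonded.planars_idx), 2.0),
        dihedrals_w=np.full(len(bonded.dihedrals_idx), 1.5),
        contacts_idx=np.empty((0, 2), int), contacts_sigma=np.empty(0),
        contacts_w=np.empty(0), exclusions=np.empty((0, 2), int),
    )
    d.update(kw)
    return sbmkit.ForceField(**d)


def free_dimer(k=1.5, r0=5.0, as_restraint=True):
    """Two atoms coupled only through one harmonic distance term."""
    if as_restraint:
        ff = make_ff(2, exclusions=np.array([[0, 1]]))
        ff = sbmkit.add_distance_restraint(ff, 0, 1, r0, k)
    else:
        ff = make_ff(2, make_bonded(bonds_idx=np.array([[0, 1]]),
                                    bonds_r0=np.array([r0])),
                     exclusions=np.array([[0, 1]]))
        ff.bonds_w = np.array([k])
    start = np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
    return ff, start


@pytest.fixture(scope="session")
def equipartition_traj(toy, toy_ff):
    """Long thermostatted run of the toy system at T = 0.5 (shared)."""
    structure, _ = toy
    cfg = sbmkit.SimConfig(temperature=0.5, n_steps=30_000, save_interval=20,
                           seed=21)
    return sbmkit.run_langevin(toy_ff, sbmkit.State(structure.coord.copy()), cfg)


@pytest.fixture(scope="session")
def harmonic_traj():
    """Long run of a single harmonic bond oscillator at T = 0.5 (shared)."""
    ff, start = free_dimer(k=1.0, r0=20.0, as_restraint=False)
    cfg = sbmkit.SimConfig(temperature=0.5, timestep=0.05, friction=2.0,
                           n_steps=200_000, save_interval=20, seed=13)
    return sbmkit.run_langevin(ff, sbmkit.State(start.copy()), cfg)


def numeric_forces(ff, coord, indices=None, h=1e-6, include_restraints=True):
    """Central-difference forces, the independent check on the analytic ones."""
    idx = range(len(coord)) if indices is None else indices
    out = {}
    for i in idx:
        row = np.zeros(3)
        for d in range(3):
            xp = coord.copy(); xp[i, d] += h
            xm = coord.copy(); xm[i, d] -= h
            ep = sbmkit.potential_energy_and_forces(ff, xp, include_restraints)[0]
            em = sbmkit.potential_energy_and_forces(ff, xm, include_restraints)[0]
            row[d] = -(ep - em) / (2 * h)
        out[i] = row
    return out
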