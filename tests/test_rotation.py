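"""Superposition, Euler-Rodrigues decomposition, a.s.d. and free-energy profiles."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation as ScipyRotation

import sbmkit


def _frames(*coords):
    return sbmkit.Trajectory(frames=np.array(coords), config=sbmkit.SimConfig())


class TestKabsch:
    def test_identity_fit(self, toy):
        structure, _ = toy
        t = sbmkit.kabsch_fit(structure.coord, structure.coord)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-10)
        assert t.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_constructed_transform_is_recovered(self, toy):
        structure, _ = toy
        rot = ScipyRotation.from_euler("z", 30, degrees=True).as_matrix()
        mobile = structure.coord @ rot.T + np.array([1.0, 2.0, 3.0])
        t = sbmkit.kabsch_fit(structure.coord, mobile)
        assert t.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(t.rotation @ rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.apply(mobile), structure.coord, atol=1e-9)

    def test_noisy_fit_matches_scipy_oracle(self):
        """Same rotation and rmsd as scipy's independent align_vectors SVD."""
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 5, (200, 3))
        rot = ScipyRotation.from_rotvec([0.3, -0.2, 0.5]).as_matrix()
        mobile = ref @ rot.T + rng.normal(0, 0.5, ref.shape) + [4.0, -2.0, 1.0]
        t = sbmkit.kabsch_fit(ref, mobile)
        ref_c = ref - ref.mean(axis=0)
        mob_c = mobile - mobile.mean(axis=0)
        oracle, rssd = ScipyRotation.align_vectors(ref_c, mob_c)
        np.testing.assert_allclose(t.rotation, oracle.as_matrix(), atol=1e-8)
        assert t.rmsd == pytest.approx(rssd / np.sqrt(len(ref)), rel=1e-6)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError):
            sbmkit.kabsch_fit(line, line)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            sbmkit.kabsch_fit(np.zeros((4, 3)), np.zeros((5, 3)))


class TestEulerRodrigues:
    def test_identical_rotations_flagged_undefined(self):
        rot = ScipyRotation.from_euler("x", 25, degrees=True).as_matrix()
        axis, angle = sbmkit.er_axis_angle(rot, rot)
        assert axis is None
        assert angle == pytest.approx(0.0, abs=1e-6)

    def test_constructed_relative_rotation(self):
        ra = np.eye(3)
        rb = ScipyRotation.from_euler("z", 45, degrees=True).as_matrix()
        axis, angle = sbmkit.er_axis_angle(ra, rb)
        assert angle == pytest.approx(45.0, abs=1e-9)
        np.testing.assert_allclose(axis, [0.0, 0.0, 1.0], atol=1e-9)

    def test_angle_in_range_for_random_pairs(self):
        rng = np.random.default_rng(8)
        for r in ScipyRotation.random(20, rng=rng):
            axis, angle = sbmkit.er_axis_angle(np.eye(3), r.as_matrix())
            assert 0.0 <= angle <= 180.0
            if axis is not None:
                # axis/angle reproduce the rotation
                back = ScipyRotation.from_rotvec(
                    np.deg2rad(angle) * axis
                ).as_matrix()
                np.testing.assert_allclose(back, r.as_matrix(), atol=1e-6)

    def test_non_orthogonal_input_rejected(self):
        with pytest.raises(ValueError):
            sbmkit.er_axis_angle(np.eye(3) * 2.0, np.eye(3))


class TestEulerZYZ:
    def test_round_trip_on_1000_random_rotations(self):
        """compose(phi, theta, psi) reproduces the input to 1e-6."""
        rng = np.random.default_rng(17)
        mats = ScipyRotation.random(1000, rng=rng).as_matrix()
        worst = 0.0
        for m in mats:
            phi, theta, psi = sbmkit.euler_zyz(m)
            assert 0.0 <= theta <= np.pi
            back = sbmkit.compose_zyz(phi, theta, psi)
            worst = max(worst, np.abs(back - m).max())
        assert worst < 1e-6

    def test_agrees_with_scipy_convention(self):
        rng = np.random.default_rng(18)
        for m in ScipyRotation.random(50, rng=rng).as_matrix():
            phi, theta, psi = sbmkit.euler_zyz(m)
            sp = ScipyRotation.from_matrix(m).as_euler("ZYZ")
            np.testing.assert_allclose([phi, theta, psi], sp, atol=1e-8)

    def test_pure_z_rotation_gives_gamma_only(self):
        m = sbmkit.compose_zyz(np.deg2rad(10.0), 0.0, 0.0)
        phi, theta, psi = sbmkit.euler_zyz(m)
        assert np.degrees(phi + psi) == pytest.approx(10.0, abs=1e-9)
        assert theta == pytest.approx(0.0, abs=1e-9)


class TestRotationTiltTimeseries:
    def test_reference_frame_gives_zero_angles(self, toy):
        structure, meta = toy
        body = sbmkit.select_atoms(structure, sbmkit.Selection(meta["body_selection"]))
        dom = sbmkit.select_atoms(structure, sbmkit.Selection(meta["domain_selection"]))
        out = sbmkit.rotation_tilt_timeseries(
            _frames(structure.coord), structure, body, dom,
            np.array(meta["er_axis_hint"]),
        )
        assert out[0].gamma == pytest.approx(0.0, abs=1e-9)
        assert out[0].theta == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("axis,angle,expect_gamma,expect_theta", [
        ((0.0, 1.0, 0.0), 10.0, 10.0, 0.0),   # about the E-R axis
        ((0.0, 0.0, 1.0), 8.0, 0.0, 8.0),     # orthogonal tilt
        ((1.0, 0.0, 0.0), 8.0, 0.0, 8.0),     # other orthogonal tilt
    ])
    def test_constructed_domain_rotations_recovered(
        self, toy, axis, angle, expect_gamma, expect_theta
    ):
        structure, meta = toy
        body = sbmkit.select_atoms(structure, sbmkit.Selection(meta["body_selection"]))
        dom = sbmkit.select_atoms(structure, sbmkit.Selection(meta["domain_selection"]))
        rotated = sbmkit.make_rotated_conformation(
            structure, np.array(axis), angle,
            (meta["hinge"]["chain"], meta["hinge"]["resid"]), dom,
        )
        out = sbmkit.rotation_tilt_timeseries(
            _frames(rotated.coord), structure, body, dom,
            np.array(meta["er_axis_hint"]),
        )
        assert out[0].gamma == pytest.approx(expect_gamma, abs=1e-6)
        assert out[0].theta == pytest.approx(expect_theta, abs=1e-6)

    def test_gauge_invariance_under_global_transform(self, toy):
        """gamma/theta are unchanged when frame AND references are rigidly moved."""
        structure, meta = toy
        body = sbmkit.select_atoms(structure, sbmkit.Selection(meta["body_selection"]))
        dom = sbmkit.select_atoms(structure, sbmkit.Selection(meta["domain_selection"]))
        rotated = sbmkit.make_rotated_conformation(
            structure, np.array([0.0, 0.0, 1.0]), 6.0,
            (meta["hinge"]["chain"], meta["hinge"]["resid"]), dom,
        )
        out1 = sbmkit.rotation_tilt_timeseries(
            _frames(rotated.coord), structure, body, dom, np.array([0.0, 1.0, 0.0])
        )
        g = ScipyRotation.from_euler("xyz", [15, -25, 40], degrees=True).as_matrix()
        shift = np.array([3.0, -7.0, 11.0])
        moved_ref = structure.copy()
        moved_ref.coord = structure.coord @ g.T + shift
        # the E-R axis is attached to the reference frame and moves with it
        er_moved = g @ np.array([0.0, 1.0, 0.0])
        out2 = sbmkit.rotation_tilt_timeseries(
            _frames(rotated.coord @ g.T + shift), moved_ref, body, dom, er_moved
        )
        assert out2[0].gamma == pytest.approx(out1[0].gamma, abs=1e-7)
        assert out2[0].theta == pytest.approx(out1[0].theta, abs=1e-7)

    def test_frame_mask_restricts_output(self, toy):
        structure, meta = toy
        body = sbmkit.select_atoms(structure, sbmkit.Selection(meta["body_selection"]))
        dom = sbmkit.select_atoms(structure, sbmkit.Selection(meta["domain_selection"]))
        traj = _frames(structure.coord, structure.coord, structure.coord)
        out = sbmkit.rotation_tilt_timeseries(
            traj, structure, body, dom, np.array([0.0, 1.0, 0.0]),
            frame_mask=np.array([True, False, True]),
        )
        assert [d.frame_index for d in out] == [0, 2]


class TestASD:
    def test_zero_for_reference_trajectory(self, toy):
        structure, meta = toy
        d0, d1 = meta["domain_residues"]
        dom_ca = sbmkit.select_atoms(structure, f"chain A and resid {d0}:{d1} and name CA")
        traj = _frames(structure.coord, structure.coord)
        prof = sbmkit.asd_per_residue(traj, structure, dom_ca)
        assert np.allclose(prof.table.asd, 0.0, atol=1e-12)
        assert len(prof.table) == d1 - d0 + 1

    def test_constructed_displacement_measured_exactly(self, toy):
        """One residue displaced by exactly 2 A in both frames -> a.s.d. 2.0."""
        structure, meta = toy
        d0, d1 = meta["domain_residues"]
        dom_ca = sbmkit.select_atoms(structure, f"chain A and resid {d0}:{d1} and name CA")
        target_res = d0 + 2
        moved = structure.coord.copy()
        ca = structure.atom_index("A", target_res, "CA")
        moved[ca] += np.array([0.0, 2.0, 0.0])
        # fit on the OTHER residues so the alignment stays the identity
        fit_sel = np.array([i for i in dom_ca if i != ca])
        prof = sbmkit.asd_per_residue(
            _frames(moved, moved), structure, dom_ca, fit_selection=fit_sel
        )
        assert prof.value("A", target_res) == pytest.approx(2.0, abs=1e-9)
        others = prof.table[prof.table.resid != target_res]
        assert np.allclose(others.asd, 0.0, atol=1e-9)

    def test_invariant_to_rigid_motion_of_frames(self, toy):
        structure, meta = toy
        d0, d1 = meta["domain_residues"]
        dom_ca = sbmkit.select_atoms(structure, f"chain A and resid {d0}:{d1} and name CA")
        rng = np.random.default_rng(5)
        frame = structure.coord + rng.normal(0, 0.3, structure.coord.shape)
        rot = ScipyRotation.from_euler("y", 33, degrees=True).as_matrix()
        prof1 = sbmkit.asd_per_residue(_frames(frame), structure, dom_ca)
        prof2 = sbmkit.asd_per_residue(
            _frames(frame @ rot.T + [5.0, 6.0, 7.0]), structure, dom_ca
        )
        np.testing.assert_allclose(prof1.table.asd, prof2.table.asd, atol=1e-9)

    def test_empty_trajectory_rejected(self, toy):
        structure, meta = toy
        d0, d1 = meta["domain_residues"]
        dom_ca = sbmkit.select_atoms(structure, f"chain A and resid {d0}:{d1} and name CA")
        with pytest.raises(ValueError):
            sbmkit.asd_per_residue(
                sbmkit.Trajectory(frames=np.empty((0, structure.n_atoms, 3)),
                                  config=sbmkit.SimConfig()),
                structure, dom_ca,
            )


class TestFreeEnergy:
    def test_uniform_samples_give_flat_profile(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, 20, 100_000)
        prof = sbmkit.free_energy_vs_tilt(theta, temperature=0.5, bin_width=1.0)
        f = prof.table.free_energy.to_numpy()
        n_bins = len(f)
        # multinomial fluctuation of -T ln p around a flat profile
        expected_sigma = 0.5 * np.sqrt(n_bins / len(theta))
        assert np.nanmax(f) < 3.0 * expected_sigma + 1e-9

    def test_gaussian_samples_recover_curvature(self):
        """Boltzmann inversion of half-Gaussian tilt: F'' = T / sigma^2."""
        rng = np.random.default_rng(4)
        sigma, temp = 3.0, 0.5
        theta = np.abs(rng.normal(0, sigma, 100_000))
        prof = sbmkit.free_energy_vs_tilt(theta, temperature=temp, bin_width=1.0)
        tbl = prof.table[(prof.table["count"] > 200)]
        coef = np.polyfit(tbl.theta_mid, tbl.free_energy, 2)
        assert 2.0 * coef[0] == pytest.approx(temp / sigma**2, rel=0.10)

    def test_invariant_under_sample_duplication(self):
        rng = np.random.default_rng(6)
        theta = np.abs(rng.normal(0, 4.0, 5000))
        p1 = sbmkit.free_energy_vs_tilt(theta, 0.5).table.free_energy
        p2 = sbmkit.free_energy_vs_tilt(np.r_[theta, theta], 0.5).table.free_energy
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_empty_bins_are_nan_and_min_is_zero(self):
        theta = np.r_[np.full(100, 1.5), np.full(50, 7.5)]  # gap between bins
        prof = sbmkit.free_energy_vs_tilt(theta, 0.5, bin_width=1.0)
        f = prof.table.free_energy
        counts = prof.table["count"]
        assert np.isnan(f[counts == 0]).all()
        assert np.nanmin(f) == pytest.approx(0.0)

    def test_single_bin_warns(self, caplog):
        with caplog.at_level("WARNING"):
            prof = sbmkit.free_energy_vs_tilt(np.full(10, 2.2), 0.5)
        assert (prof.table["count"] > 0).sum() == 1

    def test_temperature_must_be_positive(self):
        with pytest.raises(ValueError):
            sbmkit.free_energy_vs_tilt(np.ones(5), temperature=0.0)
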