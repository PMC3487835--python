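"""Collective variables: superposition, MSD metric, path CVs, dihedrals
and the dihedral-similarity variable."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ionpath as ip
from ionpath.cv import PathDefinition, _path_weights


def _horn_quaternion_rmsd(mobile, reference):
    """Independent superposition oracle: Horn's closed-form quaternion method."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    M = a.T @ b
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(N)[-1]
    msd = (np.sum(a**2) + np.sum(b**2) - 2.0 * lam) / a.shape[0]
    return math.sqrt(max(msd, 0.0))


def _random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.normal(scale=5.0, size=3)
    return R, t


class TestSuperpose:
    def test_identity(self, rng):
        coords = rng.normal(size=(10, 3))
        transform, rmsd = ip.superpose(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-10)

    def test_pure_translation_fits_exactly(self, rng):
        ref = rng.normal(size=(8, 3))
        mob = ref + np.array([1.0, 2.0, 2.0])
        _, rmsd = ip.superpose(mob, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(20):
            mob = rng.normal(size=(10, 3))
            ref = rng.normal(size=(10, 3))
            _, rmsd = ip.superpose(mob, ref)
            assert rmsd == pytest.approx(_horn_quaternion_rmsd(mob, ref), abs=1e-8)

    def test_rotation_is_proper(self, rng):
        mob = rng.normal(size=(6, 3))
        ref = rng.normal(size=(6, 3))
        # force a configuration where an improper fit would win
        ref[:, 2] *= -1
        transform, _ = ip.superpose(mob, ref)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            ip.superpose(line, line)

    def test_too_few_atoms_rejected(self, rng):
        pts = rng.normal(size=(2, 3))
        with pytest.raises(ValueError, match="three"):
            ip.superpose(pts, pts)


class TestMSDAfterFit:
    def test_zero_for_identical_frames(self, rng):
        coords = rng.normal(size=(12, 3))
        msd = ip.msd_after_fit(coords, coords, np.arange(6), np.arange(6, 12))
        assert msd == pytest.approx(0.0, abs=1e-14)

    def test_displaced_ions_arithmetic(self, rng):
        ref = np.vstack([rng.normal(size=(4, 3)), [[0, 0, 0], [0, 0, 5]]])
        frame = ref.copy()
        frame[4, 2] += 1.0  # 1 A displacement
        frame[5, 2] += 2.0  # 2 A displacement
        msd = ip.msd_after_fit(frame, ref, np.arange(4), np.array([4, 5]))
        assert msd == pytest.approx((1.0 + 4.0) / 2.0, abs=1e-10)

    def test_invariance_under_rigid_motion(self, rng):
        ref = rng.normal(size=(10, 3))
        frame = ref + rng.normal(scale=0.3, size=(10, 3))
        base = ip.msd_after_fit(frame, ref, np.arange(5), np.arange(5, 10))
        R, t = _random_rigid(rng)
        moved = frame @ R.T + t
        again = ip.msd_after_fit(moved, ref, np.arange(5), np.arange(5, 10))
        assert again == pytest.approx(base, abs=1e-8)

    def test_empty_measure_selection_rejected(self, rng):
        coords = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="measure"):
            ip.msd_after_fit(coords, coords, np.arange(4), np.array([], dtype=int))


class TestPathCVs:
    def test_endpoint_s_values(self, reference_path):
        assert ip.path_s(reference_path.frames[0], reference_path) <= 0.005
        assert ip.path_s(reference_path.frames[-1], reference_path) >= 0.995

    def test_unnormalized_convention_spans_one_to_p(self, reference_path):
        s_raw = ip.path_s(reference_path.frames[0], reference_path, normalized=False)
        assert s_raw == pytest.approx(1.0, abs=0.1)
        s_raw = ip.path_s(reference_path.frames[-1], reference_path, normalized=False)
        assert s_raw == pytest.approx(reference_path.n_frames, abs=0.1)

    def test_equidistant_configuration_symmetry(self, default_system, reference_path):
        """Halfway between frames i and i+1 (other weights negligible),
        s = (2i+1)/(2(P-1)) in 0-based frame indexing."""
        from ionpath.toy import scaffold_coordinates

        n_sc = scaffold_coordinates(default_system).shape[0]
        i = 7
        mid = 0.5 * (reference_path.frames[i] + reference_path.frames[i + 1])
        s = ip.path_s(mid, reference_path)
        expected = (2 * i + 1) / (2.0 * (reference_path.n_frames - 1))
        assert s == pytest.approx(expected, abs=0.01)

    def test_z_is_direct_sum_evaluation(self, reference_path, rng):
        config = reference_path.frames[4].copy()
        config[-3:, 2] += rng.normal(scale=0.4, size=3)
        D = reference_path.distances(config)
        lam = reference_path.lam
        expected = -math.log(np.sum(np.exp(-lam * D))) / lam
        assert ip.path_z(config, reference_path) == pytest.approx(expected, abs=1e-10)

    def test_z_bound_on_path_frames(self, reference_path):
        bound = math.log(reference_path.n_frames) / reference_path.lam
        for frame in reference_path.frames:
            assert abs(ip.path_z(frame, reference_path)) <= bound + 1e-9

    def test_s_nondecreasing_along_frame_sweep(self, reference_path):
        values = [ip.path_s(f, reference_path) for f in reference_path.frames]
        diffs = np.diff(values)
        assert np.all(diffs > -0.02)

    def test_rigid_motion_invariance(self, reference_path, rng):
        config = reference_path.frames[9]
        R, t = _random_rigid(rng)
        moved = config @ R.T + t
        assert ip.path_s(moved, reference_path) == pytest.approx(
            ip.path_s(config, reference_path), abs=1e-8
        )
        assert ip.path_z(moved, reference_path) == pytest.approx(
            ip.path_z(config, reference_path), abs=1e-8
        )

    def test_far_configuration_raises(self, reference_path):
        far = reference_path.frames[0] + 1e4
        far[:8] = reference_path.frames[0][:8]  # keep scaffold, move ions away
        with pytest.raises(ValueError, match="lambda|far"):
            _path_weights(far, reference_path)

    def test_single_frame_rejected(self, reference_path):
        with pytest.raises(ValueError, match="two frames"):
            PathDefinition(
                frames=[reference_path.frames[0]],
                lam=reference_path.lam,
                fit_selection=reference_path.fit_selection,
                measure_selection=reference_path.measure_selection,
            )


class TestDihedral:
    def test_planar_trans_is_180(self):
        assert ip.dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(180.0)

    def test_planar_cis_is_zero(self):
        assert ip.dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0)

    def test_constructed_plus_ninety(self):
        # p4 rotated +90 deg (right-hand rule about the p2->p3 axis, here +x,
        # taking +y into +z) from the cis position
        p1, p2, p3 = [0, 1, 0], [0, 0, 0], [1, 0, 0]
        assert ip.dihedral(p1, p2, p3, [1.0, 0.0, 1.0]) == pytest.approx(90.0)
        assert ip.dihedral(p1, p2, p3, [1.0, 0.0, -1.0]) == pytest.approx(-90.0)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            ip.dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_against_biotite(self, rng):
        import biotite.structure as struc

        for _ in range(25):
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                mine = ip.dihedral(*pts)
            except ValueError:
                continue
            theirs = math.degrees(
                float(struc.dihedral(pts[0], pts[1], pts[2], pts[3]))
            )
            delta = (mine - theirs + 180.0) % 360.0 - 180.0
            assert abs(delta) < 1e-3  # biotite computes in float32


class TestNTheta:
    def _param(self, rng, n=8):
        quads = np.arange(4 * n).reshape(n, 4)
        refs = rng.uniform(-180, 180, n)
        return quads, refs

    def test_reference_returns_n(self, filter_fixture):
        param = ip.psi_parameterization(filter_fixture)
        assert ip.n_theta(filter_fixture.coords, param) == pytest.approx(8.0, abs=1e-9)

    def test_half_turn_offset_returns_zero(self, filter_fixture):
        ref = ip.REFERENCE_ANGLES
        flipped = ip.build_filter_fixture(
            psi_val625=ref["psi_val625"] + 180.0,
            psi_gly626=ref["psi_gly626"] - 180.0,
        )
        param = ip.psi_parameterization(flipped)  # same quadruples/refs layout
        param = ip.psi_parameterization(filter_fixture)
        assert ip.n_theta(flipped.coords, param) == pytest.approx(0.0, abs=1e-9)

    def test_one_flipped_dihedral_gives_n_minus_one(self, filter_fixture):
        ref = ip.REFERENCE_ANGLES
        one_flip = ip.build_filter_fixture(
            per_subunit={"B": {"psi_val625": ref["psi_val625"] + 180.0}}
        )
        param = ip.psi_parameterization(filter_fixture)
        assert ip.n_theta(one_flip.coords, param) == pytest.approx(7.0, abs=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(offset=st.floats(-720.0, 720.0))
    def test_two_pi_periodicity(self, filter_fixture, offset):
        param = ip.psi_parameterization(filter_fixture)
        shifted = ip.DihedralParameterization(
            param.quadruples, param.reference_angles + 360.0 * round(offset / 360.0)
        )
        a = ip.n_theta(filter_fixture.coords, param)
        b = ip.n_theta(filter_fixture.coords, shifted)
        assert a == pytest.approx(b, abs=1e-9)

    def test_rigid_motion_invariance(self, filter_fixture, rng):
        param = ip.psi_parameterization(filter_fixture)
        R, t = _random_rigid(rng)
        moved = filter_fixture.coords @ R.T + t
        assert ip.n_theta(moved, param) == pytest.approx(
            ip.n_theta(filter_fixture.coords, param), abs=1e-8
        )
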