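import numpy as np
import pytest

from zernpatch.errors import DegeneratePatchError, NoInterfaceError, OrientationError
from zernpatch.patches import (
    extract_patch,
    find_interface,
    interface_patch_center,
    orient_patch,
    orient_point_set,
    rotation_to_axis,
)
from zernpatch.surface import compute_surface

from conftest import single_atom_structure


def brute_force_interface(cloud_a, cloud_b, cutoff):
    da = np.linalg.norm(
        cloud_a.positions[:, None, :] - cloud_b.positions[None, :, :], axis=2
    )
    return (
        np.flatnonzero(da.min(axis=1) < cutoff),
        np.flatnonzero(da.min(axis=0) < cutoff),
    )


def offset_cloud(structure_coord):
    return compute_surface(single_atom_structure("C", structure_coord))


class TestFindInterface:
    def test_sub_and_supra_cutoff(self):
        # inflated radius 3.1 each; centre distance sets surface separation
        for d, expect in ((9.0, True), (9.5, False)):
            ca = offset_cloud((0, 0, 0))
            cb = offset_cloud((d, 0, 0))
            sep = np.min(
                np.linalg.norm(
                    ca.positions[:, None] - cb.positions[None, :], axis=2
                )
            )
            region = find_interface(ca, cb, 3.0)
            assert (sep < 3.0) == expect  # geometry sanity
            assert (len(region.template_points) > 0) == expect
            assert (len(region.target_points) > 0) == expect

    def test_matches_brute_force_on_kissing_spheres(self):
        ca = offset_cloud((0, 0, 0))
        cb = offset_cloud((6.5, 0, 0))
        region = find_interface(ca, cb, 3.0)
        bf_a, bf_b = brute_force_interface(ca, cb, 3.0)
        assert np.array_equal(np.sort(region.template_points), bf_a)
        assert np.array_equal(np.sort(region.target_points), bf_b)

    def test_symmetry_under_swap(self, toy_clouds):
        ca, cb = toy_clouds
        r1 = find_interface(ca, cb, 3.0)
        r2 = find_interface(cb, ca, 3.0)
        assert np.array_equal(r1.template_points, r2.target_points)
        assert np.array_equal(r1.target_points, r2.template_points)

    def test_monotone_in_cutoff(self, toy_clouds):
        ca, cb = toy_clouds
        prev_t = prev_g = set()
        for cutoff in (1.5, 2.5, 3.5, 5.0):
            r = find_interface(ca, cb, cutoff)
            t, g = set(r.template_points), set(r.target_points)
            assert prev_t <= t and prev_g <= g
            prev_t, prev_g = t, g

    def test_residue_sets_follow_points(self, toy_clouds):
        ca, cb = toy_clouds
        r = find_interface(ca, cb, 3.0)
        ids = ca.residue_ids()
        assert r.template_residues == {ids[i] for i in r.template_points}


class TestPatchCenter:
    def test_singleton(self, toy_clouds):
        ca, cb = toy_clouds
        region = find_interface(ca, cb, 3.0)
        region.template_points = region.template_points[:1]
        c = interface_patch_center(region, "template")
        assert np.allclose(c, ca.positions[region.template_points[0]])

    def test_matches_brute_force_argmin(self, toy_clouds):
        ca, cb = toy_clouds
        region = find_interface(ca, cb, 3.0)
        pts = ca.positions[region.template_points]
        centroid = pts.mean(axis=0)
        best = np.argmin(np.linalg.norm(pts - centroid, axis=1))
        assert np.allclose(
            interface_patch_center(region, "template"), pts[best]
        )

    def test_empty_side_raises(self, toy_clouds):
        ca, cb = toy_clouds
        region = find_interface(ca, cb, 3.0)
        region.target_points = region.target_points[:0]
        with pytest.raises(NoInterfaceError):
            interface_patch_center(region, "target")


class TestExtractPatch:
    def test_saturation(self):
        cloud = offset_cloud((0, 0, 0))
        patch = extract_patch(cloud, cloud.positions[0], radius=100.0)
        assert len(patch) == len(cloud)

    def test_degenerate_patch_raises(self):
        cloud = offset_cloud((0, 0, 0))
        with pytest.raises(DegeneratePatchError, match=r"\d+ points"):
            extract_patch(cloud, cloud.positions[0], radius=0.05)

    def test_membership_equals_brute_force(self, toy_clouds):
        ca, _ = toy_clouds
        center = ca.positions[10]
        patch = extract_patch(ca, center, radius=5.0)
        d = np.linalg.norm(ca.positions - center, axis=1)
        assert set(patch.point_indices) == set(np.flatnonzero(d <= 5.0))

    def test_cap_fraction_on_big_sphere(self):
        st = single_atom_structure("C")
        st.atoms[0] = __import__("dataclasses").replace(st.atoms[0], radius=18.6)
        cloud = compute_surface(st, probe_radius=1.4, n_sphere_points=4096)
        R = 20.0
        radius = 8.0
        patch = extract_patch(cloud, cloud.positions[0], radius)
        cap_fraction = (radius**2) / (4.0 * R**2)  # chord -> cap area fraction
        n = len(cloud)
        assert abs(len(patch) - n * cap_fraction) <= 3.0 * np.sqrt(n)


class TestOrientation:
    def test_already_aligned_is_identity(self):
        pts = np.column_stack([np.random.default_rng(0).normal(size=(30, 2)),
                               np.zeros(30)])
        normals = np.tile([0.0, 0.0, 1.0], (30, 1))
        op = orient_point_set(pts, normals, "up", center=np.zeros(3))
        assert np.allclose(op.rotation, np.eye(3), atol=1e-12)

    def test_flip_to_down(self):
        normals = np.tile([0.0, 0.0, 1.0], (30, 1))
        pts = np.random.default_rng(1).normal(size=(30, 3))
        op = orient_point_set(pts, normals, "down")
        assert np.allclose(op.mean_normal, [0, 0, -1], atol=1e-6)
        assert np.linalg.det(op.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_motion_preserves_geometry(self, toy_clouds):
        ca, cb = toy_clouds
        region = find_interface(ca, cb, 3.0)
        patch = extract_patch(ca, interface_patch_center(region, "template"), 8.0)
        op = orient_patch(patch, "up")
        assert np.allclose(np.abs(op.mean_normal[2]), 1.0, atol=1e-6)
        # pairwise distances preserved
        orig = patch.positions
        d0 = np.linalg.norm(orig[:20, None] - orig[None, :20], axis=2)
        d1 = np.linalg.norm(op.points[:20, None] - op.points[None, :20], axis=2)
        assert np.allclose(d0, d1, atol=1e-9)
        assert np.allclose(
            np.linalg.norm(op.normals, axis=1),
            np.linalg.norm(patch.normals, axis=1),
            atol=1e-9,
        )

    def test_vanishing_mean_normal_raises(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(40, 3))
        normals = np.tile([0.0, 0.0, 1.0], (40, 1))
        normals[20:] *= -1.0  # exactly cancelling pairs
        with pytest.raises(OrientationError):
            orient_point_set(pts, normals, "up")

    @pytest.mark.parametrize("sign", ["up", "down"])
    def test_rotation_to_axis_antiparallel(self, sign):
        target = np.array([0, 0, 1.0 if sign == "up" else -1.0])
        R = rotation_to_axis(-target, sign)
        assert np.allclose(R @ (-target), target, atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
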