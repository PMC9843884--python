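import numpy as np
import pytest

from mitralflow import (
    Flow4DDataset,
    LVMaskStack,
    build_mpr_planes,
    build_mpr_stack,
    compute_centerline,
    resample_on_plane,
)
from tests.conftest import uniform_field_dataset


def cylinder_masks(axis, radius_mm=8.0, h=1.5, shape=(24, 24, 24), n_phases=2):
    """Binary cylinder along a given (unit) axis direction through the centre."""
    nz, ny, nx = shape
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    centre = (np.array([nx, ny, nz]) - 1) / 2.0 * h
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1) * h - centre
    par = pts @ axis
    perp = np.linalg.norm(pts - par[..., None] * axis, axis=-1)
    mask = perp <= radius_mm
    stack = np.repeat(mask[None], n_phases, axis=0)
    affine = np.diag([h, h, h, 1.0])
    return LVMaskStack(mask=stack, voxel_spacing=(h, h, h), affine=affine)


class TestCenterline:
    def test_axis_aligned_cylinder_recovers_axis(self):
        masks = cylinder_masks([0, 0, 1])
        cl = compute_centerline(masks, 0)
        assert np.allclose(np.abs(cl.tangents[:, 2]), 1.0, atol=1e-9)
        # all points on the central column
        assert np.allclose(cl.points[:, 0], cl.points[0, 0], atol=1e-9)
        assert np.allclose(cl.points[:, 1], cl.points[0, 1], atol=1e-9)

    def test_tilted_cylinder_tangents_recover_axis(self):
        """30°-tilted cylinder: smoothed centroid tangents track the known
        axis to ~1° on average; individual slices jitter with the
        rasterised-ellipse centroid (bounded at 2° here)."""
        axis = np.array([np.sin(np.deg2rad(30)), 0.0, np.cos(np.deg2rad(30))])
        masks = cylinder_masks(axis, radius_mm=15.0, shape=(26, 36, 80))
        cl = compute_centerline(masks, 0)
        # ignore the end points where slice clipping distorts centroids
        angles = [
            np.rad2deg(np.arccos(np.clip(np.abs(t @ axis), -1, 1)))
            for t in cl.tangents[2:-2]
        ]
        assert np.mean(angles) <= 1.0
        assert max(angles) <= 2.0

    def test_two_slices_insufficient(self):
        masks = cylinder_masks([0, 0, 1])
        m = masks.mask.copy()
        m[:, 3:, :, :] = False
        m[:, :1, :, :] = False
        thin = LVMaskStack(mask=m, voxel_spacing=masks.voxel_spacing, affine=masks.affine)
        with pytest.raises(ValueError, match="insufficient slices"):
            compute_centerline(thin, 0)

    def test_tangents_unit_norm(self, default_phantom):
        _, masks, gt = default_phantom
        cl = compute_centerline(masks, gt.ed_phase)
        assert np.allclose(np.linalg.norm(cl.tangents, axis=1), 1.0, atol=1e-9)


class TestPlaneConstruction:
    def test_straight_centerline_parallel_equispaced_planes(self):
        masks = cylinder_masks([0, 0, 1], shape=(40, 24, 24))
        cl = compute_centerline(masks, 0)
        planes = build_mpr_planes(cl, n_slices=20, spacing_mm=2.5)
        assert len(planes) == 20
        normals = np.array([p.normal for p in planes])
        assert np.allclose(normals, normals[0], atol=1e-9)
        origins = np.array([p.origin for p in planes])
        gaps = np.linalg.norm(np.diff(origins, axis=0), axis=1)
        assert np.allclose(gaps, 2.5, atol=1e-9)

    def test_frames_orthonormal_right_handed(self, default_phantom):
        _, masks, gt = default_phantom
        cl = compute_centerline(masks, gt.ed_phase)
        for p in build_mpr_planes(cl, n_slices=15, spacing_mm=2.5):
            u, v, n = p.in_plane_u, p.in_plane_v, p.normal
            for a, b in ((u, v), (u, n), (v, n)):
                assert abs(a @ b) <= 1e-9
            for a in (u, v, n):
                assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(np.cross(u, v), n, atol=1e-9)

    def test_truncation_when_span_exceeds_centerline(self):
        masks = cylinder_masks([0, 0, 1], shape=(24, 24, 24))
        cl = compute_centerline(masks, 0)
        planes = build_mpr_planes(cl, n_slices=60, spacing_mm=2.5)
        assert len(planes) < 60

    def test_curved_arc_origins_lie_on_arc(self):
        """Quarter-circle centreline: plane origins stay within half a pixel
        of the analytic arc."""
        r = 40.0
        theta = np.linspace(0, np.pi / 2, 200)
        pts = np.stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(theta)], axis=1)
        tan = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=1)
        from mitralflow import Centerline

        cl = Centerline(points=pts, tangents=tan)
        pixel = 1.5
        planes = build_mpr_planes(cl, n_slices=20, spacing_mm=2.5, pixel_mm=pixel)
        for p in planes:
            assert abs(np.linalg.norm(p.origin[:2]) - r) <= pixel / 2
            assert abs(p.origin[2]) <= 1e-9


class TestResampling:
    def test_uniform_field_norm_preserved_any_plane(self, default_phantom):
        ds, masks = uniform_field_dataset(v=(0.0, 0.0, 0.9))
        cl = compute_centerline(masks, 0)
        planes = build_mpr_planes(cl, n_slices=5, spacing_mm=2.0, extent_mm=12.0)
        for plane in planes:
            vel, _, valid = resample_on_plane(ds, masks, plane, 0)
            norms = np.linalg.norm(vel[valid], axis=-1)
            assert np.allclose(norms, 0.9, atol=1e-12)

    def test_uniform_field_frame_decomposition(self):
        ds, masks = uniform_field_dataset(v=(0.0, 0.0, 0.9))
        cl = compute_centerline(masks, 0)  # axis along z
        plane = build_mpr_planes(cl, n_slices=3, spacing_mm=2.0, extent_mm=12.0)[1]
        assert np.allclose(np.abs(plane.normal), [0, 0, 1], atol=1e-9)
        vel, _, valid = resample_on_plane(ds, masks, plane, 0)
        assert np.allclose(np.abs(vel[valid][:, 2]), 0.9, atol=1e-12)
        assert np.allclose(vel[valid][:, :2], 0.0, atol=1e-12)

    def test_linear_field_reproduced_exactly(self):
        """Trilinear interpolation is exact on a linear field v_z = x/100."""
        ds, masks = uniform_field_dataset(v=(0.0, 0.0, 0.0), shape=(16, 16, 16))
        nz, ny, nx = 16, 16, 16
        xs = np.arange(nx) * 1.5
        ds.velocity[..., 2] = (xs / 100.0)[None, None, None, :]
        # tilted plane so samples interpolate across all axes
        from mitralflow import MPRPlane

        n = np.array([0.0, np.sin(0.4), np.cos(0.4)])
        u = np.array([1.0, 0.0, 0.0])
        v = np.cross(n, u)
        plane = MPRPlane(
            origin=np.array([11.0, 11.0, 11.0]),
            normal=n,
            in_plane_u=u,
            in_plane_v=v,
            extent_mm=10.0,
            pixel_mm=1.1,
        )
        vel, _, valid = resample_on_plane(ds, masks, plane, 0)
        pts = plane.sample_points()
        expected_vz = pts[..., 0] / 100.0
        scanner_vel = vel @ plane.rotation()  # rotate back
        assert np.abs(scanner_vel[valid][:, 2] - expected_vz[valid]).max() <= 1e-9
        assert np.abs(scanner_vel[valid][:, :2]).max() <= 1e-9

    def test_vector_norm_frame_independent(self, default_phantom):
        ds, masks, gt = default_phantom
        cl = compute_centerline(masks, gt.ed_phase)
        planes = build_mpr_planes(cl, n_slices=10, spacing_mm=2.5)
        pts = planes[4].sample_points()
        from mitralflow.geometry_mpr import _sample_velocity

        raw, valid = _sample_velocity(ds, pts, gt.true_phase_e)
        vel, _, valid2 = resample_on_plane(ds, masks, planes[4], gt.true_phase_e)
        assert (valid == valid2).all()
        assert np.abs(
            np.linalg.norm(vel[valid], axis=-1) - np.linalg.norm(raw[valid], axis=-1)
        ).max() <= 1e-9


class TestRotationEquivariance:
    def test_masked_speeds_invariant_under_rigid_rotation(self):
        """Rotating field+mask rigidly leaves masked speed percentiles
        unchanged within interpolation tolerance (1% of VENC)."""
        from scipy import ndimage

        from mitralflow import PhantomConfig, generate_phantom

        cfg = PhantomConfig(voxel_mm=1.5, lv_radius_ed=16.0, lv_length=30.0, jet_radius=9.0)
        ds, masks, gt = generate_phantom(cfg)
        phase = gt.true_phase_e

        angle = np.deg2rad(30.0)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])  # about z, (x,y,z)

        nz, ny, nx = ds.grid_shape
        centre = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])  # voxel (x,y,z)
        zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
        tgt = np.stack([xx, yy, zz], axis=-1).astype(float) - centre
        src = tgt @ rot + centre  # rotate sample coordinates about the grid centre
        coords = np.moveaxis(src[..., ::-1], -1, 0)  # (z,y,x) order

        vel_rot = np.zeros_like(ds.velocity[phase])
        for cc in range(3):
            vals = ndimage.map_coordinates(
                ds.velocity[phase, :, :, :, cc], coords, order=1, mode="nearest"
            )
            vel_rot[..., cc] = vals
        vel_rot = vel_rot @ rot  # rotate the sampled vectors into the new frame
        mask_rot = (
            ndimage.map_coordinates(
                masks.mask[phase].astype(float), coords, order=0, mode="constant", cval=0.0
            )
            > 0.5
        )

        sp0 = np.linalg.norm(ds.velocity[phase][masks.mask[phase]], axis=-1)
        sp1 = np.linalg.norm(vel_rot[mask_rot], axis=-1)
        for q in (50, 90, 100):
            assert abs(np.percentile(sp0, q) - np.percentile(sp1, q)) <= 0.01 * ds.venc
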