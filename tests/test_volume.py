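import numpy as np
import pytest

from erprep.volume import (FrameInterpolator, ScalpGrid, ScalpTimeVolume, SmoothingSpec,
                           build_volume, interpolate_frame, project_electrodes,
                           smooth_volume, smooth_volumes, volume_matrix)


class TestProjection:
    def test_vertex_maps_to_origin(self, montage, coords):
        assert np.allclose(coords[montage.index("Cz")], [0.0, 0.0], atol=1e-12)

    def test_mirror_symmetry(self, montage, coords):
        for left, right in [("O1", "O2"), ("F7", "F8"), ("T7", "T8")]:
            xl, yl = coords[montage.index(left)]
            xr, yr = coords[montage.index(right)]
            assert np.isclose(xl, -xr, atol=1e-9) and np.isclose(yl, yr, atol=1e-9)

    def test_all_electrodes_inside_grid(self, coords, grid):
        assert np.abs(coords).max() < grid.half_extent_mm

    def test_arc_distance_preserved_up_to_scale(self, montage, grid, coords):
        # radial coordinate proportional to the polar angle from the vertex
        theta = np.arccos(np.clip(montage.positions[:, 2], -1, 1))
        r = np.linalg.norm(coords, axis=1)
        nz = theta > 1e-9
        scale = r[nz] / theta[nz]
        assert scale.std() / scale.mean() < 1e-9


class TestInterpolation:
    def test_constant_field_reproduced(self, interp):
        img = interp(np.full(61, 5.0))
        assert np.nanmax(np.abs(img - 5.0)) < 1e-9
        assert np.isnan(img[~interp.mask]).all()

    def test_linear_precision(self, interp, coords, grid):
        a, b, c = 0.4, -1.1, 3.0
        img = interp(a * coords[:, 0] + b * coords[:, 1] + c)
        cx = grid.pixel_centers_mm
        px, py = np.meshgrid(cx, cx, indexing="ij")
        expected = a * px + b * py + c
        assert np.nanmax(np.abs(img - expected)) < 1e-9

    def test_single_electrode_peak_location(self, interp, coords, grid, montage):
        # brute force: the in-mask maximum must be at the pixel nearest the electrode
        values = np.zeros(61)
        ch = montage.index("CP1")
        values[ch] = 1.0
        img = interp(values)
        ix, iy = np.unravel_index(np.nanargmax(img), img.shape)
        cx = grid.pixel_centers_mm
        px, py = np.meshgrid(cx, cx, indexing="ij")
        d2 = (px - coords[ch, 0]) ** 2 + (py - coords[ch, 1]) ** 2
        d2[~interp.mask] = np.inf
        jx, jy = np.unravel_index(np.argmin(d2), d2.shape)
        assert (ix, iy) == (jx, jy)

    def test_collinear_electrodes_rejected(self, grid):
        line = np.column_stack([np.linspace(-10, 10, 5), np.zeros(5)])
        with pytest.raises(ValueError, match="non-collinear"):
            FrameInterpolator(line, grid)

    def test_one_shot_matches_class(self, coords, grid, rng):
        v = rng.normal(size=61)
        a = interpolate_frame(v, coords, grid)
        b = FrameInterpolator(coords, grid)(v)
        assert np.array_equal(np.isnan(a), np.isnan(b))
        assert np.allclose(a[~np.isnan(a)], b[~np.isnan(b)])


class TestBuildVolume:
    def test_frame_counts(self, interp, rng):
        times = -100.0 + 2.0 * np.arange(326)  # 500 Hz epoch
        erp = rng.normal(size=(61, 326))
        assert build_volume(erp, times, interp).values.shape[2] == 226
        assert build_volume(erp, times, interp, (50.0, 52.0)).values.shape[2] == 2

    def test_frame_equals_single_interpolation(self, interp, rng):
        times = -100.0 + 2.0 * np.arange(326)
        erp = rng.normal(size=(61, 326))
        vol = build_volume(erp, times, interp)
        i100 = np.argmin(np.abs(vol.times_ms - 100.0))
        direct = interp(erp[:, np.argmin(np.abs(times - 100.0))])
        assert np.allclose(vol.values[:, :, i100][interp.mask], direct[interp.mask])

    def test_window_outside_epoch_rejected(self, interp):
        times = -100.0 + 2.0 * np.arange(326)
        with pytest.raises(ValueError, match="outside epoch"):
            build_volume(np.zeros((61, 326)), times, interp, (50.0, 900.0))


def _volume(interp, values, dt=2.0):
    times = 50.0 + dt * np.arange(values.shape[2])
    return ScalpTimeVolume(values=values, times_ms=times, grid=interp.grid)


class TestSmoothing:
    def test_constant_volume_unchanged(self, interp):
        v = np.full((32, 32, 40), np.nan)
        v[interp.mask, :] = 3.25
        out = smooth_volume(_volume(interp, v))
        assert np.nanmax(np.abs(out.values - 3.25)) < 1e-9

    def test_impulse_response_fwhm(self, interp):
        v = np.full((32, 32, 61), np.nan)
        v[interp.mask, :] = 0.0
        v[16, 16, 30] = 1.0
        out = smooth_volume(_volume(interp, v), SmoothingSpec((16.0, 16.0, 16.0)))

        def fwhm(profile, spacing):
            p = profile / np.nanmax(profile)
            above = np.where(p >= 0.5)[0]
            i0, i1 = above[0], above[-1]
            left = i0 - 1 + (0.5 - p[i0 - 1]) / (p[i0] - p[i0 - 1])
            right = i1 + (0.5 - p[i1]) / (p[i1 + 1] - p[i1])
            return (right - left) * spacing

        assert abs(fwhm(out.values[:, 16, 30], 4.25) - 16.0) < 0.8  # within 5 %
        assert abs(fwhm(out.values[16, :, 30], 4.25) - 16.0) < 0.8
        assert abs(fwhm(out.values[16, 16, :], 2.0) - 16.0) < 0.8

    def test_convexity_bounds_and_mask_invariance(self, interp, rng):
        v = np.full((32, 32, 20), np.nan)
        vals = rng.normal(size=(int(interp.mask.sum()), 20))
        v[interp.mask, :] = vals
        out = smooth_volume(_volume(interp, v))
        assert np.nanmin(out.values) >= vals.min() - 1e-12
        assert np.nanmax(out.values) <= vals.max() + 1e-12
        assert np.array_equal(np.isnan(out.values), np.isnan(v))

    def test_linearity(self, interp, rng):
        v1 = np.full((32, 32, 15), np.nan)
        v2 = np.full((32, 32, 15), np.nan)
        v1[interp.mask, :] = rng.normal(size=(int(interp.mask.sum()), 15))
        v2[interp.mask, :] = rng.normal(size=(int(interp.mask.sum()), 15))
        a, b = 2.0, -0.7
        lhs = smooth_volume(_volume(interp, a * v1 + b * v2)).values
        rhs = (
            a * smooth_volume(_volume(interp, v1)).values
            + b * smooth_volume(_volume(interp, v2)).values
        )
        mask = ~np.isnan(lhs)
        assert np.allclose(lhs[mask], rhs[mask], atol=1e-8)

    def test_batched_smoothing_matches_per_volume(self, interp, rng):
        stack = np.full((3, 32, 32, 12), np.nan)
        stack[:, interp.mask, :] = rng.normal(size=(3, int(interp.mask.sum()), 12))
        batched = smooth_volumes(stack, interp.mask, interp.grid, 2.0)
        for k in range(3):
            single = smooth_volume(_volume(interp, stack[k])).values
            m = ~np.isnan(single)
            assert np.allclose(batched[k][m], single[m], atol=1e-12)


class TestRoundTrips:
    def test_save_load_bit_identical(self, interp, rng, tmp_path):
        v = np.full((32, 32, 8), np.nan)
        v[interp.mask, :] = rng.normal(size=(int(interp.mask.sum()), 8))
        vol = _volume(interp, v)
        vol.provenance = {"subject": 3, "block": 1}
        vol.save(tmp_path / "vol.npz")
        back = ScalpTimeVolume.load(tmp_path / "vol.npz")
        assert np.array_equal(vol.values, back.values, equal_nan=True)
        assert np.array_equal(vol.times_ms, back.times_ms)
        assert back.provenance == vol.provenance and back.grid == vol.grid

    def test_nifti_export_header(self, interp):
        v = np.full((32, 32, 5), np.nan)
        v[interp.mask, :] = 1.0
        img = _volume(interp, v).to_nifti()
        assert img.shape == (32, 32, 5)
        assert np.allclose(img.header.get_zooms(), (4.25, 4.25, 2.0))

    def test_volume_matrix_masks_must_match(self, interp, rng):
        v = np.full((32, 32, 4), np.nan)
        v[interp.mask, :] = rng.normal(size=(int(interp.mask.sum()), 4))
        Y, mask3d = volume_matrix([_volume(interp, v), _volume(interp, v.copy())])
        assert Y.shape == (2, int(interp.mask.sum()) * 4)
        assert not np.isnan(Y).any()
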