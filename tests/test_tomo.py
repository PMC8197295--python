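"""Fourier-slice tomographic reconstruction from lenslet projections."""

import math

import numpy as np
import pytest

from spotfts import (
    EmissionSpectrum,
    FourierVolume,
    PSFModel,
    ProjectionSet,
    Tomogram,
    ViewingAngle,
    extract_lenslet_subimages,
    fourier_slice_insert,
    invert_fourier_volume,
    make_point_bead,
    make_shell_bead,
    measure_fwhm_3d,
    positivity_refine,
    project,
    reconstruct,
    richardson_lucy,
)
from spotfts.optics import LensletGrid, viewing_angles
from spotfts.tomo import _fourier_shear_project

SPECTRUM = EmissionSpectrum.monochromatic(530.0)
VOX = 0.27


def rms_width(volume, axis):
    idx = np.arange(volume.shape[axis], dtype=float)
    axes = tuple(i for i in range(3) if i != axis)
    prof = np.clip(volume, 0, None).sum(axis=axes)
    mu = (prof * idx).sum() / prof.sum()
    return math.sqrt((prof * (idx - mu) ** 2).sum() / prof.sum())


class TestExtractSubimages:
    def test_round_trips_a_tiled_frame(self, paper_config, paper_grid, rng):
        side = 8
        frame = rng.random((6 * side, 6 * side))
        ps = extract_lenslet_subimages(frame, paper_grid, paper_config, subimage_px=side)
        m_vals = sorted({mn[0] for mn in paper_grid.indices})
        n_vals = sorted({mn[1] for mn in paper_grid.indices})
        for img, (m, n) in zip(ps.subimages, ps.indices):
            r, c = n_vals.index(n) * side, m_vals.index(m) * side
            assert np.array_equal(img, frame[r : r + side, c : c + side])

    def test_zero_frame_gives_zero_subimages(self, paper_config, paper_grid):
        ps = extract_lenslet_subimages(
            np.zeros((60, 60)), paper_grid, paper_config, subimage_px=10
        )
        assert len(ps) == 16 and not ps.subimages.any()

    def test_defocused_point_displaced_proportional_to_tangent(
        self, paper_config, paper_grid, paper_angles
    ):
        # a point above the focal plane appears displaced by -(z-zc)*tan(angle)
        phantom = make_point_bead((64, 64, 64), VOX, SPECTRUM, diameter_um=0.6,
                                  center_um=(40 * VOX, 31.5 * VOX, 31.5 * VOX))
        dz = 40 - 32  # voxels above the axial center
        for ang in paper_angles:
            img = project(phantom, ang, None)
            row, col = np.unravel_index(np.argmax(img), img.shape)
            assert col - 31.5 == pytest.approx(-dz * math.tan(ang.alpha_rad), abs=1.0)
            assert row - 31.5 == pytest.approx(-dz * math.tan(ang.beta_rad), abs=1.0)

    def test_frame_too_small_raises(self, paper_config, paper_grid):
        with pytest.raises(ValueError, match="too small"):
            extract_lenslet_subimages(
                np.zeros((50, 50)), paper_grid, paper_config, subimage_px=10
            )

    def test_origin_outside_frame_raises(self, paper_config, paper_grid):
        with pytest.raises(ValueError, match="origin"):
            extract_lenslet_subimages(
                np.zeros((60, 60)), paper_grid, paper_config,
                subimage_px=10, origin=(70, 0),
            )


class TestRichardsonLucy:
    def test_delta_psf_is_identity(self, rng):
        image = rng.random((32, 32))
        delta = np.zeros((5, 5))
        delta[2, 2] = 1.0
        out = richardson_lucy(image, delta, iterations=7)
        assert np.allclose(out, image, atol=1e-9)

    def test_flux_conserved_for_interior_object(self):
        image = np.zeros((64, 64))
        image[28:36, 28:36] = 5.0
        psf = PSFModel(1.23)
        out = richardson_lucy(image, psf, iterations=15, pitch_um=VOX)
        assert out.sum() == pytest.approx(image.sum(), rel=1e-3)

    def test_blurred_point_sharpens_by_at_least_25_percent(self):
        psf = PSFModel(1.23)
        point = np.zeros((64, 64))
        point[32, 32] = 1.0
        blurred = psf.blur(point, VOX)

        def fwhm(img):
            prof = img[32]
            half = prof.max() / 2
            idx = np.nonzero(prof >= half)[0]
            return (idx[-1] - idx[0] + 1) * VOX

        sharp = richardson_lucy(np.clip(blurred, 0, None), psf, 20, VOX)
        assert fwhm(sharp) <= 0.75 * fwhm(blurred)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError, match="non-negative"):
            richardson_lucy(np.array([[-1.0, 2.0]]), PSFModel(1.0), 1)


class TestFourierSliceInsert:
    def test_normal_incidence_fills_kz_zero_plane_exactly(self, rng):
        n = 16
        proj = rng.random((n, n))
        vol = FourierVolume.empty(n, VOX)
        fourier_slice_insert(vol, proj, ViewingAngle(0.0, 0.0))
        assert np.allclose(vol.values[0], np.fft.fft2(proj))
        assert np.allclose(vol.weights[0], 1.0)
        assert not vol.weights[1:].any()

    def test_central_slice_consistency_against_direct_dft(self, rng):
        # forward shear projection then 2D FT equals the tilted central slice
        # of the 3D FT (z-centered), away from the Nyquist edge rows/cols
        n = 16
        vol = np.zeros((n, n, n))
        vol[5:11, 5:11, 5:11] = rng.random((6, 6, 6))
        angle = ViewingAngle(math.atan(0.4), math.atan(-0.25))
        proj_ft = np.fft.fft2(_fourier_shear_project(vol, angle))

        ta, tb = angle.tangents
        k = np.fft.fftfreq(n) * n
        kxg, kyg = np.meshgrid(k, k)
        kzg = -(kxg * ta + kyg * tb)
        zz, yy, xx = np.indices(vol.shape)
        zc = n // 2
        oracle = np.empty((n, n), dtype=complex)
        for r in range(n):
            for c in range(n):
                phase = np.exp(
                    -2j * np.pi
                    * (kxg[r, c] * xx + kyg[r, c] * yy + kzg[r, c] * (zz - zc))
                    / n
                )
                oracle[r, c] = np.sum(vol * phase)
        interior = (np.abs(kxg) < n // 2) & (np.abs(kyg) < n // 2)
        err = np.abs(proj_ft - oracle)[interior].max() / np.abs(oracle).max()
        assert err < 0.02

    def test_double_insertion_doubles_values_and_weights(self, rng):
        n = 16
        proj = rng.random((n, n))
        angle = ViewingAngle(0.3, -0.2)
        v1 = FourierVolume.empty(n, VOX)
        fourier_slice_insert(v1, proj, angle)
        v2 = FourierVolume.empty(n, VOX)
        fourier_slice_insert(v2, proj, angle)
        fourier_slice_insert(v2, proj, angle)
        assert np.allclose(v2.values, 2 * v1.values)
        assert np.allclose(v2.weights, 2 * v1.weights)

    def test_shape_mismatch_raises(self):
        vol = FourierVolume.empty(16, VOX)
        with pytest.raises(ValueError, match="shape"):
            fourier_slice_insert(vol, np.zeros((8, 8)), ViewingAngle(0.0, 0.0))


class TestInvertFourierVolume:
    def test_single_normal_view_is_constant_along_z(self):
        n = 32
        phantom = make_point_bead((n, n, n), VOX, SPECTRUM, diameter_um=1.0)
        proj = project(phantom, ViewingAngle(0.0, 0.0), None)
        vol = FourierVolume.empty(n, VOX)
        fourier_slice_insert(vol, proj, ViewingAngle(0.0, 0.0))
        tomo = invert_fourier_volume(vol)
        column = tomo.data[:, 16, 16]
        assert np.ptp(column) < 1e-9 * abs(column).max()

    def test_multi_view_point_localizes_to_true_position(
        self, wide_grid_config
    ):
        grid = LensletGrid.build(wide_grid_config)
        angles = viewing_angles(grid, wide_grid_config)
        assert len(angles) == 36
        n = 64
        phantom = make_point_bead((n, n, n), VOX, SPECTRUM)
        vol = FourierVolume.empty(n, VOX)
        for ang in angles:
            fourier_slice_insert(vol, project(phantom, ang, None), ang)
        tomo = invert_fourier_volume(vol)
        peak = np.unravel_index(np.argmax(tomo.data), tomo.data.shape)
        assert all(abs(p - 31.5) <= 1.0 for p in peak)

    def test_axial_width_exceeds_transverse_for_unrefined_point(
        self, wide_grid_config, paper_psf
    ):
        # missing-cone anisotropy of the raw weight-normalized inversion
        grid = LensletGrid.build(wide_grid_config)
        angles = viewing_angles(grid, wide_grid_config)
        phantom = make_point_bead((64, 64, 64), VOX, SPECTRUM)
        imgs = np.stack([project(phantom, a, paper_psf) for a in angles])
        ps = ProjectionSet(imgs, angles, grid.valid_indices(), VOX)
        tomo = reconstruct(ps, None, rl_iterations=0, positivity_iterations=0)
        assert measure_fwhm_3d(tomo, "z") > measure_fwhm_3d(tomo, "x")

    def test_empty_volume_raises(self):
        with pytest.raises(ValueError, match="no Fourier planes"):
            invert_fourier_volume(FourierVolume.empty(8, VOX))


class TestPositivityRefine:
    def test_zero_iterations_clips_negatives(self):
        vol = FourierVolume.empty(8, VOX)
        vol.weights[:] = 1.0
        data = np.linspace(-1, 1, 512).reshape(8, 8, 8)
        out = positivity_refine(Tomogram(data, VOX), vol, iterations=0)
        assert np.array_equal(out.data, np.clip(data, 0, None))

    def test_fully_measured_nonnegative_volume_is_fixed_point(self, rng):
        n = 8
        x = rng.random((n, n, n))
        vol = FourierVolume.empty(n, VOX)
        vol.values = np.fft.fftn(np.roll(x, -(n // 2), axis=0))
        vol.weights[:] = 1.0
        tomo = invert_fourier_volume(vol)
        assert np.allclose(tomo.data, x, atol=1e-10)
        refined = positivity_refine(tomo, vol, iterations=5)
        assert np.allclose(refined.data, x, atol=1e-9)

    def test_shell_axial_elongation_strictly_decreases(self, narrow_grid_config):
        # with viewing angles limited to ~30 deg the missing cone smears the
        # shell axially; the positivity constraint recovers part of the cone
        grid = LensletGrid.build(narrow_grid_config)
        angles = viewing_angles(grid, narrow_grid_config)
        psf = PSFModel(1.2354)
        shell = make_shell_bead((64, 64, 64), VOX, SPECTRUM)
        imgs = np.stack([project(shell, a, psf) for a in angles])
        ps = ProjectionSet(imgs, angles, grid.valid_indices(), VOX)
        plain = reconstruct(ps, psf, rl_iterations=10, positivity_iterations=0)
        refined = reconstruct(ps, psf, rl_iterations=10, positivity_iterations=50)

        def elongation(t):
            return rms_width(t.data, 0) / rms_width(t.data, 2)

        assert elongation(plain) > 1.05  # visible axial smear without the prior
        assert elongation(refined) < elongation(plain)


class TestReconstructPipeline:
    def test_scales_linearly_with_input(self, paper_config, paper_grid, paper_angles, paper_psf):
        phantom = make_point_bead((32, 32, 32), VOX, SPECTRUM,
                                  center_um=(15.5 * VOX,) * 3)
        imgs = np.stack([project(phantom, a, paper_psf) for a in paper_angles])
        ps1 = ProjectionSet(imgs, paper_angles, paper_grid.valid_indices(), VOX)
        ps3 = ProjectionSet(3 * imgs, paper_angles, paper_grid.valid_indices(), VOX)
        t1 = reconstruct(ps1, None, rl_iterations=0, positivity_iterations=0)
        t3 = reconstruct(ps3, None, rl_iterations=0, positivity_iterations=0)
        assert np.allclose(t3.data, 3 * t1.data, atol=1e-9 * t1.data.max())

    def test_index_flip_with_mirrored_images_mirrors_tomogram(
        self, paper_config, paper_grid, paper_angles, paper_psf
    ):
        phantom = make_point_bead(
            (32, 32, 32), VOX, SPECTRUM, diameter_um=1.0,
            center_um=(20 * VOX, 15.5 * VOX, 12 * VOX),
        )
        imgs = [project(phantom, a, paper_psf) for a in paper_angles]
        ps = ProjectionSet(np.stack(imgs), paper_angles, paper_grid.valid_indices(), VOX)
        tomo = reconstruct(ps, None, rl_iterations=0, positivity_iterations=0)

        # (m,n) -> (-m,-n): angles negate, images mirror in both axes
        flipped_angles = [ViewingAngle(-a.alpha_rad, -a.beta_rad) for a in paper_angles]
        flipped_imgs = [img[::-1, ::-1] for img in imgs]
        ps_f = ProjectionSet(
            np.stack(flipped_imgs), flipped_angles,
            [(-m, -n) for m, n in paper_grid.valid_indices()], VOX,
        )
        tomo_f = reconstruct(ps_f, None, rl_iterations=0, positivity_iterations=0)
        # mirroring x and y (z untouched) maps the reconstruction onto the
        # flipped-label one
        mirrored = tomo.data[:, ::-1, ::-1]
        assert np.allclose(tomo_f.data, mirrored, atol=1e-8 * tomo.data.max())

    def test_point_fwhm_between_object_size_and_psf_width(
        self, wide_grid_config, paper_psf
    ):
        # the reconstruction cannot be sharper than the bead itself nor much
        # broader than the lenslet diffraction-limited blur
        grid = LensletGrid.build(wide_grid_config)
        angles = viewing_angles(grid, wide_grid_config)
        phantom = make_point_bead((64, 64, 64), VOX, SPECTRUM)
        imgs = np.stack([project(phantom, a, paper_psf) for a in angles])
        ps = ProjectionSet(imgs, angles, grid.valid_indices(), VOX)
        tomo = reconstruct(ps, paper_psf)
        fwhm = measure_fwhm_3d(tomo, "x")
        assert 0.5 <= fwhm <= 1.2 * paper_psf.fwhm_um

    def test_requires_two_distinct_angles(self, paper_psf):
        ps = ProjectionSet(
            np.zeros((2, 16, 16)),
            [ViewingAngle(0.1, 0.0), ViewingAngle(0.1, 0.0)],
            [(0.5, 0.5), (1.5, 0.5)],
            VOX,
        )
        with pytest.raises(ValueError, match="distinct"):
            reconstruct(ps, paper_psf)

    def test_mismatched_subimage_shapes_rejected(self):
        with pytest.raises(ValueError):
            ProjectionSet(
                [np.zeros((8, 8)), np.zeros((9, 9))],
                [ViewingAngle(0.0, 0.0), ViewingAngle(0.1, 0.0)],
                [(0.5, 0.5), (1.5, 0.5)],
                VOX,
            )


class TestMeasureFwhm:
    def test_ideal_gaussian_blob(self):
        n = 48
        zz, yy, xx = np.indices((n, n, n), dtype=float)
        blob = np.exp(-((zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2) / 2.0)
        tomo = Tomogram(blob, voxel_um=1.0)
        for axis in "xyz":
            assert measure_fwhm_3d(tomo, axis) == pytest.approx(2.3548, rel=1e-3)

    def test_invariant_under_intensity_scaling(self):
        n = 32
        zz, yy, xx = np.indices((n, n, n), dtype=float)
        blob = np.exp(-((zz - 16) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2) / 8.0)
        a = measure_fwhm_3d(Tomogram(blob, 0.5), "x")
        b = measure_fwhm_3d(Tomogram(40 * blob, 0.5), "x")
        assert a == pytest.approx(b, rel=1e-9)

    def test_unknown_axis_raises(self):
        with pytest.raises(ValueError, match="axis"):
            measure_fwhm_3d(Tomogram(np.ones((4, 4, 4)), 1.0), "w")
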