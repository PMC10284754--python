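"""Synthetic phantom generation: rasterization, variants, series."""

import math

import numpy as np
import pytest

from luquant._grid import distance_to_point
from luquant.phantom import (
    NEMA_SPHERE_DIAMETERS_MM,
    PhantomSpec,
    ReconVariant,
    SphereSpec,
    VoxelImage,
    apply_recon_variant,
    default_phantom,
    emulate_edge_preserving,
    make_phantom_series,
    rasterize_phantom,
    sphere_volume_ml,
)

VOX = 4.8
GRID = (64, 64, 40)
CENTER = tuple((np.asarray(GRID, float) - 1) / 2.0 * VOX)


def _single(diameter=37.0, conc=514.0, bkg=0.0):
    return PhantomSpec(
        spheres=(SphereSpec(center=CENTER, diameter=diameter, true_concentration=conc),),
        background_concentration=bkg,
    )


class TestRasterize:
    def test_single_sphere_activity_matches_analytic_volume(self):
        """ø37 at 514 kBq/ml: total activity within 1% of 514 * pi d^3/6."""
        img = rasterize_phantom(_single(), VOX, GRID, supersampling=8)
        expected = 514.0 * sphere_volume_ml(37.0)  # ~13632 kBq
        assert expected == pytest.approx(13631.7, rel=1e-3)
        assert img.total_activity_kbq() == pytest.approx(expected, rel=0.01)

    def test_empty_sphere_list_gives_uniform_background(self):
        img = rasterize_phantom(
            PhantomSpec(spheres=(), background_concentration=2.0), VOX, GRID
        )
        assert np.all(img.values == 2.0)

    @pytest.mark.parametrize("diameter", [10.0, 17.0, 37.0])
    def test_activity_error_shrinks_with_supersampling(self, diameter):
        """Activity error vs the analytic volume drops as subdivision refines.

        Midpoint sampling makes the error oscillate between adjacent
        doublings, so convergence is asserted over 4x supersampling steps.
        """
        spec = _single(diameter=diameter)
        analytic = 514.0 * sphere_volume_ml(diameter)
        errs = [
            abs(
                rasterize_phantom(spec, VOX, GRID, supersampling=s).total_activity_kbq()
                - analytic
            )
            for s in (1, 4, 16)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_sphere_outside_grid_is_an_error(self):
        spec = PhantomSpec(
            spheres=(SphereSpec(center=(0, 0, 0), diameter=37.0, true_concentration=1.0),)
        )
        with pytest.raises(ValueError, match="outside the grid"):
            rasterize_phantom(spec, VOX, GRID)

    def test_background_added_under_spheres(self):
        img = rasterize_phantom(_single(bkg=54.1), VOX, GRID, supersampling=2)
        cidx = img.nearest_index(CENTER)
        assert img.values[cidx] == pytest.approx(514.0)
        assert img.values[0, 0, 0] == pytest.approx(54.1)


class TestReconVariants:
    def test_uniform_field_is_fixed_point_without_noise(self):
        img = VoxelImage(np.full(GRID, 3.0), VOX)
        for variant in (
            ReconVariant("sharp", psf_fwhm=12.0),
            ReconVariant("smoothed", psf_fwhm=12.0, post_filter_fwhm=10.0),
        ):
            # interior only: 'constant' boundary handling truncates edges
            out = apply_recon_variant(img, variant).values[8:-8, 8:-8, 8:-8]
            np.testing.assert_allclose(out, 3.0, rtol=1e-6)

    def test_point_source_becomes_gaussian_of_requested_fwhm(self):
        vals = np.zeros(GRID)
        vals[32, 32, 20] = 1.0
        img = VoxelImage(vals, VOX)
        out = apply_recon_variant(img, ReconVariant("sharp", psf_fwhm=12.0))
        sigma = 12.0 / (2 * math.sqrt(2 * math.log(2)))
        d = distance_to_point(GRID, VOX, np.zeros(3), np.array([32, 32, 20]) * VOX)
        expected = np.exp(-(d**2) / (2 * sigma**2))
        expected /= expected.sum()
        np.testing.assert_allclose(out.values, expected, atol=3e-5)

    def test_ringing_depresses_large_sphere_center(self):
        """The LoG edge response creates the central 'valley' of the sharp recon."""
        truth = rasterize_phantom(_single(), VOX, GRID, supersampling=4)
        img = apply_recon_variant(
            truth, ReconVariant("sharp", psf_fwhm=12.0, ringing_amplitude=0.5)
        )
        d = distance_to_point(GRID, VOX, np.zeros(3), np.asarray(CENTER))
        center_val = img.values[img.nearest_index(CENTER)]
        shell_mean = img.values[(d >= 8) & (d <= 12)].mean()
        assert center_val < shell_mean

    def test_mass_conservation_without_noise(self):
        truth = rasterize_phantom(_single(), VOX, GRID, supersampling=4)
        for variant in (
            ReconVariant("sharp", psf_fwhm=12.0, ringing_amplitude=0.5),
            ReconVariant("smoothed", psf_fwhm=12.0, post_filter_fwhm=10.0),
        ):
            out = apply_recon_variant(truth, variant)
            assert out.total_activity_kbq() == pytest.approx(
                truth.total_activity_kbq(), rel=0.01
            )

    def test_noise_reproducible_and_seed_sensitive(self):
        truth = rasterize_phantom(_single(), VOX, GRID, supersampling=2)
        v = ReconVariant("sharp", psf_fwhm=12.0, noise_scale=100.0)
        a = apply_recon_variant(truth, v, seed=7).values
        b = apply_recon_variant(truth, v, seed=7).values
        c = apply_recon_variant(truth, v, seed=8).values
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_non_finite_input_rejected(self):
        vals = np.zeros(GRID)
        vals[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            VoxelImage(vals, VOX)


class TestEdgePreserving:
    def test_noiseless_input_gives_regionwise_means(self):
        spec = _single(bkg=54.1)
        truth = rasterize_phantom(spec, VOX, GRID, supersampling=2)
        blurred = apply_recon_variant(truth, ReconVariant("sharp", psf_fwhm=12.0))
        out = emulate_edge_preserving(truth, blurred, spec, edge_fwhm=0.0)
        assert len(np.unique(out.values)) == 2  # one sphere region + background

    def test_sphere_profile_flatter_than_sharp_variant(self):
        spec = _single()
        truth = rasterize_phantom(spec, VOX, GRID, supersampling=4)
        sharp = apply_recon_variant(
            truth, ReconVariant("sharp", psf_fwhm=12.0, ringing_amplitude=0.5)
        )
        out = emulate_edge_preserving(truth, sharp, spec)
        d = distance_to_point(GRID, VOX, np.zeros(3), np.asarray(CENTER))
        inside = d <= 37.0 / 2 - VOX  # interior voxels
        assert out.values[inside].std() < sharp.values[inside].std()

    def test_grid_mismatch_rejected(self):
        spec = _single()
        truth = rasterize_phantom(spec, VOX, GRID, supersampling=1)
        other = VoxelImage(np.zeros((10, 10, 10)), VOX)
        with pytest.raises(ValueError, match="grid"):
            emulate_edge_preserving(truth, other, spec)


class TestPhantomSeries:
    def test_ratio_9_5_gives_background_54_1(self):
        specs = make_phantom_series(default_phantom(), [9.5])
        assert specs[0].background_concentration == pytest.approx(514.0 / 9.5)
        assert specs[0].background_concentration == pytest.approx(54.1, abs=0.01)

    def test_infinite_ratio_gives_cold_background(self):
        (spec,) = make_phantom_series(default_phantom(), [math.inf])
        assert spec.background_concentration == 0.0
        assert spec.label == "P_inf"

    def test_default_series_labels(self):
        specs = make_phantom_series(default_phantom(), [math.inf, 9.5, 5.0, 2.7])
        assert [s.label for s in specs] == ["P_inf", "P_9.5", "P_5.0", "P_2.7"]
        assert all(len(s.spheres) == 6 for s in specs)

    def test_ratio_at_or_below_one_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            make_phantom_series(default_phantom(), [1.0])


class TestSpecsAndIO:
    def test_overlapping_spheres_rejected(self):
        s1 = SphereSpec(center=(0, 0, 0), diameter=20, true_concentration=1)
        s2 = SphereSpec(center=(15, 0, 0), diameter=20, true_concentration=1)
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(spheres=(s1, s2))

    def test_yaml_roundtrip(self, tmp_path):
        spec = default_phantom(background_concentration=54.1, label="P_9.5")
        p = tmp_path / "spec.yaml"
        spec.to_yaml(p)
        back = PhantomSpec.from_yaml(p)
        assert back == spec

    def test_nifti_roundtrip(self, tmp_path):
        img = rasterize_phantom(_single(), VOX, GRID, supersampling=1)
        p = tmp_path / "img.nii.gz"
        img.to_nifti(p)
        back = VoxelImage.from_nifti(p)
        assert back.voxel_size == pytest.approx(VOX)
        np.testing.assert_allclose(back.values, img.values, rtol=1e-6)

    def test_default_phantom_matches_nema_layout(self, nema_phantom):
        assert tuple(s.diameter for s in nema_phantom.spheres) == NEMA_SPHERE_DIAMETERS_MM
        # all six centers on one transverse plane, on a 114.4 mm circle
        centers = np.array([s.center for s in nema_phantom.spheres])
        assert np.ptp(centers[:, 2]) == 0
        mid = centers.mean(axis=0)
        radii = np.linalg.norm(centers - mid, axis=1)
        np.testing.assert_allclose(radii, 114.4 / 2, rtol=1e-6)
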