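"""Scalar quantification metrics: contrast, deviation, RC, SBVR, CF, rescale."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from luquant.phantom import (
    PhantomSpec,
    ReconVariant,
    SphereSpec,
    VoxelImage,
    apply_recon_variant,
    rasterize_phantom,
)
from luquant.quantify import (
    accuracy_deviation,
    background_voi,
    calibration_factor,
    contrast,
    recovery_coefficient,
    rescale_to_reference,
    sbvr,
)
from luquant.voi import expanded_voi, voi_stats

VOX = 4.8
GRID = (64, 64, 40)
CENTER = tuple((np.asarray(GRID, float) - 1) / 2.0 * VOX)


def _single_truth(diameter, bkg=0.0, conc=514.0):
    spec = PhantomSpec(
        spheres=(SphereSpec(center=CENTER, diameter=diameter, true_concentration=conc),),
        background_concentration=bkg,
    )
    return spec, rasterize_phantom(spec, VOX, GRID, supersampling=4)


class TestContrast:
    @pytest.mark.parametrize(
        "c_dia,c_bkg,expected",
        [(3.0, 1.0, 0.5), (1.0, 0.0, 1.0), (5.0, 5.0, 0.0), (9.5, 1.0, 0.8095)],
    )
    def test_values(self, c_dia, c_bkg, expected):
        assert contrast(c_dia, c_bkg) == pytest.approx(expected, abs=1e-4)

    def test_undefined_for_zero_sum(self):
        with pytest.raises(ValueError):
            contrast(0.0, 0.0)

    @given(
        a=st.floats(0.01, 1e4),
        b=st.floats(0.01, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_and_bounded(self, a, b):
        c = contrast(a, b)
        assert -1 <= c <= 1
        assert c == pytest.approx(-contrast(b, a))

    @given(
        b=st.floats(0.01, 100),
        r1=st.floats(1.0, 50),
        r2=st.floats(1.0, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_ratio(self, b, r1, r2):
        if abs(r1 - r2) < 1e-9:
            return
        lo, hi = sorted([r1, r2])
        assert contrast(lo * b, b) < contrast(hi * b, b)


class TestAccuracyDeviation:
    def test_identities(self):
        assert accuracy_deviation(5.0, 5.0) == 0.0
        assert accuracy_deviation(4.5, 5.0) == pytest.approx(-0.10)
        with pytest.raises(ValueError):
            accuracy_deviation(1.0, 0.0)

    def test_large_voi_capture_matches_monte_carlo_oracle(self):
        """Activity captured in VOI_dia+15 on a blurred ø13 sphere agrees with
        an independent Monte-Carlo displacement simulation of the same blur.

        Measured on a 2.4 mm grid so voxel-boundary discretization stays
        below the comparison tolerance.
        """
        vox, grid = 2.4, (96, 96, 72)
        center = tuple((np.asarray(grid, float) - 1) / 2.0 * vox)
        spec = PhantomSpec(
            spheres=(
                SphereSpec(center=center, diameter=13.0, true_concentration=514.0),
            )
        )
        truth = rasterize_phantom(spec, vox, grid, supersampling=4)
        img = apply_recon_variant(truth, ReconVariant("sharp", psf_fwhm=12.0))
        big = expanded_voi(img, center, 13.0, 15.0)
        measured = voi_stats(img, big).activity_kbq / spec.spheres[0].activity_kbq

        rng = np.random.default_rng(42)
        n = 200_000
        # uniform points in the sphere, displaced by the Gaussian PSF
        pts = rng.normal(size=(n, 3))
        pts *= (rng.uniform(size=(n, 1)) ** (1 / 3)) * 6.5 / np.linalg.norm(
            pts, axis=1, keepdims=True
        )
        sigma = 12.0 / (2 * math.sqrt(2 * math.log(2)))
        pts += rng.normal(scale=sigma, size=(n, 3))
        oracle = float(np.mean(np.linalg.norm(pts, axis=1) <= (13.0 + 15.0) / 2))
        assert measured == pytest.approx(oracle, abs=0.01)

    def test_small_deviation_for_sharp_psf(self):
        """With a 6 mm PSF essentially all ø13-sphere counts stay in VOI_dia+15."""
        spec, truth = _single_truth(13.0)
        img = apply_recon_variant(truth, ReconVariant("sharp", psf_fwhm=6.0))
        big = expanded_voi(img, CENTER, 13.0, 15.0)
        dev = accuracy_deviation(
            voi_stats(img, big).activity_kbq, spec.spheres[0].activity_kbq
        )
        assert abs(dev) <= 0.02


class TestRecoveryCoefficient:
    def test_unblurred_truth_rc_is_one(self, single_sphere28):
        """Without blur there is no spill-out: all rasterized activity stays in
        VOI_dia (binary voxelization paired with binary masks)."""
        s = single_sphere28.spheres[0]
        truth = rasterize_phantom(single_sphere28, VOX, GRID, supersampling=1)
        rc = recovery_coefficient(truth, s.center, s.diameter, supersampling=1)
        assert rc == pytest.approx(1.0, abs=1e-6)

    def test_rc_increases_with_diameter(self):
        rcs = {}
        for d in (10.0, 22.0, 37.0):
            _, truth = _single_truth(d)
            img = apply_recon_variant(truth, ReconVariant("sharp", psf_fwhm=12.0))
            rcs[d] = recovery_coefficient(img, CENTER, d)
        assert rcs[10.0] < rcs[22.0] < rcs[37.0] < 1.0

    def test_invariant_under_global_rescaling(self):
        _, truth = _single_truth(22.0)
        img = apply_recon_variant(truth, ReconVariant("sharp", psf_fwhm=12.0))
        rc1 = recovery_coefficient(img, CENTER, 22.0)
        scaled = VoxelImage(img.values * 3.7, img.voxel_size, img.origin)
        rc2 = recovery_coefficient(scaled, CENTER, 22.0)
        assert rc1 == pytest.approx(rc2, rel=1e-12)

    def test_reference_must_be_positive(self, truth28, single_sphere28):
        s = single_sphere28.spheres[0]
        with pytest.raises(ValueError):
            recovery_coefficient(truth28, s.center, s.diameter, reference_activity=0.0)


class TestSBVRandCF:
    def test_sbvr_identities(self):
        assert sbvr(5.0, 5.0) == 1.0
        assert sbvr(6.2, 1.0) == pytest.approx(6.2)
        with pytest.raises(ValueError):
            sbvr(1.0, 0.0)

    def test_measured_sbvr_below_true_ratio_for_small_sphere(self):
        """Spill-out drags the measured sphere mean (hence SBVR) below 2.7."""
        spec, truth = _single_truth(13.0, bkg=514.0 / 2.7)
        img = apply_recon_variant(truth, ReconVariant("sharp", psf_fwhm=12.0))
        from luquant.voi import spherical_voi

        c_dia = voi_stats(img, spherical_voi(img, CENTER, 13.0)).mean
        c_bkg = voi_stats(img, background_voi(img, spec)).mean
        assert sbvr(c_dia, c_bkg) < 2.7

    def test_calibration_factor_linearity(self):
        assert calibration_factor(514.0, 514.0).cf == pytest.approx(10.9)
        assert calibration_factor(0.0, 514.0).cf == 0.0
        assert calibration_factor(257.0, 514.0).cf == pytest.approx(5.45)
        with pytest.raises(ValueError):
            calibration_factor(1.0, 0.0)


class TestRescale:
    def test_identity_and_halving(self):
        rng = np.random.default_rng(3)
        ref = VoxelImage(rng.uniform(1, 2, (10, 10, 10)), VOX)
        same = rescale_to_reference(ref, ref)
        np.testing.assert_allclose(same.values, ref.values)
        double = VoxelImage(ref.values * 2, VOX)
        back = rescale_to_reference(double, ref)
        np.testing.assert_allclose(back.values, ref.values)

    def test_sum_preserved_to_machine_precision(self):
        rng = np.random.default_rng(4)
        ref = VoxelImage(rng.uniform(0.5, 3, (16, 16, 16)), VOX)
        img = VoxelImage(rng.uniform(0.1, 9, (16, 16, 16)), VOX)
        out = rescale_to_reference(img, ref)
        assert out.values.sum() / ref.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_sum_rejected(self):
        z = VoxelImage(np.zeros((4, 4, 4)), VOX)
        r = VoxelImage(np.ones((4, 4, 4)), VOX)
        with pytest.raises(ValueError):
            rescale_to_reference(z, r)
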