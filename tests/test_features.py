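"""Derived images, discretization, and the texture/shape feature bank,
checked against brute-force direct-definition oracles."""

import numpy as np
import pytest

from periradiomics.features import (
    DiscretizationSpec,
    ExtractionSpec,
    apply_filter,
    discretize,
    extract_all,
    feature_names,
    first_order,
    glcm_features,
    ngtdm_features,
    shape_features,
)
from periradiomics.grid import BinaryMask, Volume
from periradiomics.image_ops import ImagingConfig
from periradiomics.synthetic import PhantomSpec, generate_vessel_phantom

from .conftest import make_mask, make_volume, random_roi
from .oracles import (
    entropy_uniformity_oracle,
    first_order_oracle,
    glcm_oracle,
    ngtdm_oracle,
)


class TestFilters:
    def test_squareroot_is_signed(self):
        vol = make_volume(np.array([[[4.0, -9.0, 0.0]]]))
        out = apply_filter(vol, "squareroot")
        assert out.values.ravel().tolist() == [2.0, -3.0, 0.0]

    def test_log_of_constant_is_zero(self):
        vol = make_volume(np.full((12, 12, 12), 77.0), spacing=(0.5, 0.5, 2.0))
        out = apply_filter(vol, "log_sigma_2_0_mm")
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_gradient_of_affine_field_is_slope(self):
        shape = (12, 12, 12)
        spacing = (0.5, 0.5, 1.5)
        idx = np.indices(shape).astype(float)
        a = 7.0
        vol = make_volume(a * idx[0] * spacing[0], spacing=spacing)
        out = apply_filter(vol, "gradient")
        interior = out.values[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, abs(a), atol=1e-10)

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError):
            apply_filter(make_volume(np.zeros((2, 2, 2))), "wavelet")


class TestDiscretize:
    def test_hu_anchored_bin_edges(self):
        vol = make_volume(np.array([[[-170.0, -145.1, -145.0, 200.0]]]))
        roi = make_mask(np.ones((1, 1, 4), bool))
        levels, ng = discretize(vol, roi)
        assert levels.ravel().tolist() == [1, 1, 2, 15]
        assert ng == 15

    def test_constant_roi_single_level(self):
        # constant inside the first HU bin -> level 1, Ng = 1
        vol = make_volume(np.full((3, 3, 3), -160.0))
        roi = make_mask(np.ones((3, 3, 3), bool))
        levels, ng = discretize(vol, roi)
        assert ng == 1 and set(levels[roi.values]) == {1}
        # under ROI-minimum anchoring any constant lands in level 1
        _, ng_f = discretize(make_volume(np.full((3, 3, 3), 123.4)), roi,
                             filter_name="gradient")
        assert ng_f == 1

    def test_filtered_image_anchors_at_roi_minimum(self):
        vol = make_volume(np.array([[[3.0, 3.9, 4.1]]]))
        roi = make_mask(np.ones((1, 1, 3), bool))
        levels, ng = discretize(vol, roi, filter_name="squareroot")  # width 1.0
        assert levels.ravel().tolist() == [1, 1, 2]

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            discretize(make_volume(np.zeros((2, 2, 2))), make_mask(np.zeros((2, 2, 2), bool)))


class TestFirstOrder:
    def test_simple_mean(self):
        vol = make_volume(np.array([[[1.0, 1.0, 3.0]]]))
        roi = make_mask(np.ones((1, 1, 3), bool))
        assert first_order(vol, roi)["Mean"] == pytest.approx(5.0 / 3.0)

    def test_uniform_four_bins_entropy_two_bits(self):
        vol = make_volume(np.array([[[-170.0, -145.0, -120.0, -95.0]]]))
        roi = make_mask(np.ones((1, 1, 4), bool))
        fo = first_order(vol, roi)
        assert fo["Entropy"] == pytest.approx(2.0)
        assert fo["Uniformity"] == pytest.approx(0.25)

    def test_single_voxel_roi_degenerate_moments(self):
        vol = make_volume(np.full((1, 1, 1), 12.0))
        roi = make_mask(np.ones((1, 1, 1), bool))
        fo = first_order(vol, roi)
        assert fo["Variance"] == 0.0 and fo["Skewness"] == 0.0 and fo["Kurtosis"] == 0.0

    def test_matches_direct_definition_oracle(self, rng):
        for _ in range(30):
            shape = tuple(rng.integers(2, 7, size=3))
            vals = rng.normal(0, 90, size=shape)
            roi = rng.random(shape) < 0.8
            if not roi.any():
                continue
            vol, mask = make_volume(vals), make_mask(roi)
            fo = first_order(vol, mask)
            want = first_order_oracle(vals[roi])
            for k, v in want.items():
                assert fo[k] == pytest.approx(v, rel=1e-10, abs=1e-10), k
            levels, _ = discretize(vol, mask)
            ent, uni = entropy_uniformity_oracle(levels[roi])
            assert fo["Entropy"] == pytest.approx(ent, abs=1e-10)
            assert fo["Uniformity"] == pytest.approx(uni, abs=1e-10)


class TestGLCM:
    def test_homogeneous_roi_zero_contrast_and_inverse_variance(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        roi = make_mask(np.ones((3, 3, 3), bool))
        g = glcm_features(levels, roi, 1)
        assert g["Contrast"] == 0.0
        assert g["InverseVariance"] == 0.0
        assert g["Correlation"] == 1.0  # degenerate single-level convention

    def test_two_adjacent_voxels_hand_matrix(self):
        levels = np.zeros((1, 1, 2), dtype=np.int64)
        levels[0, 0, 0], levels[0, 0, 1] = 1, 2
        roi = make_mask(np.ones((1, 1, 2), bool))
        g = glcm_features(levels, roi, 2)
        # single direction with pairs: p(1,2) = p(2,1) = 0.5 -> InvVar = 1
        assert g["InverseVariance"] == pytest.approx(1.0)
        assert g["Contrast"] == pytest.approx(1.0)
        assert g["JointEntropy"] == pytest.approx(1.0)

    def test_isolated_voxels_no_pairs_gives_zero(self):
        levels = np.zeros((5, 5, 5), dtype=np.int64)
        roi = np.zeros((5, 5, 5), bool)
        roi[0, 0, 0] = roi[4, 4, 4] = True
        levels[roi] = 1
        g = glcm_features(levels, make_mask(roi), 1)
        assert all(v == 0.0 for v in g.values())

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(25):
            levels, roi, ng = random_roi(rng, shape=tuple(rng.integers(3, 7, size=3)))
            got = glcm_features(levels, make_mask(roi), ng)
            want = glcm_oracle(levels, roi, ng)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-10), k


class TestNGTDM:
    def test_homogeneous_roi_zero_strength_capped_coarseness(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        roi = make_mask(np.ones((3, 3, 3), bool))
        f = ngtdm_features(levels, roi, 1)
        assert f["Strength"] == 0.0
        assert f["Coarseness"] == 1e12  # documented cap = 1/eps

    def test_three_voxel_line_matches_oracle(self):
        levels = np.zeros((1, 1, 3), dtype=np.int64)
        levels[0, 0] = [1, 2, 1]
        roi = np.ones((1, 1, 3), bool)
        got = ngtdm_features(levels, make_mask(roi), 2)
        want = ngtdm_oracle(levels, roi, 2)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-10), k

    def test_matches_direct_definition_oracle(self, rng):
        for _ in range(25):
            levels, roi, ng = random_roi(rng, shape=tuple(rng.integers(3, 7, size=3)))
            got = ngtdm_features(levels, make_mask(roi), ng)
            want = ngtdm_oracle(levels, roi, ng)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-10), k

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            ngtdm_features(np.zeros((2, 2, 2), np.int64), make_mask(np.zeros((2, 2, 2), bool)), 1)


class TestShape:
    def test_single_voxel(self):
        sh = shape_features(make_mask(np.ones((1, 1, 1), bool)))
        assert sh["VoxelVolume"] == 1.0
        assert sh["SurfaceArea"] == 6.0
        assert sh["Maximum3DDiameter"] == 0.0

    def test_two_voxel_block_face_count(self):
        m = np.zeros((4, 1, 1), bool)
        m[1:3, 0, 0] = True
        sh = shape_features(make_mask(m))
        assert sh["VoxelVolume"] == 2.0
        assert sh["SurfaceArea"] == 10.0
        assert sh["Maximum3DDiameter"] == 1.0

    def test_anisotropic_spacing(self):
        sh = shape_features(make_mask(np.ones((1, 1, 1), bool), spacing=(0.5, 0.5, 3.0)))
        assert sh["VoxelVolume"] == pytest.approx(0.75)
        assert sh["SurfaceArea"] == pytest.approx(2 * 0.25 + 4 * 1.5)

    def test_sphericity_approaches_one_for_growing_balls(self):
        last = 0.0
        for n, r in ((12, 4.5), (24, 9.5), (40, 17.5)):
            idx = np.indices((n, n, n)).astype(float)
            c = (n - 1) / 2
            ball = ((idx[0] - c) ** 2 + (idx[1] - c) ** 2 + (idx[2] - c) ** 2) <= r * r
            s = shape_features(make_mask(ball))["Sphericity"]
            assert s <= 1.0 + 1e-9
            assert s > last * 0.99
            last = s
        # voxelized surface area exceeds the smooth sphere's, bounding sphericity
        assert 0.6 < last < 1.0


@pytest.fixture(scope="module")
def phantom():
    spec = PhantomSpec(stenoses=[(0.5, 0.5, 10.0)],
                       plaques=[((12.0, 9.0, 21.0), 2.5, 400.0)],
                       noise_sd_hu=10.0, seed=5)
    return generate_vessel_phantom(spec)


class TestExtractAll:
    def test_schema_constant_and_named(self, phantom):
        vol, mask, _ = phantom
        fv = extract_all(vol, mask, ImagingConfig("original"))
        names = feature_names()
        assert list(fv.index) == names
        spec = ExtractionSpec()
        expected = len(spec.filters) * (12 + 5 + 5) + 4
        assert len(fv) == expected
        assert "squareroot_ngtdm_Strength" in fv.index
        assert "log_sigma_2_0_mm_glcm_InverseVariance" in fv.index
        assert np.isfinite(fv.to_numpy()).all()

    def test_deterministic_repeat(self, phantom):
        vol, mask, _ = phantom
        cfg = ImagingConfig("resampled", 1.0, "bspline3")
        a = extract_all(vol, mask, cfg)
        b = extract_all(vol, mask, cfg)
        assert a.equals(b)

    def test_translation_invariance_of_intensity_features(self):
        # noise-free phantom in constant background: lateral whole-voxel
        # shifts leave every non-shape feature unchanged
        spec = PhantomSpec(stenoses=[(0.5, 0.5, 10.0)],
                           plaques=[((12.0, 9.0, 21.0), 2.5, 400.0)],
                           noise_sd_hu=0.0)
        vol, mask, _ = generate_vessel_phantom(spec)
        fv = extract_all(vol, mask, ImagingConfig("original"))
        shifted_vals = np.roll(vol.values, shift=(2, -3, 0), axis=(0, 1, 2))
        shifted_mask = np.roll(mask.values, shift=(2, -3, 0), axis=(0, 1, 2))
        fv2 = extract_all(
            Volume(shifted_vals, vol.spacing_mm),
            BinaryMask(shifted_mask, mask.spacing_mm),
            ImagingConfig("original"),
        )
        non_shape = [n for n in fv.index if not n.startswith("original_shape")]
        assert np.allclose(fv[non_shape], fv2[non_shape], rtol=1e-10, atol=1e-10)
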