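"""Phantom generator, Agatston scoring, category maps, cohort tables."""

import numpy as np
import pytest

from periradiomics.grid import BinaryMask, Volume
from periradiomics.synthetic import (
    CohortTableSpec,
    PhantomSpec,
    agatston_score,
    cac_category,
    generate_feature_cohort,
    generate_vessel_phantom,
    stenosis_category,
)

from .oracles import agatston_oracle


def _slab(hu_2d, spacing=(0.5, 0.5, 3.0)):
    """Single-slice volume + all-true region, from a 2-D HU array."""
    hu = np.asarray(hu_2d, dtype=float)[:, :, None]
    vol = Volume(hu, spacing)
    region = BinaryMask(np.ones_like(hu, dtype=bool), spacing)
    return vol, region


class TestAgatston:
    def test_all_below_threshold_scores_zero(self):
        vol, region = _slab(np.full((8, 8), 129.9))
        assert agatston_score(vol, region) == 0.0

    def test_ten_voxel_lesion_at_150_hu(self):
        # 10 voxels x 0.25 mm^2 x weight 1, slice factor 3/3
        hu = np.zeros((8, 8))
        hu[2, 1:6] = 150.0
        hu[3, 1:6] = 150.0
        vol, region = _slab(hu)
        assert agatston_score(vol, region) == pytest.approx(2.5)

    def test_dense_lesion_weight_four(self):
        # area 2.0 mm^2 (8 voxels at 0.25 mm^2), max 405 HU -> 2.0 x 4 = 8 AU
        hu = np.zeros((8, 8))
        hu[2, 1:5] = 150.0
        hu[3, 1:5] = 150.0
        hu[2, 2] = 405.0
        vol, region = _slab(hu)
        assert agatston_score(vol, region) == pytest.approx(8.0)

    def test_sub_area_lesion_ignored(self):
        hu = np.zeros((8, 8))
        hu[4, 4:7] = 500.0  # 3 voxels -> 0.75 mm^2 < 1 mm^2
        vol, region = _slab(hu)
        assert agatston_score(vol, region) == 0.0

    def test_slice_thickness_scaling(self):
        hu = np.zeros((8, 8))
        hu[2:4, 1:6] = 150.0
        vol = Volume(hu[:, :, None], (0.5, 0.5, 1.5))
        region = BinaryMask(np.ones((8, 8, 1), bool), (0.5, 0.5, 1.5))
        assert agatston_score(vol, region) == pytest.approx(1.25)

    def test_matches_brute_force_oracle_on_random_fields(self, rng):
        for _ in range(20):
            hu = rng.normal(100.0, 120.0, size=(10, 10, 4))
            region = rng.random((10, 10, 4)) < 0.6
            spacing = (0.6, 0.6, 2.5)
            got = agatston_score(Volume(hu, spacing), BinaryMask(region, spacing))
            want = agatston_oracle(hu, region, spacing)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


class TestCategories:
    @pytest.mark.parametrize(
        "score,expected",
        [(0, 0), (10, 0), (10.5, 1), (100, 1), (101, 2), (399, 2), (400, 3), (2500, 3)],
    )
    def test_cac_bins(self, score, expected):
        assert cac_category(score) == expected

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            cac_category(-1.0)

    def test_cac_monotone_step(self):
        grid = np.linspace(0, 2000, 4001)
        cats = [cac_category(s) for s in grid]
        assert all(b >= a for a, b in zip(cats, cats[1:]))

    @pytest.mark.parametrize(
        "pct,expected",
        [(0, "none"), (5, "none"), (9.9, "none"), (10, "mild"), (49, "mild"),
         (50, "moderate"), (70, "moderate"), (70.1, "severe"), (75, "severe"), (100, "severe")],
    )
    def test_four_way_grades(self, pct, expected):
        assert stenosis_category(pct, "four") == expected

    @pytest.mark.parametrize(
        "pct,expected",
        [(5, "none"), (49, "mild"), (50, "significant"), (90, "significant")],
    )
    def test_three_way_grades(self, pct, expected):
        assert stenosis_category(pct, "three") == expected

    def test_three_way_coarsens_four_way(self):
        for pct in np.linspace(0, 100, 201):
            four = stenosis_category(pct, "four")
            three = stenosis_category(pct, "three")
            if four in ("moderate", "severe"):
                assert three == "significant"
            else:
                assert three == four

    @pytest.mark.parametrize("pct", [-1, 101])
    def test_out_of_range_pct_rejected(self, pct):
        with pytest.raises(ValueError):
            stenosis_category(pct)


class TestPhantom:
    def test_lesion_free_phantom_ground_truth(self):
        spec = PhantomSpec(noise_sd_hu=0.0)
        _, _, truth = generate_vessel_phantom(spec)
        assert truth.max_stenosis_pct == 0.0
        assert truth.agatston_au == 0.0
        assert truth.cac_class == 0
        assert truth.stenosis_class4 == "none"

    def test_severity_06_grades_moderate(self):
        spec = PhantomSpec(stenoses=[(0.5, 0.6, 10.0)])
        _, _, truth = generate_vessel_phantom(spec)
        assert truth.max_stenosis_pct == pytest.approx(60.0, abs=0.5)
        assert truth.stenosis_class4 == "moderate"
        assert truth.stenosis_class3 == "significant"

    def test_plaque_cac_class_from_per_voxel_oracle(self):
        spec = PhantomSpec(
            plaques=[((12.0, 9.0, 21.0), 3.0, 600.0)], noise_sd_hu=0.0
        )
        vol, lumen, truth = generate_vessel_phantom(spec)
        want = agatston_oracle(
            vol.values, ~lumen.values, tuple(vol.spacing_mm)
        )
        assert truth.agatston_au == pytest.approx(want, rel=1e-12)
        assert truth.cac_class == cac_category(want)

    def test_bit_identical_under_same_seed(self):
        spec = dict(stenoses=[(0.5, 0.4, 9.0)], noise_sd_hu=12.0, seed=77)
        v1, m1, t1 = generate_vessel_phantom(PhantomSpec(**spec))
        v2, m2, t2 = generate_vessel_phantom(PhantomSpec(**spec))
        assert np.array_equal(v1.values, v2.values)
        assert np.array_equal(m1.values, m2.values)
        assert t1 == t2

    def test_lumen_mask_is_tube_rasterization(self):
        vol, lumen, _ = generate_vessel_phantom(PhantomSpec(noise_sd_hu=0.0))
        # noise-free lumen voxels carry lumen attenuation exactly
        assert np.all(vol.values[lumen.values] == 400.0)
        assert lumen.count() > 0

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="grid too small"):
            generate_vessel_phantom(PhantomSpec(grid_shape=(6, 6, 8)))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(stenoses=[(0.5, 0.95, 10.0)]),  # severity > 0.9
            dict(plaques=[((9, 9, 20), 2.0, 100.0)]),  # peak < 130
            dict(spacing_mm=(0.5, -0.5, 3.0)),
            dict(segment_id="RCA"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs)


class TestCohort:
    def test_duplicated_block_has_unit_correlation(self):
        spec = CohortTableSpec(
            n_subjects=80, n_features=6, corr_blocks=[((3, 4), 1.0)], seed=5
        )
        table = generate_feature_cohort(spec)
        r = np.corrcoef(table.features["f003"], table.features["f004"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_partial_correlation_block(self):
        spec = CohortTableSpec(
            n_subjects=4000, n_features=5, corr_blocks=[((0, 1, 2), 0.6)], seed=5
        )
        table = generate_feature_cohort(spec)
        sub = table.features[["f000", "f001", "f002"]].to_numpy()
        corr = np.corrcoef(sub.T)
        off = corr[np.triu_indices(3, 1)]
        assert np.allclose(off, 0.6, atol=0.05)

    def test_zero_effect_sizes_give_equal_class_means(self):
        spec = CohortTableSpec(
            n_subjects=4000, n_features=3,
            informative=[(0, (0.0, 0.0))], seed=9,
        )
        table = generate_feature_cohort(spec)
        means = table.features.groupby(table.labels.values)["f000"].mean()
        assert abs(means.iloc[0] - means.iloc[1]) < 0.12

    def test_planted_shift_appears(self):
        spec = CohortTableSpec(
            n_subjects=2000, n_features=3, informative=[(1, (0.0, 1.5))], seed=2
        )
        table = generate_feature_cohort(spec)
        means = table.features.groupby(table.labels.values)["f001"].mean()
        assert means.iloc[1] - means.iloc[0] == pytest.approx(1.5, abs=0.15)

    def test_per_config_panel_layout_and_perturbation(self):
        spec = CohortTableSpec(
            n_subjects=50, n_features=4, unstable_set=[2], n_configs=6, seed=3
        )
        table = generate_feature_cohort(spec)
        assert table.per_config.shape == (6, 50, 4)
        # original layer equals the base features
        assert np.array_equal(table.per_config[0], table.features.to_numpy())
        # stable columns identical across configs; unstable perturbed
        assert np.array_equal(table.per_config[3][:, 0], table.per_config[0][:, 0])
        assert not np.array_equal(table.per_config[3][:, 2], table.per_config[0][:, 2])

    def test_missing_covariates_mean_imputed(self):
        spec = CohortTableSpec(
            n_subjects=400, n_features=2,
            clinical_covariates={"age": ("normal", 58.0, 9.0), "sex": ("bernoulli", 0.55)},
            missing_rate=0.2, seed=4,
        )
        table = generate_feature_cohort(spec)
        assert not table.covariates.isna().any().any()
        # imputed values collapse onto the observed mean -> duplicated value
        assert (table.covariates["age"].round(9).value_counts().iloc[0] > 1)

    def test_reproducible_under_seed(self):
        spec = CohortTableSpec(n_subjects=30, n_features=5, n_configs=3,
                               unstable_set=[1], seed=11)
        a = generate_feature_cohort(spec)
        b = generate_feature_cohort(spec)
        assert a.features.equals(b.features)
        assert np.array_equal(a.per_config, b.per_config)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(class_priors=(0.6, 0.6)),
            dict(corr_blocks=[((0, 99), 0.5)]),
            dict(corr_blocks=[((0, 1), 1.5)]),
            dict(informative=[(99, (0.0, 1.0))]),
            dict(informative=[(0, (0.0, 1.0, 2.0))]),
        ],
    )
    def test_invalid_cohort_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortTableSpec(n_subjects=10, n_features=4, **kwargs)
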