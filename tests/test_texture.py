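"""Texture families: worked examples, brute-force equivalence, invariants."""

import numpy as np
import pandas as pd
import pytest

from oracles import brute_glcm_counts, brute_rlm_counts, grey_from_slices
from radstage.grids import ROIMask, VoxelGrid
from radstage import texture as tx


@pytest.fixture()
def toy_glcm():
    """The 2x3 slice [[0,0,1],[0,1,1]]: four ordered pairs at angle0."""
    g = grey_from_slices([[0, 0, 1], [0, 1, 1]], L=2)
    return tx.glcm(g, "angle0", 1)


class TestGLCM:
    def test_enumerated_pair_probabilities(self, toy_glcm):
        np.testing.assert_allclose(toy_glcm.g, np.full((2, 2), 0.25))

    def test_energy_and_entropy_worked_example(self, toy_glcm):
        assert tx.glcm_energy(toy_glcm) == pytest.approx(0.25, abs=1e-10)
        assert tx.glcm_entropy(toy_glcm) == pytest.approx(2.0, abs=1e-10)

    def test_constant_image_energy_one_entropy_zero(self):
        g = grey_from_slices(np.zeros((4, 5), dtype=int), L=2)
        m = tx.glcm(g, "angle0", 1)
        assert tx.glcm_energy(m) == pytest.approx(1.0, abs=1e-12)
        assert tx.glcm_entropy(m) == pytest.approx(0.0, abs=1e-12)
        fs = tx.glcm_feature_set(m)
        assert fs["GLCMContrast"] == 0.0
        assert fs["GLCMInverseDifferenceMoment"] == pytest.approx(1.0)

    def test_checkerboard_contrast(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        m = tx.glcm(grey_from_slices(board, L=2), "angle0", 1)
        assert tx.glcm_feature_set(m)["GLCMContrast"] == pytest.approx(1.0)

    def test_cluster_shade_zero_for_symmetric_distribution(self, toy_glcm):
        # uniform g is symmetric about its mean index
        assert tx.glcm_feature_set(toy_glcm)["GLCMClusterShade"] == \
            pytest.approx(0.0, abs=1e-12)

    def test_uniform_energy_is_one_over_k(self):
        assert tx.glcm_energy(tx.CooccurrenceMatrix(
            np.full((4, 4), 1 / 16), "angle0", 1)) == pytest.approx(1 / 16)

    def test_normalized_and_symmetric(self, rng):
        for _ in range(10):
            arr = rng.integers(0, 5, size=(6, 6, 3))
            mask = ROIMask(rng.random((6, 6, 3)) < 0.7)
            g = tx.GreyVolume(arr.astype(np.int32), L=5, mask=mask)
            m = tx.glcm(g, "angle45", 1)
            assert m.g.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(m.g, m.g.T)
            assert 0 < tx.glcm_energy(m) <= 1
            assert 0 <= tx.glcm_entropy(m) <= 2 * np.log2(5)

    def test_no_pairs_raises(self):
        arr = np.zeros((1, 1, 1), dtype=np.int32)
        g = tx.GreyVolume(arr, L=2, mask=ROIMask(np.ones((1, 1, 1), dtype=bool)))
        with pytest.raises(tx.NoPairsError):
            tx.glcm(g, "angle0", 1)


class TestHaralick:
    def test_dissimilarity_worked_example(self, toy_glcm):
        fs = tx.haralick_features(toy_glcm)
        assert fs["HaralickDissimilarity"] == pytest.approx(0.5, abs=1e-10)

    def test_constant_image_degenerate(self):
        g = grey_from_slices(np.zeros((4, 4), dtype=int), L=2)
        fs = tx.haralick_features(tx.glcm(g, "angle0", 1))
        assert fs["HaralickDifferenceEntropy"] == pytest.approx(0.0)
        assert fs["HaralickDissimilarity"] == pytest.approx(0.0)

    def test_imc1_zero_for_independent_matrix(self):
        px = np.array([0.3, 0.7])
        m = tx.CooccurrenceMatrix(np.outer(px, px), "angle0", 1)
        assert tx.haralick_features(m)["HaralickIMC1"] == \
            pytest.approx(0.0, abs=1e-12)


class TestRLM:
    def test_row_223_enumeration(self):
        t = tx.rlm(grey_from_slices([[2, 2, 3]], L=4), "angle0", 1)
        assert t.n_r == 2
        assert t.counts[2, 1] == 1  # level 2, length 2
        assert t.counts[3, 0] == 1  # level 3, length 1

    def test_row_223_emphases(self):
        t = tx.rlm(grey_from_slices([[2, 2, 3]], L=4), "angle0", 1)
        fs = tx.rlm_feature_set(t)
        assert fs["HighGreyLevelRunEmphasis"] == pytest.approx(6.5, abs=1e-10)
        assert fs["LowGreyLevelRunEmphasis"] == pytest.approx(
            (1 / 4 + 1 / 9) / 2, abs=1e-10)
        assert fs["ShortRunHighGreyLevelEmphasis"] == pytest.approx(
            5.0, abs=1e-10)

    def test_constant_row_single_run(self):
        t = tx.rlm(grey_from_slices([[1] * 5], L=2), "angle0", 1)
        assert t.n_r == 1
        assert t.counts[1, 4] == 1

    def test_stride_subsamples_the_lattice(self):
        # stride 4 on a row of five equal voxels: lattice points 0 and 4
        # form a single run of length 2
        t = tx.rlm(grey_from_slices([[2, 2, 2, 2, 2]], L=4), "angle0", 4)
        assert t.n_r == 1
        assert t.counts[2, 1] == 1

    def test_level_zero_rejected(self):
        t = tx.rlm(grey_from_slices([[0, 1]], L=2), "angle0", 1)
        with pytest.raises(ValueError, match="grey level 0"):
            tx.rlm_feature_set(t)

    def test_emphasis_bounds(self, rng):
        for _ in range(10):
            arr = rng.integers(1, 6, size=(7, 7, 2))
            mask = ROIMask(rng.random((7, 7, 2)) < 0.8)
            g = tx.GreyVolume(arr.astype(np.int32), L=7, mask=mask)
            fs = tx.rlm_feature_set(tx.rlm(g, "angle135", 1))
            assert fs["HighGreyLevelRunEmphasis"] >= 1.0
            assert fs["LowGreyLevelRunEmphasis"] <= 1.0
            assert 0 < fs["RunPercentage"] <= 1.0


class TestBruteForceEquivalence:
    """GLCM/RLM match an independent pair/run enumerator exactly."""

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("direction", list(tx.DIRECTIONS))
    def test_glcm_counts_match(self, seed, direction):
        r = np.random.default_rng(seed)
        L = int(r.integers(2, 9))
        arr = r.integers(0, L, size=(8, 8, 3)).astype(np.int32)
        mask = r.random((8, 8, 3)) < 0.8
        g = tx.GreyVolume(arr, L=L, mask=ROIMask(mask))
        offset = int(r.choice([1, 4, 7]))
        brute = brute_glcm_counts(arr, mask, L, direction, offset)
        if brute.sum() == 0:
            with pytest.raises(tx.NoPairsError):
                tx.glcm(g, direction, offset)
            return
        m = tx.glcm(g, direction, offset)
        np.testing.assert_array_equal(m.g, brute / brute.sum())

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("direction", list(tx.DIRECTIONS))
    def test_rlm_runs_match(self, seed, direction):
        r = np.random.default_rng(100 + seed)
        L = int(r.integers(2, 9))
        arr = r.integers(1, L + 1, size=(8, 8, 3)).astype(np.int32)
        mask = r.random((8, 8, 3)) < 0.8
        step = int(r.choice([1, 4, 7]))
        brute = brute_rlm_counts(arr, mask, direction, step)
        g = tx.GreyVolume(arr, L=L + 1, mask=ROIMask(mask))
        t = tx.rlm(g, direction, step)
        assert t.n_r == sum(brute.values())
        for (grey, length), n in brute.items():
            assert t.counts[grey, length - 1] == n
        assert t.counts.sum() == sum(brute.values())


class TestDirectionVariants:
    def test_mean_and_sd_arithmetic(self):
        out = tx.direction_variants({"angle0": 0.2, "angle45": 0.2,
                                     "angle90": 0.3, "angle135": 0.3})
        assert out["AllDirection"] == pytest.approx(0.25)
        assert out["AllDirection_SD"] == pytest.approx(0.05)

    def test_isotropic_constant_sd_zero(self):
        g = grey_from_slices(np.zeros((5, 5), dtype=int), L=2)
        per_dir = {d: tx.glcm_energy(tx.glcm(g, d, 1)) for d in tx.DIRECTIONS}
        assert tx.direction_variants(per_dir)["AllDirection_SD"] == 0.0

    def test_striped_texture_has_nonzero_sd(self):
        stripes = np.tile(np.array([[0], [1]]), (3, 6))
        g = grey_from_slices(stripes, L=2)
        per_dir = {d: tx.glcm_feature_set(tx.glcm(g, d, 1))["GLCMContrast"]
                   for d in tx.DIRECTIONS}
        assert tx.direction_variants(per_dir)["AllDirection_SD"] > 0

    def test_rotation_swaps_angles_and_preserves_mean(self, rng):
        arr = rng.integers(0, 6, size=(9, 9, 1)).astype(np.int32)
        rot = np.rot90(arr, axes=(0, 1)).copy()
        for a, b in (("angle0", "angle90"), ("angle45", "angle135")):
            ga = tx.GreyVolume(arr, L=6, mask=ROIMask(np.ones_like(arr, bool)))
            gb = tx.GreyVolume(rot, L=6, mask=ROIMask(np.ones_like(rot, bool)))
            fa = tx.glcm_feature_set(tx.glcm(ga, a, 1))
            fb = tx.glcm_feature_set(tx.glcm(gb, b, 1))
            for k in fa:
                assert fa[k] == pytest.approx(fb[k], abs=1e-10)


class TestHistogram:
    def test_min_of_small_set(self):
        vals = np.array([3.0, 7.0, 9.0]).reshape(3, 1, 1)
        mask = ROIMask(np.ones((3, 1, 1), bool))
        fs = tx.histogram_features(VoxelGrid(vals), mask)
        assert fs["MinIntensity"] == 3.0
        assert fs["MaxIntensity"] == 9.0

    def test_constant_region_degenerate_statistics(self):
        vals = np.full((3, 3, 1), 4.0)
        fs = tx.histogram_features(VoxelGrid(vals), ROIMask(np.ones((3, 3, 1), bool)))
        assert fs["StandardDeviation"] == 0.0
        assert fs["Variance"] == 0.0
        assert fs["HistogramEntropy"] == 0.0
        assert fs["Skewness"] == 0.0
        assert fs["Uniformity"] == 1.0

    def test_median_linear_interpolation_convention(self):
        vals = np.arange(1.0, 101.0).reshape(100, 1, 1)
        fs = tx.histogram_features(VoxelGrid(vals), ROIMask(np.ones((100, 1, 1), bool)))
        assert fs["Percentile50"] == pytest.approx(50.5)
        assert fs["MedianIntensity"] == pytest.approx(50.5)


class TestShape:
    def test_cube_face_counting(self):
        m = np.zeros((14, 14, 14), dtype=bool)
        m[2:12, 2:12, 2:12] = True
        fs = tx.shape_features(ROIMask(m))
        assert fs["Volume"] == pytest.approx(1000.0)
        assert fs["SurfaceArea"] == pytest.approx(600.0)
        assert fs["Sphericity"] == pytest.approx(
            np.pi ** (1 / 3) * 6000 ** (2 / 3) / 600, abs=1e-10)
        assert fs["Sphericity"] == pytest.approx(0.806, abs=5e-4)
        assert fs["SphericalDisproportion"] == pytest.approx(1 / fs["Sphericity"])

    def test_sphere_rounder_than_elongated_box(self):
        # face-counted surface areas of digital spheres carry a staircase
        # inflation (~1.5x the smooth area), so the isoperimetric ordering
        # is asserted against a clearly elongated shape of similar volume
        idx = np.indices((24, 24, 24)).astype(float) + 0.5
        rho = np.sqrt(((idx - 12.0) ** 2).sum(axis=0))
        sphere = tx.shape_features(ROIMask(rho <= 10.0))
        slab = np.zeros((80, 24, 8), dtype=bool)
        slab[4:76, 4:20, 2:6] = True
        assert sphere["Sphericity"] > tx.shape_features(ROIMask(slab))["Sphericity"]

    def test_elongation_of_anisotropic_box(self):
        m = np.zeros((20, 10, 10), dtype=bool)
        m[2:18, 3:7, 3:7] = True
        fs = tx.shape_features(ROIMask(m))
        assert fs["Elongation"] < 1.0


class TestCatalogAndExtraction:
    def test_catalog_has_396_unique_names(self):
        cat = tx.build_catalog()
        assert len(cat) == 396
        assert len(set(cat)) == 396

    def test_catalog_contains_the_published_feature_names(self):
        cat = set(tx.build_catalog())
        required = [
            "GLCMEnergy_AllDirection_offset1_SD",
            "GLCMEntropy_angle0_offset4",
            "HighGreyLevelRunEmphasis_AllDirection_offset1_SD",
            "LowGreyLevelRunEmphasis_AllDirection_offset1_SD",
            "ShortRunHighGreyLevelEmphasis_AllDirection_offset4_SD",
            "GLCMEntropy_AllDirection_offset1_SD",
            "MinIntensity",
            "HighGreyLevelRunEmphasis_AllDirection_offset4_SD",
        ]
        assert cat.issuperset(required)

    def test_family_counts_sum_to_396(self):
        assert 42 + 9 + 21 + 126 + 198 == 396
        assert len(tx.HISTOGRAM_NAMES) == 42
        assert len(tx.SHAPE_NAMES) == 9

    def test_extract_all_deterministic_and_complete(self, rng):
        vals = rng.uniform(0, 255, size=(16, 16, 8)).round()
        idx = np.indices((16, 16, 8)).astype(float) + 0.5
        mask = ROIMask(np.sqrt((((idx.T - [8, 8, 4]).T) ** 2).sum(axis=0)) <= 6)
        vol = VoxelGrid(vals)
        v1 = tx.extract_all(vol, mask)
        v2 = tx.extract_all(vol, mask)
        assert len(v1) == 396
        assert list(v1.index) == tx.build_catalog()
        assert not v1.isna().any()
        pd.testing.assert_series_equal(v1, v2)


class TestMonotoneHeterogeneity:
    def test_entropy_increases_with_planted_texture_amplitude(self):
        """Mean GLCM entropy rises with the planted heterogeneity sd."""
        from dataclasses import replace
        from scipy import stats as sps
        from radstage.synthetic import PhantomSpec, generate_cohort
        from radstage.preprocessing import normalize_grey

        sds = np.round(np.linspace(0.0, 0.30, 7), 3)
        means = []
        for sd in sds:
            spec = PhantomSpec(
                n_subjects=6, seed=11,
                grid_shape=(40, 40, 40),
                lesion_radius_mm={"early": (8.0, 0.5), "advanced": (8.0, 0.5)},
                heterogeneity_sd={"early": float(sd), "advanced": float(sd)},
                heterogeneity_volume_coupling=0.0)
            ents = []
            for rec in generate_cohort(spec):
                vol = normalize_grey(rec.pet_volume)
                grey = tx.discretize(vol, rec.lesion_mask, 32)
                ents.append(tx.glcm_entropy(tx.glcm(grey, "angle0", 1)))
            means.append(np.mean(ents))
        rho, p = sps.spearmanr(sds, means)
        assert rho > 0 and p < 0.01
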