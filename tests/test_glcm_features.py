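"""Co-occurrence construction, marginals, the 19 descriptors, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from renotex import (
    ANGLES_DEG,
    FEATURE_NAMES,
    FeatureConfig,
    FeatureVector19,
    OffsetSpec,
    PreprocessConfig,
    ROISpec,
    average_over_angles,
    build_glcm,
    compute_features,
    compute_marginals,
    compute_roi_features,
    extract_roi_features,
    quantize,
)
from renotex.glcm_features import NoPairsError

from _oracles import brute_features, brute_glcm

# the worked 4x4 two-by-two block image: six co-occurring pairs, each p = 1/6
BLOCK_IMAGE = np.array(
    [[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]]
) * 60
CFG4 = FeatureConfig(n_levels=4)


def _block_glcm(symmetric=False):
    return build_glcm(quantize(BLOCK_IMAGE, CFG4), OffsetSpec(0), symmetric=symmetric)


class TestQuantize:
    def test_constant_image_maps_to_level_one(self):
        q = quantize(np.full((5, 5), 200), FeatureConfig(n_levels=8))
        assert np.array_equal(q.levels, np.ones((5, 5)))

    def test_full_range_binning_is_floor_div_32(self):
        img = np.arange(256).reshape(16, 16)
        q = quantize(img, FeatureConfig(n_levels=8, gray_limits="full_range"))
        assert np.array_equal(q.levels, img // 32 + 1)

    def test_requantizing_a_full_span_level_raster_is_identity(self, rng):
        n = 8
        raster = rng.integers(1, n + 1, size=(10, 10))
        raster[0, 0], raster[0, 1] = 1, n  # make both extremes present
        q = quantize(raster, FeatureConfig(n_levels=n))
        assert np.array_equal(q.levels, raster)

    def test_minmax_stretches_narrow_range(self):
        img = np.array([[100, 101], [102, 103]])
        q = quantize(img, FeatureConfig(n_levels=4))
        assert np.array_equal(q.levels, [[1, 2], [3, 4]])


class TestBuildGlcm:
    def test_worked_example_six_equal_cells(self):
        g = _block_glcm()
        nz = {(i + 1, j + 1): v for (i, j), v in np.ndenumerate(g.p) if v > 0}
        assert set(nz) == {(1, 1), (1, 2), (2, 2), (3, 3), (3, 4), (4, 4)}
        assert all(abs(v - 1 / 6) < 1e-12 for v in nz.values())

    def test_constant_image_single_cell(self):
        q = quantize(np.full((4, 4), 9), CFG4)
        g = build_glcm(q, OffsetSpec(45), symmetric=True)
        assert g.p[0, 0] == 1.0 and g.p.sum() == 1.0

    def test_checkerboard_off_diagonal_half_each(self):
        img = (np.indices((6, 6)).sum(axis=0) % 2) * 255
        g = build_glcm(quantize(img, FeatureConfig(n_levels=2)), OffsetSpec(0), symmetric=False)
        assert g.p[0, 1] == pytest.approx(0.5) and g.p[1, 0] == pytest.approx(0.5)

    def test_symmetric_mode_equals_transpose(self, rng):
        q = quantize(rng.integers(0, 256, (8, 8)), FeatureConfig(n_levels=4))
        for angle in ANGLES_DEG:
            g = build_glcm(q, OffsetSpec(angle), symmetric=True)
            assert np.allclose(g.p, g.p.T)

    def test_no_pairs_raises(self):
        q = quantize(np.array([[5]]), CFG4)
        with pytest.raises(NoPairsError):
            build_glcm(q, OffsetSpec(0))

    def test_matches_skimage_reference(self, rng):
        """Dual-route check against scikit-image's co-occurrence counter."""
        from skimage.feature import graycomatrix

        img = rng.integers(0, 4, size=(12, 12)).astype(np.uint8)
        q = quantize(img * 85, FeatureConfig(n_levels=4, gray_limits="full_range"))
        # skimage measures angles with row offsets growing downward, so its
        # 45 deg equals our 135 deg (and vice versa) once symmetrized
        ref = graycomatrix(img, [1], np.deg2rad(ANGLES_DEG), levels=4, symmetric=True)
        for ours, theirs in ((0, 0), (45, 3), (90, 2), (135, 1)):
            g = build_glcm(q, OffsetSpec(ours), symmetric=True)
            assert np.array_equal(g.counts, ref[:, :, 0, theirs])


class TestMarginals:
    def test_worked_example_marginals(self):
        m = compute_marginals(_block_glcm(), CFG4)
        assert np.allclose(m.px, [1 / 3, 1 / 6, 1 / 3, 1 / 6])
        assert np.allclose(m.py, [1 / 6, 1 / 3, 1 / 6, 1 / 3])
        nz_sum = {k for k, v in enumerate(m.px_plus_y) if v > 0}
        assert nz_sum == {2, 3, 4, 6, 7, 8}
        assert np.allclose(m.px_plus_y[sorted(nz_sum)], 1 / 6)
        assert np.allclose(m.px_minus_y, [4 / 6, 2 / 6, 0, 0])

    def test_uniform_marginal_entropy_is_log_n(self):
        # constant rows: each row level co-occurs only with itself at 0 deg
        img = np.repeat(np.arange(4), 4).reshape(4, 4) * 85
        g = build_glcm(quantize(img, CFG4), OffsetSpec(0), symmetric=False)
        m = compute_marginals(g, CFG4)
        assert m.hx == pytest.approx(math.log(4))

    def test_single_cell_degenerate_marginals(self):
        q = quantize(np.full((3, 3), 10), CFG4)
        m = compute_marginals(build_glcm(q, OffsetSpec(0)), CFG4)
        assert m.hxy == 0.0 and m.mu_x == 1.0 and m.mu_y == 1.0

    def test_log2_base_scales_entropies(self):
        g = _block_glcm()
        nat = compute_marginals(g, CFG4)
        two = compute_marginals(g, FeatureConfig(n_levels=4, log_base="log2"))
        assert two.hxy == pytest.approx(nat.hxy / math.log(2))


class TestComputeFeatures:
    def test_single_cell_trivial_vector(self):
        q = quantize(np.full((10, 10), 50), FeatureConfig())
        g = build_glcm(q, OffsetSpec(0))
        fv = compute_features(g, cfg=FeatureConfig())
        assert fv.energy == 1.0
        assert fv.entropy == 0.0
        assert fv.contrast == 0.0
        assert fv.dissimilarity == 0.0
        assert fv.homogeneity == 1.0
        assert fv.maximum_probability == 1.0
        assert fv.correlation == 0.0 and fv.imc1 == 0.0 and fv.imc2 == 0.0

    def test_single_cell_inverse_difference_by_dialect(self):
        # the printed inner sum starts at the second column, so the all-mass
        # cell (1, 1) is excluded under the as_printed dialect
        q = quantize(np.full((10, 10), 50), FeatureConfig())
        g = build_glcm(q, OffsetSpec(0))
        classical = compute_features(g, cfg=FeatureConfig(dialect="classical_haralick"))
        printed = compute_features(g, cfg=FeatureConfig(dialect="as_printed"))
        assert classical.inverse_difference == 1.0
        assert printed.inverse_difference == 0.0

    def test_worked_example_descriptors(self):
        fv = compute_features(_block_glcm(), cfg=CFG4)
        assert fv.contrast == pytest.approx(1 / 3, abs=1e-12)
        assert fv.energy == pytest.approx(1 / 6, abs=1e-12)
        assert fv.entropy == pytest.approx(math.log(6), abs=1e-12)
        assert fv.dissimilarity == pytest.approx(1 / 3, abs=1e-12)
        assert fv.homogeneity == pytest.approx(5 / 6, abs=1e-12)
        assert fv.sum_average == pytest.approx(5, abs=1e-12)
        assert fv.difference_entropy == pytest.approx(
            -(4 / 6) * math.log(4 / 6) - (2 / 6) * math.log(2 / 6), abs=1e-12
        )

    def test_checkerboard_closed_form(self):
        img = (np.indices((6, 6)).sum(axis=0) % 2) * 255
        g = build_glcm(quantize(img, FeatureConfig(n_levels=2)), OffsetSpec(0), symmetric=False)
        fv = compute_features(g, cfg=FeatureConfig(n_levels=2))
        assert fv.correlation == pytest.approx(-1.0, abs=1e-12)
        assert fv.contrast == pytest.approx(1.0, abs=1e-12)
        assert fv.energy == pytest.approx(0.5, abs=1e-12)

    def test_dialect_swaps_cluster_exponents(self):
        g = _block_glcm()
        printed = compute_features(g, cfg=CFG4)
        classical = compute_features(g, cfg=FeatureConfig(n_levels=4, dialect="classical_haralick"))
        assert printed.cluster_prominence == pytest.approx(classical.cluster_shade)
        assert printed.cluster_shade == pytest.approx(classical.cluster_prominence)


@settings(deadline=None, max_examples=60)
@given(
    img=arrays(np.uint8, st.tuples(st.integers(2, 6), st.integers(2, 6)),
               elements=st.integers(0, 255)),
    angle=st.sampled_from(ANGLES_DEG),
    n=st.integers(2, 4),
    symmetric=st.booleans(),
    dialect=st.sampled_from(["as_printed", "classical_haralick"]),
)
def test_descriptors_match_brute_force_oracle(img, angle, n, symmetric, dialect):
    """Every descriptor agrees with the loop-based oracle to 1e-10."""
    cfg = FeatureConfig(n_levels=n, symmetric=symmetric, dialect=dialect)
    q = quantize(img, cfg)
    try:
        g = build_glcm(q, OffsetSpec(angle), symmetric)
    except NoPairsError:
        return
    fv = compute_features(g, cfg=cfg).to_dict()
    p_ref = brute_glcm(q.levels.tolist(), *OffsetSpec(angle).displacement, symmetric)
    ref = brute_features(p_ref, n, dialect)
    for name in FEATURE_NAMES:
        assert fv[name] == pytest.approx(ref[name], abs=1e-10), name


@settings(deadline=None, max_examples=40)
@given(
    img=arrays(np.uint8, st.tuples(st.integers(3, 8), st.integers(3, 8)),
               elements=st.integers(0, 255)),
    angle=st.sampled_from(ANGLES_DEG),
    symmetric=st.booleans(),
)
def test_glcm_invariants(img, angle, symmetric):
    """Normalization, symmetry, entropy and boundedness invariants."""
    cfg = FeatureConfig(n_levels=4, symmetric=symmetric)
    g = build_glcm(quantize(img, cfg), OffsetSpec(angle), symmetric)
    m = compute_marginals(g, cfg)
    assert g.p.sum() == pytest.approx(1.0, abs=1e-12)
    for marg in (m.px, m.py, m.px_plus_y, m.px_minus_y):
        assert marg.sum() == pytest.approx(1.0, abs=1e-12)
    assert m.hxy1 >= m.hxy - 1e-12  # KL divergence nonnegativity
    fv = compute_features(g, m, cfg)
    assert 0 < fv.energy <= 1
    assert fv.entropy >= 0
    assert 0 < fv.homogeneity <= 1
    assert 0 < fv.maximum_probability <= 1
    assert -1 - 1e-12 <= fv.correlation <= 1 + 1e-12
    assert fv.contrast >= 0 and fv.dissimilarity >= 0
    assert fv.imc1 <= 1e-12  # printed formula is -KL / max entropy
    if symmetric:
        assert np.allclose(m.px, m.py)
        assert m.hx == pytest.approx(m.hy)
    # zero contrast iff all mass on the diagonal
    diagonal_mass = np.trace(g.p)
    assert (fv.contrast == 0) == (diagonal_mass == pytest.approx(1.0))


class TestAngleAveraging:
    def test_four_identical_vectors_average_to_themselves(self):
        fv = compute_features(_block_glcm(), cfg=CFG4)
        assert average_over_angles([fv] * 4).to_array() == pytest.approx(fv.to_array())

    def test_elementwise_mean(self):
        base = compute_features(_block_glcm(), cfg=CFG4).to_array()
        vecs = [FeatureVector19.from_array(base + k) for k in range(4)]
        assert average_over_angles(vecs).to_array() == pytest.approx(base + 1.5)

    @pytest.mark.parametrize("count", [0, 3, 5])
    def test_wrong_count_rejected(self, count):
        fv = compute_features(_block_glcm(), cfg=CFG4)
        with pytest.raises(ValueError):
            average_over_angles([fv] * count)

    def test_rotating_image_permutes_angles_and_preserves_average(self, rng):
        img = rng.integers(0, 256, size=(20, 20))
        cfg = FeatureConfig()

        def per_angle(image):
            q = quantize(image, cfg)
            return {
                a: compute_features(build_glcm(q, OffsetSpec(a), True), cfg=cfg).to_array()
                for a in ANGLES_DEG
            }

        orig = per_angle(img)
        rot = per_angle(np.rot90(img))
        for a, b in ((0, 90), (90, 0), (45, 135), (135, 45)):
            assert orig[a] == pytest.approx(rot[b], abs=1e-12)
        avg_orig = np.mean([orig[a] for a in ANGLES_DEG], axis=0)
        avg_rot = np.mean([rot[a] for a in ANGLES_DEG], axis=0)
        assert avg_orig == pytest.approx(avg_rot, abs=1e-12)


class TestExtractRoiFeatures:
    def test_constant_roi_with_preprocessing_off_gives_trivial_vector(self):
        img = np.full((60, 60), 150)
        roi = ROISpec("cortex", 5, 5, 50)
        pcfg = PreprocessConfig(equalize=False, range_filter=False)
        fv = extract_roi_features(img, roi, pcfg, FeatureConfig())
        assert fv.energy == 1.0 and fv.entropy == 0.0 and fv.homogeneity == 1.0

    def test_output_has_19_descriptors(self, small_records):
        rec = small_records[0]
        fv = extract_roi_features(rec.image, rec.rois["cortex"])
        assert fv.to_array().shape == (19,)

    def test_out_of_bounds_roi_rejected(self):
        img = np.zeros((40, 40), dtype=np.uint8)
        with pytest.raises(ValueError):
            extract_roi_features(img, ROISpec("cortex", 0, 0, 50))

    def test_deterministic(self, small_records):
        rec = small_records[-1]
        a = extract_roi_features(rec.image, rec.rois["boundary"]).to_array()
        b = extract_roi_features(rec.image, rec.rois["boundary"]).to_array()
        assert np.array_equal(a, b)

    def test_seeded_cortex_roi_regression_vector(self):
        """Frozen descriptor vector for one seeded synthetic cortex ROI."""
        from renotex import ClassLabel, default_profiles, generate_region_texture
        from renotex.preprocessing import preprocess_roi

        cortex = default_profiles()[ClassLabel.NORMAL].cortex
        roi = generate_region_texture(cortex, (50, 50), np.random.default_rng(424242))
        fv = compute_roi_features(preprocess_roi(roi), FeatureConfig())
        frozen = [
            15.033044564765, 2.365949604332, 0.542508919137, 6.802588198553,
            166.050081436109, 1.152238650562, 0.03729015561, 3.51367827044,
            0.539826181913, 0.070428987922, 2.587286489659, 7.383400666389,
            7.983196354306, 2.424672045544, 1.005861894227, 1.334086184651,
            -0.108815226997, 0.320317918727, 0.536303804466,
        ]
        assert fv.to_array() == pytest.approx(frozen, abs=5e-13)

    def test_compute_roi_features_matches_manual_angle_average(self, rng):
        img = rng.integers(0, 256, size=(50, 50))
        cfg = FeatureConfig()
        q = quantize(img, cfg)
        manual = average_over_angles(
            [compute_features(build_glcm(q, OffsetSpec(a), True), cfg=cfg) for a in ANGLES_DEG]
        )
        assert compute_roi_features(img, cfg).to_array() == pytest.approx(manual.to_array())
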