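"""Sum/difference images, Unser feature maps and the 64-layer bank.

The fast filtered implementation is held against a naive per-pixel oracle
that evaluates the disk-neighborhood statistics literally.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ki67hotspot import (
    FeatureStack,
    NeighborhoodSpec,
    RGBImage,
    ScalarPlane,
    build_feature_bank,
    fisher_rank,
    local_histograms,
    select_features,
    sum_difference_images,
    unser_feature_maps,
    DEFAULT_SELECTED_FEATURES,
)


def naive_unser_maps(plane, displacement, radius, features):
    """Literal per-pixel evaluation of the disk-neighborhood statistics."""
    pair = sum_difference_images(ScalarPlane(plane), displacement)
    S, D = pair.S.values, pair.D.values
    H, W = S.shape
    mask = NeighborhoodSpec(radius).mask
    n = mask.sum()
    Sp = np.pad(S, radius, mode="edge")
    Dp = np.pad(D, radius, mode="edge")
    out = {f: np.zeros((H, W)) for f in features}
    for r in range(H):
        for c in range(W):
            s = Sp[r:r + 2 * radius + 1, c:c + 2 * radius + 1][mask]
            d = Dp[r:r + 2 * radius + 1, c:c + 2 * radius + 1][mask]
            mu = s.sum() / (2 * n)
            for f in features:
                if f == 1:
                    v = mu
                elif f == 2:
                    v = 0.5 * (((s - 2 * mu) ** 2).sum() + (d ** 2).sum()) / n
                elif f == 3:
                    v = (s ** 2).sum() * (d ** 2).sum() / n ** 2
                elif f == 4:
                    v = 0.5 * (((s - 2 * mu) ** 2).sum() - (d ** 2).sum()) / n
                elif f == 5:
                    v = (d ** 2).sum() / n
                elif f == 6:
                    v = (1.0 / (1.0 + d ** 2)).sum() / n
                elif f == 7:
                    v = ((s - 2 * mu) ** 3).sum() / n
                else:
                    v = ((s - 2 * mu) ** 4).sum() / n
                out[f][r, c] = v
    return out


class TestSumDifferenceImages:
    def test_constant_plane(self):
        pair = sum_difference_images(ScalarPlane(np.full((8, 8), 5.0)), (3, 3))
        assert pair.S.values == pytest.approx(10.0)
        assert pair.D.values == pytest.approx(0.0)

    def test_hand_computed_two_by_two(self):
        pair = sum_difference_images(
            ScalarPlane(np.array([[1.0, 2.0], [3.0, 4.0]])), (0, 1))
        assert pair.S.values[:, 0] == pytest.approx([3.0, 7.0])
        assert pair.D.values[:, 0] == pytest.approx([-1.0, -1.0])

    def test_difference_antisymmetry_on_overlap(self, rng):
        f = rng.normal(size=(12, 12))
        fwd = sum_difference_images(ScalarPlane(f), (2, 1)).D.values
        bwd = sum_difference_images(ScalarPlane(f), (-2, -1)).D.values
        # D_{+d}(x) = f(x) − f(x+d) = −D_{−d}(x+d) on the interior overlap
        assert fwd[:-2, :-1] == pytest.approx(-bwd[2:, 1:])

    def test_oversized_displacement_rejected(self):
        with pytest.raises(ValueError):
            sum_difference_images(ScalarPlane(np.zeros((4, 4))), (4, 0))


class TestLocalHistograms:
    def test_constant_sum_gives_unit_mass(self):
        pair = sum_difference_images(ScalarPlane(np.full((4, 4), 5.0)), (1, 1))
        hist = local_histograms(pair, np.ones((4, 4), bool))
        assert hist.probs_sum == {10: 1.0}

    def test_counts_normalize_by_region_size(self):
        pair = sum_difference_images(ScalarPlane(np.zeros((2, 2))), (0, 1))
        pair.S.values[:] = [[2, 4], [2, 6]]
        hist = local_histograms(pair, np.ones((2, 2), bool))
        assert hist.probs_sum == {2: 0.5, 4: 0.25, 6: 0.25}

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_distributions_sum_to_one(self, seed):
        r = np.random.default_rng(seed)
        pair = sum_difference_images(ScalarPlane(r.integers(0, 50, (6, 6)) * 1.0),
                                     (1, 1))
        region = r.random((6, 6)) < 0.7
        if not region.any():
            region[0, 0] = True
        hist = local_histograms(pair, region)
        assert sum(hist.probs_sum.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(hist.probs_diff.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_region_rejected(self):
        pair = sum_difference_images(ScalarPlane(np.zeros((3, 3))), (1, 1))
        with pytest.raises(ValueError):
            local_histograms(pair, np.zeros((3, 3), bool))


class TestUnserFeatureMaps:
    def test_constant_input_feature_values(self):
        pair = sum_difference_images(ScalarPlane(np.full((16, 16), 7.0)), (3, 3))
        maps = unser_feature_maps(pair, NeighborhoodSpec(3))
        by_id = {m.feature_id: m.values.values for m in maps}
        assert by_id[1] == pytest.approx(7.0)
        for fid in (2, 3, 5, 7, 8):
            assert by_id[fid] == pytest.approx(0.0, abs=1e-9)
        assert by_id[6] == pytest.approx(1.0)

    def test_fast_equals_naive_oracle(self, rng):
        plane = rng.random((32, 32)) * 255
        pair = sum_difference_images(ScalarPlane(plane), (3, 3))
        fast = unser_feature_maps(pair, NeighborhoodSpec(3))
        naive = naive_unser_maps(plane, (3, 3), 3, list(range(1, 9)))
        for m in fast:
            ref = naive[m.feature_id]
            scale = np.maximum(np.abs(ref), 1e-6)
            rel = np.abs(m.values.values - ref) / scale
            assert rel.max() < 1e-9, f"feature {m.feature_id}"

    def test_translation_equivariance_interior(self, rng):
        plane = rng.random((40, 40)) * 100
        shifted = np.roll(plane, (5, 5), axis=(0, 1))
        spec = NeighborhoodSpec(3)
        a = unser_feature_maps(sum_difference_images(ScalarPlane(plane), (1, 1)),
                               spec, [2])[0].values.values
        b = unser_feature_maps(sum_difference_images(ScalarPlane(shifted), (1, 1)),
                               spec, [2])[0].values.values
        inner = slice(12, 28)
        assert np.roll(a, (5, 5), axis=(0, 1))[inner, inner] == pytest.approx(
            b[inner, inner])

    def test_brighter_constant_yields_larger_mean(self):
        spec = NeighborhoodSpec(2)
        lo = unser_feature_maps(
            sum_difference_images(ScalarPlane(np.full((8, 8), 10.0)), (1, 1)),
            spec, [1])[0]
        hi = unser_feature_maps(
            sum_difference_images(ScalarPlane(np.full((8, 8), 20.0)), (1, 1)),
            spec, [1])[0]
        assert (hi.values.values > lo.values.values).all()

    def test_unknown_feature_id_rejected(self):
        pair = sum_difference_images(ScalarPlane(np.zeros((8, 8))), (1, 1))
        with pytest.raises(ValueError):
            unser_feature_maps(pair, NeighborhoodSpec(2), [9])


class TestFeatureBank:
    def test_exactly_64_layers(self, rng):
        img = RGBImage(rng.integers(0, 256, (48, 48, 3)).astype(np.uint8))
        stack = build_feature_bank(img, radius=10)
        assert sorted(stack.maps) == list(range(1, 65))

    def test_layer_indexing_follows_channel_blocks(self):
        assert FeatureStack.layer_label(3) == ("R", 3)    # energy of R
        assert FeatureStack.layer_label(5) == ("R", 5)    # contrast of R
        assert FeatureStack.layer_label(25) == ("u+C", 1)
        assert FeatureStack.layer_label(63) == ("K", 7)   # cluster shade of K
        assert FeatureStack.layer_index("G", 3) == 11

    def test_constant_image_has_zero_variance_and_contrast(self):
        img = RGBImage(np.full((32, 32, 3), (120, 80, 40), dtype=np.uint8))
        stack = build_feature_bank(img, radius=4)
        for block in range(8):
            assert stack.maps[block * 8 + 2].values.values == pytest.approx(0, abs=1e-9)
            assert stack.maps[block * 8 + 5].values.values == pytest.approx(0, abs=1e-9)

    def test_default_selected_set_has_25_entries(self):
        assert len(DEFAULT_SELECTED_FEATURES) == 25
        assert all(1 <= i <= 64 for i in DEFAULT_SELECTED_FEATURES)

    def test_tiny_image_rejected(self):
        img = RGBImage(np.zeros((12, 12, 3), np.uint8))
        with pytest.raises(ValueError):
            build_feature_bank(img, radius=10)


class TestFisherRanking:
    def test_uninformative_feature_ranked_last_with_zero_score(self, rng):
        X = rng.normal(size=(20, 3))
        labels = np.array([0] * 10 + [1] * 10)
        X[:, 1] = 5.0                      # identical across classes
        X[labels == 1, 0] += 10.0          # strongly separating
        ranked, scores = fisher_rank(X, labels)
        assert scores[1] == 0.0
        assert ranked[-1] == 2
        assert ranked[0] == 1

    def test_textbook_score_value(self):
        a = np.array([[-1.0], [1.0], [0.0], [0.0]])
        b = a + 1.0
        X = np.vstack([a, b])
        labels = np.array([0] * 4 + [1] * 4)
        _, scores = fisher_rank(X, labels)
        # means 0 and 1, variances 0.5 each -> J = 1/(0.5+0.5) = 1
        assert scores[0] == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fisher_rank(np.zeros((4, 2)), np.zeros(4))

    def test_selection_is_prefix_of_ranking(self):
        ranked = np.arange(1, 65)
        assert select_features(ranked, 0) == ()
        assert select_features(ranked, 64) == tuple(range(1, 65))
        assert len(select_features(ranked, 25)) == 25
        with pytest.raises(ValueError):
            select_features(ranked, 65)
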