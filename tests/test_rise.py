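"""Stage 2: occlusion mask construction, saliency accumulation, seed rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spixseg.rise import (
    MaskSet,
    SeedMap,
    apply_healthy_override,
    generate_masks,
    rise_heatmap,
    seeds_from_heatmap,
)


@pytest.fixture(scope="module")
def small_masks():
    return generate_masks(K=500, cell_grid=4, keep_prob=0.5,
                          image_shape=(16, 16), rng_seed=9)


class TestGenerateMasks:
    def test_determinism(self, small_masks):
        again = generate_masks(K=500, cell_grid=4, keep_prob=0.5,
                               image_shape=(16, 16), rng_seed=9)
        np.testing.assert_array_equal(small_masks.masks, again.masks)

    def test_mean_matches_keep_prob(self, small_masks):
        # mean of K*H*W Bernoulli-derived soft values; tolerance 3 s.e. on
        # the K mask means (cells are the independent units: 16 per mask)
        means = small_masks.masks.mean(axis=(1, 2))
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 0.5) < 3 * se + 1e-3

    def test_values_in_unit_interval(self, small_masks):
        assert small_masks.masks.min() >= 0 and small_masks.masks.max() <= 1

    @pytest.mark.parametrize("bad", [0.0, 1.0])
    def test_degenerate_keep_prob_errors(self, bad):
        with pytest.raises(ValueError, match="keep_prob"):
            generate_masks(K=4, keep_prob=bad, image_shape=(16, 16))

    def test_nonpositive_k_errors(self):
        with pytest.raises(ValueError, match="K"):
            generate_masks(K=0, image_shape=(16, 16))


class TestRiseHeatmap:
    def test_constant_zero_classifier_gives_zero_heatmap(self, small_masks, rng):
        img = rng.random((4, 16, 16)).astype(np.float32)
        heat = rise_heatmap(None, img, small_masks,
                            score_fn=lambda b: np.zeros(len(b)))
        np.testing.assert_array_equal(heat, 0.0)

    def test_constant_classifier_closed_form(self, small_masks, rng):
        """Score c for every mask gives exactly c * (sum_i mask_i) / (K p)."""
        img = rng.random((4, 16, 16)).astype(np.float32)
        c = 0.7
        heat = rise_heatmap(None, img, small_masks,
                            score_fn=lambda b: np.full(len(b), c))
        K, p = len(small_masks.masks), small_masks.keep_prob
        expect = c * small_masks.masks.astype(np.float64).sum(axis=0) / (K * p)
        np.testing.assert_allclose(heat, expect, atol=1e-10)

    def test_box_mean_classifier_localises_box(self):
        """An analytic scorer (mean intensity inside a known box) must put the
        heatmap argmax inside that box."""
        masks = generate_masks(K=2000, cell_grid=4, keep_prob=0.5,
                               image_shape=(16, 16), rng_seed=2)
        img = np.zeros((4, 16, 16), dtype=np.float32)
        box = np.s_[4:9, 6:11]
        img[:, box[0], box[1]] = 1.0

        def score(batch):
            return batch[:, 0, box[0], box[1]].mean(axis=(1, 2))

        heat = rise_heatmap(None, img, masks, score_fn=score)
        iy, ix = np.unravel_index(np.argmax(heat), heat.shape)
        assert 4 <= iy < 9 and 6 <= ix < 11

    def test_linearity_in_the_scorer(self, small_masks, rng):
        """Heatmap of a*f + b equals a*heat(f) + b*heat(const 1)."""
        img = rng.random((4, 16, 16)).astype(np.float32)

        def f(batch):
            return batch[:, 3].mean(axis=(1, 2))

        h_f = rise_heatmap(None, img, small_masks, score_fn=f)
        h_1 = rise_heatmap(None, img, small_masks,
                           score_fn=lambda b: np.ones(len(b)))
        h_aff = rise_heatmap(None, img, small_masks,
                             score_fn=lambda b: 2.0 * f(b) + 0.3)
        np.testing.assert_allclose(h_aff, 2.0 * h_f + 0.3 * h_1, atol=1e-9)

    def test_shape_mismatch_errors(self, small_masks, rng):
        img = rng.random((4, 8, 8)).astype(np.float32)
        with pytest.raises(ValueError, match="does not match"):
            rise_heatmap(None, img, small_masks, score_fn=lambda b: np.ones(len(b)))


class TestSeedsFromHeatmap:
    def test_exact_counts_on_128(self, rng):
        heat = rng.permutation(128 * 128).reshape(128, 128).astype(float)
        seeds = seeds_from_heatmap(heat, quantile=0.2)
        assert seeds.positive.sum() == 3277  # round(0.2 * 16384)
        assert seeds.negative.sum() == 3277
        assert not (seeds.positive & seeds.negative).any()

    def test_increasing_raster_order(self):
        heat = np.arange(100, dtype=float).reshape(10, 10)
        seeds = seeds_from_heatmap(heat, quantile=0.2)
        flat_pos = seeds.positive.ravel()
        flat_neg = seeds.negative.ravel()
        assert flat_neg[:20].all() and not flat_neg[20:].any()
        assert flat_pos[80:].all() and not flat_pos[:80].any()

    def test_constant_heatmap_raster_tiebreak(self):
        seeds = seeds_from_heatmap(np.ones((10, 10)), quantile=0.2)
        # ties resolve in raster order: negatives first 20 pixels,
        # positives last 20 pixels, deterministic
        assert seeds.negative.ravel()[:20].all()
        assert seeds.positive.ravel()[80:].all()
        assert seeds.positive.sum() == seeds.negative.sum() == 20

    def test_rank_invariance_under_monotone_transform(self, rng):
        heat = rng.random((12, 12))
        a = seeds_from_heatmap(heat)
        b = seeds_from_heatmap(np.exp(3.0 * heat))  # strictly monotone
        np.testing.assert_array_equal(a.positive, b.positive)
        np.testing.assert_array_equal(a.negative, b.negative)

    def test_tiny_heatmap_errors(self):
        with pytest.raises(ValueError, match="too small"):
            seeds_from_heatmap(np.ones((3, 3)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_seed_maps_always_disjoint(self, seed):
        heat = np.random.default_rng(seed).random((11, 13))
        seeds = seeds_from_heatmap(heat)
        assert not (seeds.positive & seeds.negative).any()
        assert seeds.positive.sum() + seeds.negative.sum() <= heat.size


class TestHealthyOverride:
    def _seeds(self):
        heat = np.arange(144, dtype=float).reshape(12, 12)
        return seeds_from_heatmap(heat)

    def test_healthy_prediction_makes_all_negative(self):
        out = apply_healthy_override(self._seeds(), predicted_label=0)
        assert out.negative.all() and not out.positive.any()

    def test_tumor_prediction_is_identity(self):
        seeds = self._seeds()
        out = apply_healthy_override(seeds, predicted_label=1)
        np.testing.assert_array_equal(out.positive, seeds.positive)

    def test_idempotent(self):
        once = apply_healthy_override(self._seeds(), 0)
        twice = apply_healthy_override(once, 0)
        np.testing.assert_array_equal(once.negative, twice.negative)

    def test_bad_label_errors(self):
        with pytest.raises(ValueError):
            apply_healthy_override(self._seeds(), 2)


def test_seedmap_rejects_overlap():
    with pytest.raises(ValueError, match="disjoint"):
        SeedMap(positive=np.ones((4, 4)), negative=np.ones((4, 4)))


def test_heatmap_on_trained_classifier_is_deterministic(tiny_classifier,
                                                        tiny_phantom_val,
                                                        small_masks):
    s = tiny_phantom_val[0]
    h1 = rise_heatmap(tiny_classifier, s, small_masks)
    h2 = rise_heatmap(tiny_classifier, s, small_masks)
    np.testing.assert_array_equal(h1, h2)
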