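"""Objective terms: moment algebra, closed-form loss values, differentiability.

The closed-form expectations are computed inside the tests from first
principles (centroid geometry, constant-probability logs), independent of the
implementation's tensor path.
"""

import numpy as np
import pytest

from spixseg import nn
from spixseg.losses import (
    LossConfig,
    combined_loss,
    seed_loss,
    soft_cluster,
    spixel_loss,
    spixel_loss_terms,
    superpixel_moments,
)
from spixseg.rise import SeedMap


def _one_hot_halves(h, w, n_s=2):
    """Hard associations: superpixel 0 = left half, 1 = right half."""
    q = np.zeros((1, n_s, h, w), dtype=np.float64)
    q[0, 0, :, : w // 2] = 1.0
    q[0, 1, :, w // 2 :] = 1.0
    return q


class TestSuperpixelMoments:
    def test_uniform_q_constant_image(self):
        q = np.full((1, 4, 6, 6), 0.25)
        img = np.full((1, 4, 6, 6), 0.7)
        m = superpixel_moments(img, q)
        np.testing.assert_allclose(m.u.data, 0.7, atol=1e-12)

    def test_one_hot_halves_centroids(self):
        h, w = 6, 8
        q = _one_hot_halves(h, w)
        img = np.zeros((1, 4, h, w))
        m = superpixel_moments(img, q)
        # left half columns 0..3: centroid col = 1.5; rows 0..5: row = 2.5
        np.testing.assert_allclose(m.l.data[0, 0], [2.5, 1.5], atol=1e-9)
        np.testing.assert_allclose(m.l.data[0, 1], [2.5, 5.5], atol=1e-9)

    def test_mass_conserved(self, rng):
        q = nn.Tensor(rng.random((2, 8, 6, 6))).softmax(axis=1)
        img = rng.random((2, 4, 6, 6))
        m = superpixel_moments(img, q)
        np.testing.assert_allclose(m.mass.data.sum(axis=1), 36.0, atol=1e-4)


class TestSpixelLoss:
    def test_two_block_image_closed_form(self):
        """Hard q matching a piecewise-constant image: intensity term 0, total
        = m * mean within-block distance to centroid (computed directly)."""
        h, w = 8, 8
        q = _one_hot_halves(h, w)
        img = np.zeros((1, 4, h, w))
        img[0, :, :, : w // 2] = 0.2
        img[0, :, :, w // 2 :] = 0.9
        m_coef = 3.0 / 160.0
        intensity, position = spixel_loss_terms(img, q)
        assert intensity.item() == pytest.approx(0.0, abs=1e-9)
        # independent oracle: enumerate pixel distances to each half centroid
        yy, xx = np.mgrid[0:h, 0:w]
        expect = 0.0
        for half, cols in ((0, xx < w // 2), (1, xx >= w // 2)):
            cy, cx = yy[cols].mean(), xx[cols].mean()
            expect += np.sqrt((yy[cols] - cy) ** 2 + (xx[cols] - cx) ** 2).sum()
        assert position.item() == pytest.approx(expect, rel=1e-6)
        total = spixel_loss(img, q, m=m_coef)
        assert total.item() == pytest.approx(m_coef * expect, rel=1e-6)

    def test_constant_image_single_superpixel_zero_intensity(self):
        q = np.ones((1, 1, 6, 6))
        img = np.full((1, 4, 6, 6), 0.4)
        intensity, _ = spixel_loss_terms(img, q)
        assert intensity.item() == pytest.approx(0.0, abs=1e-9)

    def test_nonnegative_and_linear_in_m(self, rng):
        q = nn.Tensor(rng.random((1, 6, 8, 8))).softmax(axis=1)
        img = np.full((1, 4, 8, 8), 0.5)  # constant -> pure position term
        l1 = spixel_loss(img, q, m=0.01).item()
        l2 = spixel_loss(img, q, m=0.02).item()
        assert l1 >= 0
        assert l2 == pytest.approx(2 * l1, rel=1e-5)


class TestSeedLoss:
    def _seeds(self, h=8, w=8):
        pos = np.zeros((h, w), dtype=bool)
        neg = np.zeros((h, w), dtype=bool)
        pos[:2], neg[-2:] = True, True
        return SeedMap(positive=pos, negative=neg)

    def test_perfect_heatmap_zero_loss(self):
        seeds = self._seeds()
        h = np.zeros((8, 8))
        h[seeds.positive] = 1.0
        assert seed_loss(h[None], [seeds]).item() == pytest.approx(0.0, abs=1e-6)

    def test_constant_half_heatmap_ln2(self):
        h = np.full((1, 8, 8), 0.5)
        assert seed_loss(h, [self._seeds()]).item() == pytest.approx(
            np.log(2), abs=1e-6
        )

    def test_healthy_override_with_zero_heatmap(self):
        all_neg = SeedMap(positive=np.zeros((8, 8), bool),
                          negative=np.ones((8, 8), bool))
        h = np.zeros((1, 8, 8))
        assert seed_loss(h, [all_neg]).item() == pytest.approx(0.0, abs=1e-6)

    def test_empty_seeds_warn_and_zero(self):
        empty = SeedMap(positive=np.zeros((8, 8), bool),
                        negative=np.zeros((8, 8), bool))
        with pytest.warns(UserWarning, match="no seeds"):
            assert seed_loss(np.full((1, 8, 8), 0.3), [empty]).item() == 0.0


class TestCombinedLoss:
    def _setup(self, rng):
        q = nn.Tensor(rng.random((1, 6, 8, 8)).astype(np.float64)).softmax(axis=1)
        r = nn.Tensor(rng.random((1, 6)).astype(np.float64)).softmax(axis=1)
        img = rng.random((1, 4, 8, 8))
        pos = np.zeros((8, 8), bool)
        neg = np.zeros((8, 8), bool)
        pos[:3, :3], neg[5:, 5:] = True, True
        return img, q, r, [SeedMap(positive=pos, negative=neg)]

    def test_alpha_zero_equals_spixel(self, rng):
        img, q, r, seeds = self._setup(rng)
        cfg = LossConfig(alpha=0.0)
        assert combined_loss(img, q, r, seeds, cfg).item() == pytest.approx(
            spixel_loss(img, q, cfg.m).item(), rel=1e-9
        )

    def test_seed_contribution_linear_in_alpha(self, rng):
        img, q, r, seeds = self._setup(rng)
        l0 = combined_loss(img, q, r, seeds, LossConfig(alpha=0.0)).item()
        l1 = combined_loss(img, q, r, seeds, LossConfig(alpha=50.0)).item()
        l2 = combined_loss(img, q, r, seeds, LossConfig(alpha=100.0)).item()
        assert l2 - l0 == pytest.approx(2 * (l1 - l0), rel=1e-6)

    def test_default_weight_is_fifty(self):
        assert LossConfig().alpha == 50.0

    def test_finite_and_nonnegative(self, rng):
        img, q, r, seeds = self._setup(rng)
        val = combined_loss(img, q, r, seeds).item()
        assert np.isfinite(val) and val >= 0


def test_gradients_match_finite_differences(rng):
    """End-to-end autodiff gradient through q and r logits vs central
    differences on an 8×8 toy input (float64, tolerance 1e-3)."""
    img = rng.random((1, 4, 8, 8))
    pos = np.zeros((8, 8), bool)
    neg = np.zeros((8, 8), bool)
    pos[:2, :2], neg[6:, 6:] = True, True
    seeds = [SeedMap(positive=pos, negative=neg)]
    q_logits = rng.normal(size=(1, 5, 8, 8))
    r_logits = rng.normal(size=(1, 5))

    def loss_of(ql, rl):
        q = nn.Tensor(ql).softmax(axis=1) if not isinstance(ql, nn.Tensor) else ql
        r = nn.Tensor(rl).softmax(axis=1) if not isinstance(rl, nn.Tensor) else rl
        return combined_loss(img, q, r, seeds)

    qt = nn.Tensor(q_logits.copy(), requires_grad=True)
    rt = nn.Tensor(r_logits.copy(), requires_grad=True)
    loss = loss_of(qt.softmax(axis=1), rt.softmax(axis=1))
    loss.backward()

    probe = np.random.default_rng(0)
    eps = 1e-6
    for tensor, base in ((qt, q_logits), (rt, r_logits)):
        flat = base.ravel()
        for i in probe.choice(base.size, size=min(8, base.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            fp = loss_of(q_logits, r_logits).item()
            flat[i] = orig - eps
            fm = loss_of(q_logits, r_logits).item()
            flat[i] = orig
            num = (fp - fm) / (2 * eps)
            assert abs(num - tensor.grad.ravel()[i]) < 1e-3


def test_one_optimizer_step_decreases_loss(rng):
    """Descent smoke test: a small Adam step on generator+clusterer params
    strictly decreases the combined loss on a fixed toy batch."""
    from spixseg.models import SuperpixelClusterer, SuperpixelGenerator

    nn.seed(2)
    gen = SuperpixelGenerator(n_superpixels=8, base_channels=4)
    clu = SuperpixelClusterer(n_superpixels=8)
    x = nn.Tensor(rng.random((2, 4, 8, 8)).astype(np.float32))
    pos = np.zeros((8, 8), bool)
    neg = np.zeros((8, 8), bool)
    pos[2:5, 2:5], neg[0, :] = True, True
    seeds = [SeedMap(positive=pos, negative=neg)] * 2
    opt = nn.Adam(gen.parameters() + clu.parameters(), lr=1e-4, weight_decay=0.0)

    def forward():
        q = gen(x)
        r = clu(x, q)
        return combined_loss(x, q, r, seeds)

    gen.train(), clu.train()
    before = forward()
    opt.zero_grad()
    before.backward()
    opt.step()
    after = forward()
    assert after.item() < before.item()


def test_soft_cluster_matches_manual_sum(rng):
    q = nn.Tensor(rng.random((2, 6, 5, 5))).softmax(axis=1)
    r = nn.Tensor(rng.random((2, 6))).softmax(axis=1)
    h = soft_cluster(q, r)
    manual = np.einsum("nshw,ns->nhw", q.data, r.data)
    np.testing.assert_allclose(h.data, manual, atol=1e-12)
    assert h.data.min() >= 0 and h.data.max() <= 1
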