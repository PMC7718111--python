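"""Saliency, Grad-CAM and the attention-supervision loss."""

import numpy as np
import pytest

from t1qc import autodiff as ad
from t1qc.autodiff import Tensor, backward
from t1qc.attention import (
    AttentionMap,
    attention_loss,
    attention_mass_fraction,
    classification_loss,
    combined_loss,
    grad_cam,
    grad_cam_map,
    saliency_map,
    supervised_attention_maps,
)
from t1qc.network import ModelInput
from t1qc.nn import Adam


def _model_input(rng, size=32):
    return ModelInput(
        t1_image=rng.random((size, size)).astype(np.float32),
        r2_image=rng.random((size, size)).astype(np.float32),
        irw_stack=rng.normal(size=(7, size, size)).astype(np.float32),
    )


def _calibrated_micro_net(config, rng, seed=5, n_warm=4):
    """Fresh micro classifier with batch-norm running statistics warmed on a
    few random batches, so evaluation-mode scores are not saturated."""
    from t1qc.network import build_classifier

    net = build_classifier(config, seed=seed)
    warm = [_model_input(rng, config.crop_size) for _ in range(4)]
    for _ in range(n_warm):
        net.forward(warm, training=True)
    net.fc.weight.data = net.fc.weight.data * 0.05  # keep sigmoid unsaturated
    return net


class TestSaliency:
    def test_matches_central_finite_differences(self, micro_config, rng):
        """Gradient-oracle check: ∂l/∂pixel against central differences at
        ≥10 probed pixels, 1e-3 relative tolerance."""
        with ad.use_dtype(np.float64):
            net = _calibrated_micro_net(micro_config, rng)
            mi = _model_input(rng)
            seg = 2
            am = saliency_map(net, mi, seg)
            assert am.map.shape == (32, 32)
            assert am.map.min() >= 0.0

            # analytic gradient of the R2 component (one addend of the map)
            t1 = Tensor(mi.t1_image[None, None, None])
            r2 = Tensor(mi.r2_image[None, None, None], requires_grad=True)
            irw = Tensor(mi.irw_stack[None, None])
            scores = net.forward_tensors(t1, r2, irw)
            onehot = np.zeros(6)
            onehot[seg - 1] = 1
            backward((scores * Tensor(onehot)).sum())
            grad = r2.grad[0, 0, 0].copy()
            net.zero_grad()

            eps = 1e-3
            checked = 0
            for _ in range(120):
                y, x = rng.integers(0, 32, size=2)

                def score_with(value):
                    r2p = mi.r2_image.astype(np.float64).copy()
                    r2p[y, x] = value
                    probe = ModelInput(mi.t1_image, r2p, mi.irw_stack)
                    return float(net.predict(probe)[seg - 1])

                base = float(mi.r2_image[y, x])
                fd = (score_with(base + eps) - score_with(base - eps)) / (2 * eps)
                fd_small = (score_with(base + eps / 8) - score_with(base - eps / 8)) / (eps / 4)
                if abs(fd) < 1e-6 or abs(fd - fd_small) > 1e-4 * abs(fd):
                    continue  # probe sits on a ReLU/pool kink: derivative jumps
                assert abs(grad[y, x] - fd) <= 1e-3 * abs(fd)
                checked += 1
                if checked >= 10:
                    break
            assert checked >= 10

    def test_zero_head_gives_zero_map(self, micro_net, rng):
        mi = _model_input(rng)
        saved = micro_net.fc.weight.data.copy()
        micro_net.fc.weight.data = np.zeros_like(saved)
        try:
            am = saliency_map(micro_net, mi, 1)
            assert np.all(am.map == 0.0)
        finally:
            micro_net.fc.weight.data = saved

    def test_segment_index_validated(self, micro_net, rng):
        with pytest.raises(ValueError):
            saliency_map(micro_net, _model_input(rng), 0)
        with pytest.raises(ValueError):
            saliency_map(micro_net, _model_input(rng), 7)


class TestGradCam:
    def test_closed_form_on_single_channel_stub(self, rng):
        """score = <G, A> gives dscore/dA = G, so the map must equal
        ReLU(mean(G) * A) exactly."""
        A = Tensor(rng.normal(size=(1, 1, 1, 5, 5)).astype(np.float32))
        G = rng.normal(size=(1, 1, 1, 5, 5)).astype(np.float32)
        backward((A * Tensor(G)).sum(), stop=(A,))
        cam = grad_cam_map(A.data[0, :, 0], A.grad[0, :, 0])
        oracle = np.maximum(G[0, 0, 0].mean() * A.data[0, 0, 0], 0.0).astype(np.float32)
        assert np.array_equal(cam, oracle)

    def test_all_negative_weighted_sum_is_muted(self):
        acts = np.ones((1, 3, 3), np.float32)
        grads = -np.ones((1, 3, 3), np.float32)
        assert np.all(grad_cam_map(acts, grads) == 0.0)

    def test_nonnegative_over_many_seeds(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            cam = grad_cam_map(
                r.normal(size=(4, 6, 6)).astype(np.float32),
                r.normal(size=(4, 6, 6)).astype(np.float32),
                out_size=12,
            )
            assert cam.min() >= 0.0

    def test_end_to_end_map_properties(self, micro_net, rng):
        mi = _model_input(rng)
        am, weights = grad_cam(micro_net, mi, 4)
        assert am.map.shape == (32, 32)
        assert am.map.min() >= 0.0
        assert weights.weights.shape == (micro_net.config.stage_channels[-1],)


class TestAttentionLoss:
    def _masks(self, size=8):
        masks = np.zeros((6, size, size), np.float32)
        for s in range(6):
            masks[s, s, :] = 1.0
        return masks

    def test_uniform_half_gives_ln2_per_segment(self):
        maps = [Tensor(np.full((1, 8, 8), 0.5, np.float32)) for _ in range(6)]
        loss = attention_loss(maps, self._masks())
        assert abs(loss.data / 6 - np.log(2)) < 1e-5

    def test_perfect_maps_give_near_zero_loss(self):
        masks = self._masks()
        maps = [Tensor(masks[s][None]) for s in range(6)]
        loss = attention_loss(maps, masks)
        assert float(loss.data) < 6 * 2e-5  # clamp floor only

    def test_two_by_two_pencil_and_paper_oracle(self):
        # map [[0.8, 0.2], [0.6, 0.4]], mask [[1, 0], [1, 0]]
        m = np.array([[0.8, 0.2], [0.6, 0.4]], np.float32)
        mask = np.array([[1.0, 0.0], [1.0, 0.0]], np.float32)
        expected = -(
            np.log(0.8) + np.log(1 - 0.2) + np.log(0.6) + np.log(1 - 0.4)
        ) / 4
        maps = [Tensor(m[None])] * 6
        masks = np.stack([mask] * 6)
        loss = attention_loss(maps, masks)
        assert abs(loss.data - 6 * expected) < 1e-5

    def test_maps_above_one_are_rescaled(self):
        # peak 4 -> divided by 4; uniform 4 becomes uniform 1
        maps = [Tensor(np.full((1, 4, 4), 4.0, np.float32))] * 6
        masks = np.ones((6, 4, 4), np.float32)
        loss = attention_loss(maps, masks)
        assert float(loss.data) < 6 * 2e-5

    def test_shape_mismatch_rejected(self):
        maps = [Tensor(np.zeros((1, 4, 4), np.float32))] * 6
        with pytest.raises(ValueError):
            attention_loss(maps, np.zeros((6, 8, 8), np.float32))

    def test_gradient_step_decreases_attention_loss(self, micro_net, rng):
        """Supervision must reach classifier parameters: one optimisation
        step on a fixed input strictly decreases L_att."""
        mi = _model_input(rng)
        masks = np.zeros((1, 6, 32, 32), np.float32)
        for s in range(6):
            masks[0, s, 4 * s : 4 * s + 4] = 1.0
        opt = Adam(micro_net.parameters(), lr=5e-3)

        def current_loss(update):
            scores, feats = micro_net.forward([mi], training=True, capture_features=True)
            maps = supervised_attention_maps(scores, feats, out_size=32)
            micro_net.zero_grad()
            loss = attention_loss(maps, masks)
            if update:
                backward(loss)
                opt.step()
                opt.zero_grad()
            return float(loss.data)

        before = current_loss(update=True)
        after = current_loss(update=False)
        assert after < before


class TestCombinedLoss:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_decomposition_is_exact(self, alpha, rng):
        scores = Tensor(rng.uniform(0.1, 0.9, size=(2, 6)).astype(np.float32))
        labels = rng.integers(0, 2, size=(2, 6))
        maps = [Tensor(rng.random((2, 8, 8)).astype(np.float32)) for _ in range(6)]
        masks = np.stack([np.stack([np.eye(8, dtype=np.float32)] * 6)] * 2)
        lv = combined_loss(scores, labels, maps, masks, alpha=alpha)
        assert lv.total == lv.l_att + alpha * lv.l_cl
        assert lv.l_att >= 0 and lv.l_cl >= 0

    def test_alpha_zero_reduces_to_attention_only(self, rng):
        scores = Tensor(rng.uniform(0.1, 0.9, size=(1, 6)).astype(np.float32))
        maps = [Tensor(rng.random((1, 8, 8)).astype(np.float32)) for _ in range(6)]
        masks = np.stack([np.eye(8, dtype=np.float32)] * 6)
        lv = combined_loss(scores, np.ones((1, 6)), maps, masks, alpha=0.0)
        assert lv.total == lv.l_att

    def test_joint_minimum_near_zero(self):
        masks = np.stack([np.eye(8, dtype=np.float32)] * 6)
        scores = Tensor(np.full((1, 6), 1.0 - 1e-7, np.float32))
        maps = [Tensor(masks[s][None]) for s in range(6)]
        lv = combined_loss(scores, np.ones((1, 6)), maps, masks, alpha=1.0)
        assert lv.total < 1e-3

    def test_negative_alpha_rejected(self, rng):
        scores = Tensor(np.full((1, 6), 0.5, np.float32))
        maps = [Tensor(np.zeros((1, 4, 4), np.float32))] * 6
        with pytest.raises(ValueError):
            combined_loss(scores, np.zeros((1, 6)), maps,
                          np.zeros((6, 4, 4), np.float32), alpha=-1.0)


class TestMassFraction:
    def test_mass_fraction_bounds_and_zero_map(self):
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        am = AttentionMap(map=np.ones((4, 4), np.float32), segment_index=1, method="grad_cam")
        assert attention_mass_fraction(am, mask) == pytest.approx(0.5)
        zero = AttentionMap(map=np.zeros((4, 4), np.float32), segment_index=1, method="grad_cam")
        assert attention_mass_fraction(zero, mask) == 0.0
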