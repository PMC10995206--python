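"""Localization-network losses (vs scalar reference implementations),
architecture contracts, and detection post-processing."""

import math

import numpy as np
import pytest

from ulmloc import nn
from ulmloc.decode import (DecodeModel, DecodeOutput, GmmTarget, build_network,
                           count_loss, decode_detections, gt_to_target, infer,
                           localization_loss, total_loss)

SIGMA_FLOOR = 0.01


def naive_count_loss(p, E, eps=1e-6):
    p = np.asarray(p, dtype=float).ravel()
    mu = float(sum(p))
    var = float(sum(pi * (1 - pi) for pi in p)) + eps
    return 0.5 * (E - mu) ** 2 / var + math.log(math.sqrt(2 * math.pi * var))


def naive_localization_loss(p, dx, dy, I, sx, sy, sI, gts):
    """Direct scalar-loop evaluation of the weighted-mixture likelihood."""
    h, w = np.asarray(p).shape
    total_p = float(np.sum(p))
    loss = 0.0
    for (gr, gc, gi) in gts:
        mix = 0.0
        for r in range(h):
            for c in range(w):
                wk = p[r, c] / total_p
                if wk == 0:
                    continue
                mr, mc, mi = r + dy[r, c], c + dx[r, c], I[r, c]
                quad = ((gr - mr) / sy[r, c]) ** 2 + \
                       ((gc - mc) / sx[r, c]) ** 2 + \
                       ((gi - mi) / sI[r, c]) ** 2
                norm = (2 * math.pi) ** 1.5 * sy[r, c] * sx[r, c] * sI[r, c]
                mix += wk * math.exp(-0.5 * quad) / norm
        loss -= math.log(mix)
    return loss / len(gts)


class TestCountLoss:
    def test_hand_case(self):
        assert float(count_loss(np.full(4, 0.5), 2).data) == pytest.approx(
            math.log(math.sqrt(2 * math.pi * (1 + 1e-6))), abs=1e-9)

    def test_saturated_probabilities_hit_floored_minimum(self):
        p = np.array([1.0, 0.0, 1.0, 0.0])
        base = float(count_loss(p, 2).data)
        assert base == pytest.approx(0.5 * math.log(2 * math.pi * 1e-6), abs=1e-9)
        assert np.isfinite(base)
        perturbed = float(count_loss(np.array([0.9, 0.1, 1.0, 0.0]), 2).data)
        assert base < perturbed

    def test_gradient_zero_at_exact_count(self):
        p = nn.Tensor(np.full(6, 0.5), requires_grad=True)
        loss = count_loss(p, 3)
        loss.backward()
        # d(quadratic)/d(mu) = 0 at mu = E; remaining gradient is the
        # variance term's, identical across pixels by symmetry
        quad_grad = p.grad - p.grad.mean()
        assert np.allclose(quad_grad, 0.0, atol=1e-12)

    def test_matches_naive_on_fuzz(self, rng):
        for _ in range(500):
            k = rng.integers(1, 30)
            p = rng.random(k)
            e = int(rng.integers(0, k + 1))
            assert float(count_loss(p, e).data) == pytest.approx(
                naive_count_loss(p, e), rel=1e-9, abs=1e-9)


class TestLocalizationLoss:
    def test_single_pixel_identity_covariance(self):
        t = GmmTarget(np.array([[0.3, -0.2, 1.5]]))
        loss = localization_loss(np.array([[1.0]]), np.array([[-0.2]]),
                                 np.array([[0.3]]), np.array([[1.5]]),
                                 np.array([[1.0]]), np.array([[1.0]]),
                                 np.array([[1.0]]), t)
        assert float(loss.data) == pytest.approx(1.5 * math.log(2 * math.pi),
                                                 abs=1e-9)

    def test_zero_weight_component_excluded(self):
        t = GmmTarget(np.array([[0.0, 0.0, 1.0]]))
        single = localization_loss(np.array([[1.0]]), np.array([[0.0]]),
                                   np.array([[0.0]]), np.array([[1.0]]),
                                   np.array([[1.0]]), np.array([[1.0]]),
                                   np.array([[1.0]]), t)
        two = localization_loss(np.array([[1.0, 0.0]]), np.zeros((1, 2)),
                                np.zeros((1, 2)), np.ones((1, 2)),
                                np.ones((1, 2)), np.ones((1, 2)),
                                np.ones((1, 2)), t)
        assert float(two.data) == pytest.approx(float(single.data), abs=1e-9)

    def test_all_zero_probability_raises(self):
        t = GmmTarget(np.array([[0.0, 0.0, 1.0]]))
        with pytest.raises(ValueError):
            localization_loss(np.zeros((2, 2)), np.zeros((2, 2)),
                              np.zeros((2, 2)), np.ones((2, 2)),
                              np.ones((2, 2)), np.ones((2, 2)),
                              np.ones((2, 2)), t)

    def test_matches_naive_on_fuzz(self, rng):
        for _ in range(100):
            h, w = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            p = rng.random((h, w)) + 1e-3
            dx = rng.uniform(-0.5, 0.5, (h, w))
            dy = rng.uniform(-0.5, 0.5, (h, w))
            ii = rng.random((h, w)) + 0.5
            sx = rng.random((h, w)) + 0.3
            sy = rng.random((h, w)) + 0.3
            si = rng.random((h, w)) + 0.3
            e = int(rng.integers(1, 4))
            gts = np.column_stack([rng.uniform(0, h - 1, e),
                                   rng.uniform(0, w - 1, e),
                                   rng.random(e) + 0.5])
            got = float(localization_loss(p, dx, dy, ii, sx, sy, si,
                                          GmmTarget(gts)).data)
            want = naive_localization_loss(p, dx, dy, ii, sx, sy, si, gts)
            assert got == pytest.approx(want, rel=1e-8, abs=1e-8)

    def test_minimized_at_ground_truth_mean(self):
        """Gradient of the single-component mixture vanishes at mu = GT."""
        t = GmmTarget(np.array([[0.25, -0.1, 1.2]]))
        dy = nn.Tensor(np.array([[0.25]]), requires_grad=True)
        dx = nn.Tensor(np.array([[-0.1]]), requires_grad=True)
        ii = nn.Tensor(np.array([[1.2]]), requires_grad=True)
        loss = localization_loss(np.array([[1.0]]), dx, dy, ii,
                                 np.array([[0.5]]), np.array([[0.5]]),
                                 np.array([[0.5]]), t)
        loss.backward()
        for g in (dy.grad, dx.grad, ii.grad):
            assert abs(g[0, 0]) < 1e-10


class TestTotalLoss:
    def test_empty_frame_uses_count_only(self):
        p = np.full((2, 2), 0.1)
        z = np.zeros((2, 2))
        o = np.ones((2, 2))
        t = GmmTarget(np.empty((0, 3)))
        assert float(total_loss(p, z, z, o, o, o, o, t).data) == pytest.approx(
            naive_count_loss(p, 0), abs=1e-9)

    def test_perfect_single_bubble_sum(self):
        t = GmmTarget(np.array([[0.0, 0.0, 1.0]]))
        o = np.ones((1, 1))
        z = np.zeros((1, 1))
        got = float(total_loss(o, z, z, o, o, o, o, t).data)
        want = naive_count_loss(np.ones(1), 1) + 1.5 * math.log(2 * math.pi)
        assert got == pytest.approx(want, abs=1e-9)

    def test_finite_on_random_inputs(self, rng):
        for _ in range(1000):
            h = w = 3
            p = rng.random((h, w))
            if p.sum() == 0:
                continue
            args = (p, rng.uniform(-0.5, 0.5, (h, w)),
                    rng.uniform(-0.5, 0.5, (h, w)), rng.random((h, w)),
                    rng.random((h, w)) + SIGMA_FLOOR,
                    rng.random((h, w)) + SIGMA_FLOOR,
                    rng.random((h, w)) + SIGMA_FLOOR)
            e = int(rng.integers(0, 4))
            gts = np.column_stack([rng.uniform(0, 2, e), rng.uniform(0, 2, e),
                                   rng.random(e)])
            assert np.isfinite(float(total_loss(*args, GmmTarget(gts)).data))


class TestNetwork:
    def test_output_shape_contract(self):
        model = build_network(base_filters=8, seed=0)
        raw = model.forward(np.zeros((2, 3, 40, 40), dtype=np.float32))
        assert raw.data.shape == (2, 40, 40, 9)

    def test_wrong_arity_rejected(self):
        model = build_network(base_filters=8)
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 4, 40, 40)))

    def test_default_parameter_count_regression(self):
        # declared widths 48/96/192 over two U-Nets and a 9-channel head
        assert build_network(48).n_parameters == 2183529
        assert build_network(48).n_parameters < 4_000_000

    def test_separate_frame_nets_supported(self):
        model = build_network(base_filters=4, share_frame_weights=False)
        assert len(model.frame_nets) == 3
        raw = model.forward(np.zeros((1, 3, 16, 16), dtype=np.float32))
        assert raw.data.shape == (1, 16, 16, 9)

    def test_channel_ranges(self, rng):
        model = build_network(base_filters=4, seed=1)
        ch = DecodeModel.split_raw(
            model.forward(rng.normal(size=(1, 3, 16, 16)).astype(np.float32)))
        assert np.all((ch["p"].data >= 0) & (ch["p"].data <= 1))
        assert np.all(np.abs(ch["dx"].data) < 0.5)
        assert np.all(np.abs(ch["dy"].data) < 0.5)
        for k in ("sigma_x", "sigma_y", "sigma_I"):
            assert np.all(ch[k].data >= SIGMA_FLOOR)
        assert np.all(ch["I_hat"].data >= 0)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = build_network(base_filters=4, seed=3)
        model.train_log = [2.5, 1.5]
        model.save(tmp_path / "model.npz")
        loaded = DecodeModel.load(tmp_path / "model.npz")
        x = rng.normal(size=(1, 3, 16, 16)).astype(np.float32)
        with nn.no_grad():
            assert np.array_equal(model.forward(x).data, loaded.forward(x).data)
        assert loaded.train_log == [2.5, 1.5]


class TestInference:
    def test_window_arithmetic(self):
        model = build_network(base_filters=4)
        outs = infer(model, np.zeros((3, 16, 16)))
        assert len(outs) == 1
        outs = infer(model, np.zeros((10, 16, 16)))
        assert len(outs) == 8
        with pytest.raises(ValueError):
            infer(model, np.zeros((2, 16, 16)))


def _blank_output(h=20, w=20):
    z = np.zeros((h, w))
    return DecodeOutput(p=z.copy(), dx=z.copy(), dy=z.copy(), I_hat=z.copy(),
                        sigma_x=np.ones((h, w)), sigma_y=np.ones((h, w)),
                        sigma_I=np.ones((h, w)), B=z.copy())


class TestDecodeDetections:
    def test_offset_arithmetic(self):
        out = _blank_output()
        out.p[10, 10] = 1.0
        out.dx[10, 10] = 0.3
        out.dy[10, 10] = -0.2
        locs = decode_detections(out)
        assert len(locs) == 1
        assert locs[0].row == pytest.approx(9.8)
        assert locs[0].col == pytest.approx(10.3)

    def test_adjacent_pixels_aggregate_to_one(self):
        out = _blank_output()
        out.p[5, 5] = 0.5
        out.p[5, 6] = 0.5
        locs = decode_detections(out, p_thresh=0.6)
        assert len(locs) == 1

    def test_below_threshold_dropped(self):
        out = _blank_output()
        out.p[5, 5] = 0.4
        assert decode_detections(out, p_thresh=0.6) == []

    def test_rejection_disabled_keeps_all(self):
        out = _blank_output()
        for k in range(5):
            out.p[3 + 4 * k, 3] = 1.0
            out.sigma_x[3 + 4 * k, 3] = k + 1.0
        all_locs = decode_detections(out, uncertainty_reject_frac=0.0)
        assert len(all_locs) == 5
        kept = decode_detections(out, uncertainty_reject_frac=0.2)
        assert len(kept) == 4
        assert max(l.sigma_col for l in kept) < 5.0


class TestTargetMapping:
    def test_fine_to_output_grid(self, cam_cfg):
        t = gt_to_target([(0, 40.7, 39.2, 1.0)], cam_cfg)
        assert t.coords[0, 0] == pytest.approx((40.7 - 0.5) / 2)
        assert t.coords[0, 1] == pytest.approx((39.2 - 0.5) / 2)
        assert t.E == 1
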