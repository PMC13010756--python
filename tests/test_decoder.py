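import numpy as np
import pytest

import gazedecode as gd
from gazedecode import nn
from gazedecode.decoder import (ConfigError, DegenerateDataError,
                                evaluate_accuracy, maps_to_batch)


def gaussian_blob_maps(n, side, size=32, rng=None, sigma=3.0):
    """Maps with mass in the left (side=0) or right (side=1) half."""
    rng = rng or np.random.default_rng(0)
    yy, xx = np.mgrid[0:size, 0:size]
    half = size // 2
    maps = np.empty((n, size, size), dtype=np.float32)
    xs = rng.integers(2, half - 2, n) + (half if side else 0)
    ys = rng.integers(2, size - 2, n)
    for i in range(n):
        maps[i] = np.exp(-((xx - xs[i]) ** 2 + (yy - ys[i]) ** 2)
                         / (2 * sigma ** 2))
    return maps


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(1)
    tx = np.concatenate([gaussian_blob_maps(250, 0, rng=rng),
                         gaussian_blob_maps(250, 1, rng=rng)])[:, None]
    ty = np.repeat([0, 1], 250)
    vx = np.concatenate([gaussian_blob_maps(100, 0, rng=rng),
                         gaussian_blob_maps(100, 1, rng=rng)])[:, None]
    vy = np.repeat([0, 1], 100)
    return tx, ty, vx, vy


@pytest.fixture(scope="module")
def arch32():
    return gd.ArchitectureSpec(family="small", input_size_px=(32, 32))


class TestBuildDecoder:
    def test_alexnet_final_layer_two_classes(self):
        dec = gd.build_decoder(gd.ArchitectureSpec(family="alexnet"), seed=0)
        final = dec.net.layers[-1]
        assert final.w.shape[1] == 2

    def test_same_seed_identical_parameters(self, arch32):
        a = gd.build_decoder(arch32, seed=3)
        b = gd.build_decoder(arch32, seed=3)
        for pa, pb in zip(a.net.state(), b.net.state()):
            np.testing.assert_array_equal(pa, pb)
        c = gd.build_decoder(arch32, seed=4)
        assert any((pa != pc).any()
                   for pa, pc in zip(a.net.state(), c.net.state()))

    def test_small_forward_on_zero_map_finite(self):
        spec = gd.ArchitectureSpec(family="small", input_size_px=(64, 64))
        dec = gd.build_decoder(spec, seed=0)
        out = dec.forward(np.zeros((1, 1, 64, 64), dtype=np.float32))
        assert out.shape == (1, 2) and np.isfinite(out).all()

    def test_alexnet_forward_shape(self):
        dec = gd.build_decoder(gd.ArchitectureSpec(family="alexnet"), seed=0)
        out = dec.forward(np.zeros((1, 3, 227, 227), dtype=np.float32))
        assert out.shape == (1, 2) and np.isfinite(out).all()

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            gd.ArchitectureSpec(family="resnet")


class TestTrainDecoder:
    def test_separable_problem_high_accuracy(self, separable, arch32):
        tx, ty, vx, vy = separable
        dec = gd.build_decoder(arch32, seed=1)
        gd.train_decoder(dec, tx, ty, vx, vy, gd.TrainConfig(seed=2))
        assert evaluate_accuracy(dec, vx, vy) > 0.9
        # memorisation sanity: training maps classified even better
        assert evaluate_accuracy(dec, tx, ty) > 0.95

    def test_best_checkpoint_beats_untrained(self, separable, arch32):
        tx, ty, vx, vy = separable
        untrained = gd.build_decoder(arch32, seed=1)
        base = evaluate_accuracy(untrained, vx, vy)
        dec = gd.build_decoder(arch32, seed=1)
        gd.train_decoder(dec, tx, ty, vx, vy,
                         gd.TrainConfig(seed=2, max_epochs=2))
        best = max(h["val_accuracy"] for h in dec.history)
        assert best >= base

    def test_single_class_stream_is_degenerate(self, arch32):
        x = np.zeros((8, 1, 32, 32), dtype=np.float32)
        y = np.zeros(8, dtype=int)
        dec = gd.build_decoder(arch32, seed=0)
        with pytest.raises(DegenerateDataError):
            gd.train_decoder(dec, x, y, x, y, gd.TrainConfig(seed=0))

    def test_lr_schedule(self):
        cfg = gd.TrainConfig()
        assert gd.lr_at_epoch(cfg, 1) == pytest.approx(6e-4)
        assert gd.lr_at_epoch(cfg, 4) == pytest.approx(6e-4)
        assert gd.lr_at_epoch(cfg, 5) == pytest.approx(6e-5)
        assert gd.lr_at_epoch(cfg, 9) == pytest.approx(6e-6)

    def test_training_is_seed_reproducible(self, separable, arch32):
        tx, ty, vx, vy = separable
        sub = np.r_[0:64, 250:314]  # both classes represented
        hists = []
        for _ in range(2):
            dec = gd.build_decoder(arch32, seed=5)
            gd.train_decoder(dec, tx[sub], ty[sub], vx[:64], vy[:64],
                             gd.TrainConfig(seed=6, max_epochs=2))
            hists.append(dec.history)
        assert hists[0] == hists[1]

    def test_history_recorded_every_50_iterations(self, separable, arch32):
        tx, ty, vx, vy = separable
        dec = gd.build_decoder(arch32, seed=1)
        gd.train_decoder(dec, tx, ty, vx, vy,
                         gd.TrainConfig(seed=2, max_epochs=4))
        iters = [h["iteration"] for h in dec.history]
        # 500 maps / 32 per batch = 16 iters/epoch; 64 total, checkpoint at 50
        assert 50 in iters
        assert len(dec.history) > 4


class TestPredict:
    def test_prediction_deterministic_for_duplicates(self, separable,
                                                     arch32):
        tx, ty, vx, vy = separable
        dec = gd.build_decoder(arch32, seed=1)
        gd.train_decoder(dec, tx, ty, vx, vy,
                         gd.TrainConfig(seed=2, max_epochs=1))
        dup = np.concatenate([vx[:1], vx[:1]])
        pred, scores = gd.predict(dec, dup)
        assert pred[0] == pred[1]
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_batch_permutation_invariance(self, separable, arch32):
        tx, ty, vx, vy = separable
        sub = np.r_[0:32, 250:282]
        dec = gd.build_decoder(arch32, seed=1)
        gd.train_decoder(dec, tx[sub], ty[sub], vx[:32], vy[:32],
                         gd.TrainConfig(seed=2, max_epochs=1))
        perm = np.random.default_rng(0).permutation(len(vx))
        _, s1 = gd.predict(dec, vx)
        _, s2 = gd.predict(dec, vx[perm])
        assert np.isfinite(s1).all()
        np.testing.assert_allclose(s1[perm], s2, atol=1e-6)

    def test_shape_mismatch_rejected(self, arch32):
        dec = gd.build_decoder(arch32, seed=0)
        with pytest.raises(ConfigError):
            gd.predict(dec, np.zeros((1, 1, 64, 64), dtype=np.float32))

    def test_channel_replication_for_alexnet(self):
        spec = gd.ArchitectureSpec(family="alexnet")
        batch = maps_to_batch(np.zeros((2, 227, 227), dtype=np.float32),
                              spec)
        assert batch.shape == (2, 3, 227, 227)


class TestNNGradients:
    """Finite-difference checks of the backward passes."""

    @pytest.mark.parametrize("layer_fn,shape", [
        (lambda rng: nn.Conv2d(2, 3, 3, stride=1, pad=1, rng=rng),
         (2, 2, 6, 6)),
        (lambda rng: nn.Conv2d(1, 2, 3, stride=2, rng=rng), (2, 1, 7, 7)),
        (lambda rng: nn.MaxPool2d(2), (2, 2, 6, 6)),
        (lambda rng: nn.MaxPool2d(3, 2), (1, 2, 7, 7)),
        (lambda rng: nn.Dense(12, 4, rng=rng), (3, 12)),
    ])
    def test_input_gradient_matches_finite_difference(self, layer_fn, shape):
        rng = np.random.default_rng(0)
        layer = layer_fn(rng)
        x = rng.standard_normal(shape).astype(np.float32)
        out = layer.forward(x, train=True)
        g_out = rng.standard_normal(out.shape).astype(np.float32)
        g_in = layer.backward(g_out)
        eps = 1e-3
        idx = tuple(rng.integers(0, s) for s in shape)
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        num = (np.sum(layer.forward(xp, train=True) * g_out)
               - np.sum(layer.forward(xm, train=True) * g_out)) / (2 * eps)
        assert g_in[idx] == pytest.approx(num, abs=5e-2, rel=5e-2)

    def test_softmax_cross_entropy_gradient(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((4, 2)).astype(np.float32)
        targets = np.array([0, 1, 1, 0])
        _, grad = nn.softmax_cross_entropy(logits, targets)
        eps = 1e-4
        for i in range(4):
            for j in range(2):
                lp, lm = logits.copy(), logits.copy()
                lp[i, j] += eps
                lm[i, j] -= eps
                num = (nn.softmax_cross_entropy(lp, targets)[0]
                       - nn.softmax_cross_entropy(lm, targets)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-4)
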