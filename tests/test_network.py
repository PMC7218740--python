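"""Siamese patch classifier: data pipeline, training, dense conversion."""

import numpy as np
import pytest

from cpfuse.network import (
    DivergenceError,
    NetConfig,
    SiameseNet,
    evaluate_accuracy,
    make_blur_stack,
    pairs_to_arrays,
    sample_pairs,
    softmax2,
    to_dense,
    train,
    weight_map,
)
from scipy import ndimage


class TestSoftmax:
    def test_symmetric_input_splits_evenly(self):
        np.testing.assert_allclose(softmax2(np.array([0.0, 0.0])), [0.5, 0.5])

    def test_closed_form_value(self):
        np.testing.assert_allclose(
            softmax2(np.array([1.0, 2.0])),
            [np.e / (np.e + np.e**2), np.e**2 / (np.e + np.e**2)],
            atol=1e-12,
        )

    def test_large_gap_saturates_but_normalizes(self):
        p = softmax2(np.array([0.0, 50.0]))
        assert p[1] > 0.999999 and p.sum() == pytest.approx(1.0, abs=0)


class TestBlurStack:
    def test_constant_image_unchanged_by_blur(self):
        stack = make_blur_stack(np.full((32, 32), 0.6), 3)
        for lvl in stack:
            np.testing.assert_allclose(lvl, 0.6, atol=1e-12)

    def test_five_levels_plus_original(self, rng):
        stack = make_blur_stack(rng.uniform(0, 1, (32, 32)), 5)
        assert len(stack) == 6

    def test_variance_strictly_decreases(self, rng):
        stack = make_blur_stack(rng.uniform(0, 1, (64, 64)), 5)
        variances = [lvl.var() for lvl in stack]
        assert all(b < a for a, b in zip(variances, variances[1:]))

    def test_rejects_small_images(self):
        with pytest.raises(ValueError):
            make_blur_stack(np.ones((8, 8)), 2)


class TestSamplePairs:
    def test_counts_and_balance(self, rng):
        img = rng.uniform(0, 1, (64, 64))
        pairs = sample_pairs(img, ndimage.gaussian_filter(img, 2), 20, seed=0)
        assert len(pairs) == 40
        labels = [p.label for p in pairs]
        assert labels.count(1) == labels.count(0) == 20

    def test_positive_and_negative_are_swapped_views(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        blur = ndimage.gaussian_filter(img, 2)
        pairs = sample_pairs(img, blur, 5, seed=3)
        for pos, neg in zip(pairs[::2], pairs[1::2]):
            assert pos.label == 1 and neg.label == 0
            np.testing.assert_array_equal(pos.p1, neg.p2)
            np.testing.assert_array_equal(pos.p2, neg.p1)

    def test_same_seed_reproduces_coordinates(self, rng):
        img = rng.uniform(0, 1, (48, 48))
        blur = ndimage.gaussian_filter(img, 2)
        a = sample_pairs(img, blur, 10, seed=7)
        b = sample_pairs(img, blur, 10, seed=7)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.p1, pb.p1)

    def test_rejects_mismatched_or_small_images(self):
        with pytest.raises(ValueError):
            sample_pairs(np.ones((32, 32)), np.ones((31, 32)), 5, seed=0)
        with pytest.raises(ValueError):
            sample_pairs(np.ones((8, 8)), np.ones((8, 8)), 5, seed=0)


def _tiny_separable_pairs(rng, n=64):
    """Synthetic clearly-separable data: sharp checkerboards vs heavy blur."""
    img = np.kron(rng.integers(0, 2, (16, 16)), np.ones((4, 4))).astype(float)
    blur = ndimage.gaussian_filter(img, 3.0)
    return sample_pairs(img, blur, n, seed=int(rng.integers(2**31)))


class TestTraining:
    def test_zero_epochs_leaves_parameters_unchanged(self, rng):
        net = SiameseNet(seed=0)
        before = {k: v.copy() for k, v in net.params.items()}
        train(net, _tiny_separable_pairs(rng), epochs=0, seed=0)
        for k in before:
            np.testing.assert_array_equal(net.params[k], before[k])

    def test_loss_decreases_on_separable_data(self, rng):
        net = SiameseNet(seed=1)
        train(net, _tiny_separable_pairs(rng, 128), epochs=5, seed=1)
        assert net.history[-1] < net.history[0]
        # no epoch may blow the loss back up
        assert max(net.history) <= net.history[0] * 1.05

    def test_training_is_seed_reproducible(self, rng):
        data = _tiny_separable_pairs(rng, 32)
        nets = []
        for _ in range(2):
            net = SiameseNet(seed=5)
            train(net, data, epochs=2, seed=5)
            nets.append(net)
        for k in nets[0].params:
            np.testing.assert_array_equal(nets[0].params[k], nets[1].params[k])

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(SiameseNet(seed=0), [], epochs=1)

    def test_divergent_learning_rate_raises_with_epoch(self, rng):
        net = SiameseNet(NetConfig(lr=1e8), seed=0)
        with pytest.raises(DivergenceError), np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                train(net, _tiny_separable_pairs(rng, 64), epochs=10, seed=0)


class TestDenseConversion:
    def test_single_patch_scores_match_head(self, rng):
        net = SiameseNet(seed=2)
        dense = to_dense(net)
        p1 = rng.uniform(0, 1, (16, 16)).astype(np.float32)
        p2 = rng.uniform(0, 1, (16, 16)).astype(np.float32)
        s_head = net.scores(p1[None, None], p2[None, None])[0]
        s_dense = dense.dense_scores(p1, p2)
        assert s_dense.shape == (2, 1, 1)
        np.testing.assert_allclose(s_dense[:, 0, 0], s_head, atol=1e-6)

    def test_grid_matches_sliding_window_oracle(self, rng):
        net = SiameseNet(seed=3)
        dense = to_dense(net)
        a = rng.uniform(0, 1, (32, 30)).astype(np.float32)
        b = rng.uniform(0, 1, (32, 30)).astype(np.float32)
        grid = dense.dense_scores(a, b)
        gh, gw_ = grid.shape[1:]
        assert (gh, gw_) == ((32 - 16) // 2 + 1, (30 - 16) // 2 + 1)
        for i in range(gh):
            for j in range(gw_):
                win_a = a[2 * i : 2 * i + 16, 2 * j : 2 * j + 16]
                win_b = b[2 * i : 2 * i + 16, 2 * j : 2 * j + 16]
                ref = net.scores(win_a[None, None], win_b[None, None])[0]
                np.testing.assert_allclose(grid[:, i, j], ref, atol=1e-6)

    def test_architecture_mismatch_raises(self):
        net = SiameseNet(seed=0)
        net.params["wf"] = net.params["wf"][:, :100].copy()
        with pytest.raises(ValueError, match="head shape"):
            to_dense(net)


class TestWeightMap:
    @pytest.mark.parametrize("shape", [(64, 64), (65, 63), (128, 96)])
    def test_output_shape_matches_sources(self, rng, shape):
        net = SiameseNet(seed=4)
        a = rng.uniform(0, 1, shape)
        b = rng.uniform(0, 1, shape)
        wm = weight_map(net, a, b)
        assert wm.shape == shape
        assert wm.min() >= 0.0 and wm.max() <= 1.0

    def test_identical_inputs_give_valid_map(self, rng):
        net = SiameseNet(seed=4)
        a = rng.uniform(0, 1, (48, 48))
        wm = weight_map(net, a, a)
        assert np.all((0.0 <= wm) & (wm <= 1.0))

    def test_sharp_source_dominates_blurred_source(self, trained_net, rng):
        from cpfuse.fixtures import PhantomSpec, make_phantom_pair

        a, _ = make_phantom_pair(PhantomSpec(shape=(96, 96), seed=77))
        b = ndimage.gaussian_filter(a, 4.0)
        wm = weight_map(trained_net, a, b)
        assert wm.mean() > 0.9

    def test_size_mismatch_rejected(self):
        net = SiameseNet(seed=0)
        with pytest.raises(ValueError, match="differ"):
            weight_map(net, np.ones((32, 32)), np.ones((32, 31)))


class TestCheckpoint:
    def test_save_load_round_trips_bit_exactly(self, tmp_path, rng):
        net = SiameseNet(NetConfig(channels=(4, 8, 16)), seed=9)
        train(net, _tiny_separable_pairs(rng, 32), epochs=1, seed=9)
        path = tmp_path / "net.npz"
        net.save(path)
        loaded = SiameseNet.load(path)
        assert loaded.config == net.config
        for k in net.params:
            np.testing.assert_array_equal(loaded.params[k], net.params[k])
        # loaded net scores identically
        x = rng.uniform(0, 1, (2, 1, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(net.scores(x, x), loaded.scores(x, x))


def test_trained_net_separates_held_out_pairs(trained_net):
    """Reduced-scale trainability proxy: unseen-seed fixture accuracy."""
    from cpfuse.fixtures import make_training_corpus

    held_out = make_training_corpus(6, seed=20_000)
    assert evaluate_accuracy(trained_net, held_out) >= 0.9
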