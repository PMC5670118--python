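"""Sparse coding, dictionary learning, network geometry, two-path control."""

import numpy as np
import pytest

from texsig import shmax
from texsig.shmax import (Dictionary, LayerSpec, NetworkSpec, build_two_path,
                          desk_spec, encode, forward, kkt_violation,
                          learn_dictionary, randomize_weights, rf_size,
                          rf_size_sets, sample_patches, unit_count)


def _random_dict(rng, d, m):
    A = rng.standard_normal((d, m))
    A /= np.linalg.norm(A, axis=0)
    return A


class TestEncode:
    def test_large_lambda_gives_zero_code(self):
        rng = np.random.default_rng(0)
        A = _random_dict(rng, 12, 6)
        x = rng.standard_normal(12)
        lam = 2.0 * max(0.0, (A.T @ x).max()) + 0.1
        s = encode(x, A, lam)
        np.testing.assert_array_equal(s, 0.0)
        # the stationarity condition certifies the zero solution
        assert kkt_violation(x, A, s, lam) < 1e-10

    def test_orthonormal_soft_threshold_closed_form(self):
        # orthonormal A: s_i = max(0, a_i^T x - lam/2)
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.standard_normal((10, 10)))
        A = Q[:, :6]
        lam = 1e-6
        x = A[:, 3].copy()
        s = encode(x, A, lam)
        expected = np.maximum(0.0, A.T @ x - lam / 2)
        np.testing.assert_allclose(s, expected, atol=1e-9)
        assert np.argmax(s) == 3

    def test_zero_input_zero_code(self):
        rng = np.random.default_rng(2)
        A = _random_dict(rng, 8, 4)
        np.testing.assert_array_equal(encode(np.zeros(8), A, 0.1), 0.0)

    def test_objective_never_worse_than_zero_code(self):
        rng = np.random.default_rng(3)
        A = _random_dict(rng, 15, 10)
        x = rng.standard_normal(15)
        s = encode(x, A, 0.2)
        obj = np.sum((x - A @ s) ** 2) + 0.2 * s.sum()
        assert obj <= np.sum(x ** 2) + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_kkt_conditions_on_random_problems(self, seed):
        rng = np.random.default_rng(seed)
        d, m = rng.integers(8, 30), rng.integers(4, 20)
        A = _random_dict(rng, d, m)
        X = rng.standard_normal((d, 5))
        lam = float(rng.uniform(0.05, 0.5))
        S = encode(X, A, lam)
        assert (S >= 0).all()
        assert kkt_violation(X, A, S, lam) < 1e-6

    def test_nonfinite_rejected(self):
        A = _random_dict(np.random.default_rng(4), 8, 4)
        x = np.full(8, np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            encode(x, A, 0.1)


class TestLearnDictionary:
    @staticmethod
    def _planted_problem(seed, n=400, d=20, m=3):
        rng = np.random.default_rng(seed)
        true = _random_dict(rng, d, m)
        codes = rng.exponential(1.0, size=(m, n)) * (rng.random((m, n)) < 0.4)
        X = (true @ codes).T + 0.01 * rng.standard_normal((n, d))
        return X, true

    def test_recovers_planted_bases(self):
        X, true = self._planted_problem(1)
        D, _ = learn_dictionary(X, m=3, lam=0.1, n_iters=40, seed=1)
        sims = np.abs(true.T @ D.bases)     # m_true x m_learned cosines
        best = sims.max(axis=1)
        assert (best >= 0.95).all()

    def test_objective_monotone_nonincreasing(self):
        X, _ = self._planted_problem(5)
        _, info = learn_dictionary(X, m=3, lam=0.05, n_iters=20, seed=2,
                                   tol=0.0)
        obj = np.asarray(info["objective"])
        assert (np.diff(obj) <= 1e-6 * np.abs(obj[:-1]) + 1e-12).all()

    def test_deterministic_given_seed(self):
        X, _ = self._planted_problem(7)
        D1, _ = learn_dictionary(X, m=3, lam=0.05, n_iters=3, seed=3)
        D2, _ = learn_dictionary(X, m=3, lam=0.05, n_iters=3, seed=3)
        np.testing.assert_array_equal(D1.bases, D2.bases)

    def test_column_norm_constraint(self):
        X, _ = self._planted_problem(8)
        D, _ = learn_dictionary(X, m=5, lam=0.05, n_iters=10, seed=4)
        assert ((D.bases ** 2).sum(axis=0) <= 1 + 1e-9).all()

    def test_bad_iteration_count_rejected(self):
        with pytest.raises(ValueError):
            learn_dictionary(np.zeros((10, 4)), m=2, lam=0.1, n_iters=0)

    def test_warns_with_too_few_patches(self):
        with pytest.warns(UserWarning, match="patches"):
            learn_dictionary(np.random.default_rng(0).random((3, 4)),
                             m=5, lam=0.1, n_iters=1)


class TestSamplePatches:
    def test_count_is_images_times_rate(self):
        maps = [np.random.default_rng(i).random((20, 20)) for i in range(10)]
        P = sample_patches(maps, patch_size=5, n_per_image=200, seed=0)
        assert P.shape == (2000, 25)

    def test_zero_rate_gives_empty(self):
        maps = [np.zeros((10, 10))]
        assert sample_patches(maps, 3, n_per_image=0).shape[0] == 0

    def test_seed_reproducible(self):
        maps = [np.random.default_rng(0).random((12, 12, 2))]
        a = sample_patches(maps, 4, 50, seed=5)
        b = sample_patches(maps, 4, 50, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            sample_patches([np.zeros((8, 8))], patch_size=9, n_per_image=1)


def _tiny_net():
    layers = [
        LayerSpec("sparse_coding", kernel=5, stride=1, m=4, lam=0.15),
        LayerSpec("max_pool", kernel=2, stride=2),
        LayerSpec("sparse_coding", kernel=3, stride=1, m=6, lam=0.1),
    ]
    return NetworkSpec(layers=layers, grouping=[[0, 1], [2]])


def _tiny_dicts(seed=0):
    rng = np.random.default_rng(seed)
    return {
        0: Dictionary(bases=_random_dict(rng, 25, 4), patch_shape=(5, 5, 1)),
        2: Dictionary(bases=_random_dict(rng, 36, 6), patch_shape=(3, 3, 4)),
    }


class TestForward:
    def test_zero_image_all_zero_responses(self):
        out = forward(_tiny_net(), _tiny_dicts(), np.zeros((16, 16)))
        for fm in out["layers"]:
            np.testing.assert_array_equal(fm, 0.0)

    def test_shapes_and_nonnegativity(self):
        rng = np.random.default_rng(1)
        out = forward(_tiny_net(), _tiny_dicts(), rng.standard_normal((16, 16)))
        assert out["layers"][0].shape == (12, 12, 4)
        assert out["layers"][1].shape == (6, 6, 4)
        assert out["layers"][2].shape == (4, 4, 6)
        assert len(out["big"]) == 2
        for fm in out["layers"]:
            assert (fm >= 0).all()

    def test_max_pool_propagates_single_peak(self):
        fm = np.zeros((4, 4, 1))
        fm[1, 2, 0] = 3.0
        pooled = shmax._max_pool(fm, 2, 2)
        assert pooled[0, 1, 0] == 3.0
        assert pooled.sum() == 3.0

    def test_dictionary_shape_mismatch_names_layer(self):
        dicts = _tiny_dicts()
        dicts[0] = Dictionary(
            bases=_random_dict(np.random.default_rng(0), 16, 4),
            patch_shape=(4, 4, 1))
        with pytest.raises(ValueError, match="layer 0"):
            forward(_tiny_net(), dicts, np.ones((16, 16)))

    def test_batch_forward_matches_single(self):
        rng = np.random.default_rng(2)
        imgs = [rng.standard_normal((16, 16)) for _ in range(3)]
        net, dicts = _tiny_net(), _tiny_dicts()
        batch = shmax.forward_batch(net, dicts, imgs)
        for i, img in enumerate(imgs):
            single = forward(net, dicts, img)
            for b in range(2):
                np.testing.assert_allclose(batch["big"][b][i],
                                           single["big"][b], atol=1e-8)


class TestGeometry:
    def test_single_layer_rf_is_kernel(self):
        net = NetworkSpec(
            layers=[LayerSpec("sparse_coding", 11, 4, m=96, lam=0.15)],
            grouping=[[0]])
        assert rf_size(net, 0) == 11

    def test_rf_recursion_with_pooling(self):
        net = NetworkSpec(
            layers=[LayerSpec("sparse_coding", 11, 4, m=96, lam=0.15),
                    LayerSpec("max_pool", 3, 2)],
            grouping=[[0, 1]])
        assert rf_size(net, 1) == 11 + 2 * 4

    def test_rf_nondecreasing_with_depth(self):
        net = desk_spec(n_big=3, m=(4, 4, 4))
        rfs = [rf_size(net, i) for i in range(len(net.layers))]
        assert all(b >= a for a, b in zip(rfs, rfs[1:]))
        for i in range(1, len(net.layers)):
            if net.layers[i].kernel > 1:
                assert rfs[i] > rfs[i - 1]

    def test_reference_first_layer_unit_count(self):
        # 11x11 stride-4 convolution on a 224-px input with padding 2
        # produces 55x55 maps; with 96 filters that is 290400 units
        net = NetworkSpec(
            layers=[LayerSpec("sparse_coding", 11, 4, padding=2, m=96,
                              lam=0.15)],
            grouping=[[0]])
        assert unit_count(net, 0, input_size=224) == 290400

    def test_unit_count_trivial(self):
        net = NetworkSpec(
            layers=[LayerSpec("sparse_coding", 8, 1, m=1, lam=0.1)],
            grouping=[[0]])
        assert unit_count(net, 0, input_size=8) == 1

    def test_infeasible_geometry_reported(self):
        net = NetworkSpec(
            layers=[LayerSpec("sparse_coding", 9, 4, m=2, lam=0.1)],
            grouping=[[0]])
        with pytest.raises(ValueError, match="infeasible"):
            unit_count(net, 0, input_size=8)


class TestTwoPath:
    def _base(self):
        return desk_spec(n_big=3, m=(8, 8, 8), kernels=(5, 3, 3),
                         strides=(1, 1, 1))

    def test_rf_equalities_hold_constructively(self):
        split = build_two_path(self._base(), 0, 1, split=0.5)
        rf = rf_size_sets(split)
        assert rf["a"] == rf["b"]
        assert rf["b"] > rf["c"]

    def test_merge_map_sizes_agree(self):
        split = build_two_path(self._base(), 0, 1, split=0.5)
        rng = np.random.default_rng(0)
        imgs = [rng.standard_normal((32, 32)) * 0.05 for _ in range(4)]
        model = shmax.ShmaxModel(split, n_patches_per_image=30, n_iters=2)
        res = model.fit(imgs, seed=0)
        out = res.forward(imgs[0])
        assert out["sets"]["a"].shape[:2] == out["sets"]["d"].shape[:2]
        assert out["sets"]["b"].shape[:2] == out["sets"]["c"].shape[:2]

    def test_non_consecutive_big_layers_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            build_two_path(self._base(), 0, 2)


class TestRandomizeWeights:
    def test_unit_norm_and_reproducible(self):
        dicts = _tiny_dicts()
        r1 = randomize_weights(dicts, seed=0)
        r2 = randomize_weights(dicts, seed=0)
        for k in dicts:
            np.testing.assert_allclose(
                np.linalg.norm(r1[k].bases, axis=0), 1.0, atol=1e-12)
            np.testing.assert_array_equal(r1[k].bases, r2[k].bases)

    def test_uncorrelated_with_originals_in_expectation(self):
        dicts = _tiny_dicts()
        sims = []
        for seed in range(30):
            r = randomize_weights(dicts, seed=seed)
            sims.append((dicts[0].bases * r[0].bases).sum(axis=0).mean())
        assert abs(np.mean(sims)) < 0.05
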