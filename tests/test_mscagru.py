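"""MS-CAGRU network: GRU cell, multi-scale encoding, training behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrosoil.data import SyntheticConfig, generate_synthetic_dataset, minmax_scale, split_train_test
from hydrosoil.mscagru import (
    FeatureBundle,
    GRUCellParams,
    MSCAGRUConfig,
    build_model,
    encode_multiscale,
    gru_step,
    predict,
    pretrain_autoencoders,
    train_mscagru,
)


def zero_cell(H=4, I=3):
    z = np.zeros
    return GRUCellParams(z((H, H + I)), z(H), z((H, H + I)), z(H), z((H, H + I)), z(H))


def random_cell(rng, H=5, I=4):
    n = lambda *s: rng.normal(size=s)
    return GRUCellParams(n(H, H + I), n(H), n(H, H + I), n(H), n(H, H + I), n(H))


def make_bundles(effect_size, n=240, seed=0, shuffle_labels=False):
    table = generate_synthetic_dataset(
        SyntheticConfig(n_samples=n, effect_size=effect_size, n_noise_features=3, seed=seed)
    )
    if shuffle_labels:
        rng = np.random.default_rng(seed + 1)
        table.labels = rng.permutation(table.labels)
    train, test = split_train_test(table, 0.75, seed=seed)
    Xtr = minmax_scale(train, train).features
    Xte = minmax_scale(test, train).features
    return (
        FeatureBundle(Xtr, 0.5 * Xtr, Xtr),
        train.labels,
        FeatureBundle(Xte, 0.5 * Xte, Xte),
        test.labels,
    )


class TestGRUStep:
    def test_zero_parameters_halve_state(self):
        h_prev = np.array([1.0, -2.0, 0.5, 3.0])
        h = gru_step(zero_cell(), np.zeros(3), h_prev)
        assert np.allclose(h, 0.5 * h_prev)

    def test_update_gate_saturation_high(self):
        cell = zero_cell()
        cell.b_z[:] = 30.0  # z ~ 1 -> h equals the candidate (0 here)
        h = gru_step(cell, np.ones(3), np.array([1.0, 2.0, 3.0, 4.0]))
        assert np.allclose(h, 0.0, atol=1e-9)

    def test_update_gate_saturation_low(self):
        cell = zero_cell()
        cell.b_z[:] = -30.0  # z ~ 0 -> h equals h_prev
        h_prev = np.array([1.0, 2.0, 3.0, 4.0])
        h = gru_step(cell, np.ones(3), h_prev)
        assert np.allclose(h, h_prev, atol=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            gru_step(zero_cell(), np.zeros(5), np.zeros(4))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_convex_combination_property(self, seed):
        """Each h coordinate lies between h_prev and the candidate c."""
        rng = np.random.default_rng(seed)
        cell = random_cell(rng)
        x = rng.normal(size=4)
        h_prev = rng.normal(size=5)
        hx = np.concatenate([h_prev, x])
        z = 1 / (1 + np.exp(-(hx @ cell.W_z.T + cell.b_z)))
        r = 1 / (1 + np.exp(-(hx @ cell.W_r.T + cell.b_r)))
        c = np.tanh(np.concatenate([r * h_prev, x]) @ cell.W_c.T + cell.b_c)
        h = gru_step(cell, x, h_prev)
        lo = np.minimum(h_prev, c) - 1e-12
        hi = np.maximum(h_prev, c) + 1e-12
        assert np.all(h >= lo) and np.all(h <= hi)


class TestEncodeMultiscale:
    def test_row_count_preserved_and_deterministic(self, rng):
        bundle = FeatureBundle(rng.random((7, 5)), rng.random((7, 5)), rng.random((7, 8)))
        model = build_model(bundle.widths, MSCAGRUConfig(seed=0))
        a = encode_multiscale(bundle, model)
        b = encode_multiscale(bundle, model)
        assert a.shape[0] == 7
        assert np.array_equal(a, b)

    def test_identity_kernels_reproduce_concatenation(self, rng):
        """Center-tap single-channel linear encoders act as the identity."""
        O, W, D = rng.random((6, 4)), rng.random((6, 4)), rng.random((6, 5))
        bundle = FeatureBundle(O, W, D)
        cfg = MSCAGRUConfig(branch_channels=1, activation="linear", seed=0)
        model = build_model(bundle.widths, cfg)
        for name, k in zip(("orig", "wtd", "deep"), cfg.branch_kernel_sizes):
            ident = np.zeros((1, 1, k))
            ident[0, 0, k // 2] = 1.0
            model.params[f"enc_W_{name}"] = ident
            model.params[f"enc_b_{name}"] = np.zeros(1)
        fused = encode_multiscale(bundle, model)
        assert np.allclose(fused, np.hstack([O, W, D]), atol=1e-9)

    def test_width_mismatch_rejected(self, rng):
        bundle = FeatureBundle(rng.random((3, 4)), rng.random((3, 4)), rng.random((3, 4)))
        model = build_model((4, 4, 5), MSCAGRUConfig(seed=0))
        with pytest.raises(ValueError, match="widths"):
            encode_multiscale(bundle, model)


class TestPretraining:
    def test_reconstruction_loss_decreases(self, rng):
        X = rng.random((200, 6))
        bundle = FeatureBundle(X, X, X)
        finals, initials = [], []
        for seed in range(3):
            cfg = MSCAGRUConfig(pretrain_epochs=20, seed=seed)
            model = pretrain_autoencoders(bundle, cfg)
            for curve in model.pretrain_loss:
                initials.append(curve[0])
                finals.append(curve[-1])
        assert np.median(finals) <= np.median(initials)

    def test_zero_epochs_leave_parameters_at_initialization(self, rng):
        X = rng.random((20, 5))
        bundle = FeatureBundle(X, X, X)
        cfg = MSCAGRUConfig(pretrain_epochs=0, seed=4)
        fresh = build_model(bundle.widths, cfg)
        trained = pretrain_autoencoders(bundle, cfg)
        for key in fresh.params:
            assert np.array_equal(fresh.params[key], trained.params[key])

    def test_seeded_determinism(self, rng):
        X = rng.random((40, 5))
        bundle = FeatureBundle(X, X, X)
        cfg = MSCAGRUConfig(pretrain_epochs=3, seed=5)
        a = pretrain_autoencoders(bundle, cfg)
        b = pretrain_autoencoders(bundle, cfg)
        for key in a.params:
            assert np.array_equal(a.params[key], b.params[key])


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        losses_first, losses_last = [], []
        for seed in range(3):
            btr, ytr, _, _ = make_bundles(3.0, n=160, seed=seed)
            cfg = MSCAGRUConfig(pretrain_epochs=0, train_epochs=15, seed=seed)
            model = train_mscagru(btr, ytr, cfg)
            losses_first.append(model.train_loss[0])
            losses_last.append(model.train_loss[-1])
        assert np.median(losses_last) <= np.median(losses_first)

    def test_holdout_accuracy_on_separable_data(self):
        btr, ytr, bte, yte = make_bundles(3.0, n=400, seed=0)
        model = train_mscagru(btr, ytr, MSCAGRUConfig(seed=0))
        y_pred, probs = predict(model, bte)
        assert np.mean(y_pred == yte) >= 0.9
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_shuffled_labels_stay_near_chance(self):
        btr, ytr, bte, yte = make_bundles(3.0, n=240, seed=2, shuffle_labels=True)
        model = train_mscagru(btr, ytr, MSCAGRUConfig(train_epochs=30, seed=2))
        y_pred, _ = predict(model, bte)
        majority = max(np.mean(yte == c) for c in np.unique(yte))
        assert abs(np.mean(y_pred == yte) - majority) <= 0.1 + 1e-9

    def test_deterministic_predictions(self):
        btr, ytr, bte, _ = make_bundles(2.0, n=120, seed=3)
        cfg = MSCAGRUConfig(pretrain_epochs=2, train_epochs=5, seed=6)
        a = predict(train_mscagru(btr, ytr, cfg), bte)
        b = predict(train_mscagru(btr, ytr, cfg), bte)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_single_class_rejected(self, rng):
        X = rng.random((10, 4))
        bundle = FeatureBundle(X, X, X)
        with pytest.raises(ValueError, match="two classes"):
            train_mscagru(bundle, np.zeros(10), MSCAGRUConfig(seed=0))

    def test_single_sample_prediction(self):
        btr, ytr, bte, _ = make_bundles(2.0, n=120, seed=4)
        cfg = MSCAGRUConfig(pretrain_epochs=0, train_epochs=3, seed=0)
        model = train_mscagru(btr, ytr, cfg)
        one = FeatureBundle(bte.original[:1], bte.weighted[:1], bte.deep[:1])
        labels, probs = predict(model, one)
        assert labels.shape == (1,) and probs.shape[0] == 1
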