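"""Network building blocks: convolutions, heads, blocks, full model."""

import numpy as np
import pytest

from lightptnet import (LSTCHeadSpec, NetworkSpec, build_network,
                        conv_chain_receptive_field, load_preset,
                        network_spec_from_hyperparameters, receptive_field,
                        softmax, save_checkpoint, load_checkpoint)
from lightptnet import nn
from lightptnet.network import _DilationLevel, _LSTCHead


def brute_force_conv1d(x, w, dilation, padding):
    """Direct nested-loop dilated convolution oracle. x: [T, Cin],
    w: [k, Cin, Cout]."""
    T, cin = x.shape
    k, _, cout = w.shape
    left, _ = nn.pad_amounts(k, dilation, padding)
    out = np.zeros((T, cout))
    for t in range(T):
        for j in range(k):
            src = t - left + j * dilation
            if 0 <= src < T:
                for o in range(cout):
                    out[t, o] += x[src] @ w[j, :, o]
    return out


class TestSeparableConv:
    @pytest.mark.parametrize("dilation,padding", [(1, "same"), (2, "same"),
                                                  (1, "causal"), (3, "causal")])
    def test_equals_depthwise_then_pointwise_composition(self, dilation,
                                                         padding):
        """Separable conv == depthwise conv (diagonal standard conv) followed
        by a 1x1 conv, against the nested-loop oracle."""
        rng = np.random.default_rng(0)
        for trial in range(25):
            x = rng.normal(size=(16, 3))
            wd = rng.normal(size=(3, 3))     # [k, C]
            wp = rng.normal(size=(3, 5))     # [Cin, Cout]
            got = nn.pointwise_conv1d(
                nn.depthwise_conv1d(x[None], wd, dilation, padding), wp)[0]
            # depthwise as standard conv with a diagonal channel kernel
            wfull = np.zeros((3, 3, 3))
            for c in range(3):
                wfull[:, c, c] = wd[:, c]
            expect = brute_force_conv1d(x, wfull, dilation, padding) @ wp
            np.testing.assert_allclose(got, expect, atol=1e-5)

    def test_dilation_one_equals_plain_correlation(self):
        # np.correlate oracle: dilation 1 is the ordinary sliding dot product
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 20, 4))
        w = rng.normal(size=(5, 4))
        out = nn.depthwise_conv1d(x, w, 1, "same")
        left, right = nn.pad_amounts(5, 1, "same")
        for c in range(4):
            xp = np.pad(x[0, :, c], (left, right))
            expect = np.correlate(xp, w[:, c], mode="valid")
            np.testing.assert_allclose(out[0, :, c], expect, atol=1e-10)

    def test_identity_kernels_pass_input_through(self):
        # single 1 at the centre tap + identity pointwise -> identity
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 10, 3))
        wd = np.zeros((3, 3))
        wd[1, :] = 1.0   # centre tap of k=3, 'same' pads 1 left / 1 right
        wp = np.eye(3)
        out = nn.pointwise_conv1d(nn.depthwise_conv1d(x, wd, 1, "same"), wp)
        np.testing.assert_allclose(out, x)

    def test_same_padding_preserves_length(self):
        x = np.zeros((1, 37, 2))
        for k, d in [(4, 1), (8, 2), (12, 4)]:
            out = nn.depthwise_conv1d(x, np.ones((k, 2)), d, "same")
            assert out.shape[1] == 37

    def test_causal_mode_no_lookahead(self):
        """Perturbation probe: changing x at time t never changes causal
        outputs before t."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 24, 2))
        w = rng.normal(size=(6, 2))
        base = nn.depthwise_conv1d(x, w, 2, "causal")
        for t in [0, 5, 12, 23]:
            xp = x.copy()
            xp[0, t, :] += 10.0
            out = nn.depthwise_conv1d(xp, w, 2, "causal")
            np.testing.assert_array_equal(out[0, :t], base[0, :t])

    def test_layer_gradients_match_numerical(self):
        """Finite-difference check of the separable conv backward pass."""
        rng = np.random.default_rng(4)
        layer = nn.SeparableConv1d(2, 3, kernel=3, dilation=2,
                                   padding="same", rng=rng)
        x = rng.normal(size=(2, 8, 2)).astype(np.float64)
        g = rng.normal(size=(2, 8, 3))

        def loss(xv):
            return float((nn.pointwise_conv1d(
                nn.depthwise_conv1d(xv, layer.depthwise.w.value, 2, "same"),
                layer.pointwise.w.value) * g).sum())

        layer.forward(x)
        gx = layer.backward(g)
        eps = 1e-5
        for idx in [(0, 0, 0), (1, 3, 1), (0, 7, 0)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (loss(xp) - loss(xm)) / (2 * eps)
            assert gx[idx] == pytest.approx(num, rel=1e-3, abs=1e-4)


class TestLSTCHead:
    def _head(self, cin=2, F=3, dropout=0.05, seed=0):
        rng = np.random.default_rng(seed)
        spec = LSTCHeadSpec(kernel_size=3, dilation=1, filters=F,
                            dropout_rate=dropout)
        return _LSTCHead(cin, spec, rng, rng)

    def test_eval_mode_deterministic_and_nonnegative(self):
        head = self._head()
        x = np.random.default_rng(1).normal(size=(2, 12, 2)).astype(np.float32)
        a = head.forward(x, training=False)
        b = head.forward(x, training=False)
        np.testing.assert_array_equal(a, b)
        assert (a >= 0).all()   # post-ReLU

    def test_zero_input_yields_shifted_bn_output(self):
        """BN formula oracle: all-zero input gives zero pre-BN activations;
        in training mode the output is ReLU(beta) for each unit.

        Kernel size 1 keeps a constant signal constant through the second
        conv (no padding edge effects), so its batch variance is exactly 0.
        """
        rng = np.random.default_rng(0)
        spec = LSTCHeadSpec(kernel_size=1, dilation=1, filters=3,
                            dropout_rate=0.0)
        head = _LSTCHead(2, spec, rng, rng)
        beta1 = head.layers[1].beta
        beta2 = head.layers[5].beta
        beta1.value[...] = np.array([0.5, -0.5, 0.2], np.float32)
        beta2.value[...] = np.array([-1.0, 0.3, 0.0], np.float32)
        x = np.zeros((2, 10, 2), np.float32)
        out = head.forward(x, training=True)
        # unit 1 emits ReLU(beta1) (constant per channel); unit 2's conv of a
        # constant is constant, its BN has zero variance -> output ReLU(beta2)
        expect = np.maximum(beta2.value, 0.0)
        np.testing.assert_allclose(out, np.broadcast_to(expect, out.shape),
                                   atol=1e-4)

    def test_dropout_stochastic_in_train_mode(self):
        head = self._head(dropout=0.4)
        x = np.random.default_rng(2).normal(size=(4, 12, 2)).astype(np.float32)
        a = head.forward(x, training=True)
        b = head.forward(x, training=True)
        assert not np.array_equal(a, b)

    def test_dropout_rate_validation(self):
        with pytest.raises(ValueError):
            LSTCHeadSpec(kernel_size=3, dilation=1, filters=4,
                         dropout_rate=1.0)


class TestDilationLevel:
    def _level(self, cin=3, F=3, seed=0):
        rng = np.random.default_rng(seed)
        heads = [LSTCHeadSpec(kernel_size=k, dilation=1, filters=F,
                              dropout_rate=0.0) for k in (2, 3, 4)]
        return _DilationLevel(cin, heads, rng, rng)

    def test_residual_pass_through_when_heads_zeroed(self):
        level = self._level()
        for head in level.heads:
            for p in head.params():
                p.value[...] = 0.0
        level.residual.w.value[...] = np.eye(3, dtype=np.float32)
        x = np.random.default_rng(5).normal(size=(2, 8, 3)).astype(np.float32)
        out = level.forward(x, training=False)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_hand_computed_head_unit(self):
        """Pencil-and-paper oracle for one head on a length-4 input.

        conv1: k=2 'same' (pad right) with taps [1, 1] -> x[t] + x[t+1];
        pointwise doubles; BN is made the identity (gamma=sqrt(var+eps),
        beta=mean-compensated in eval mode with running stats); conv2 is the
        identity.  Expected output: 2 * (x[t] + x[t+1]) with x[4] = 0.
        """
        rng = np.random.default_rng(0)
        spec = LSTCHeadSpec(kernel_size=2, dilation=1, filters=1,
                            dropout_rate=0.0)
        head = _LSTCHead(1, spec, rng, rng)
        dw1, pw1, bn1 = head.layers[0].depthwise, head.layers[0].pointwise, \
            head.layers[1]
        dw2, pw2, bn2 = head.layers[4].depthwise, head.layers[4].pointwise, \
            head.layers[5]
        dw1.w.value[...] = np.array([[1.0], [1.0]], np.float32)
        pw1.w.value[...] = np.array([[2.0]], np.float32)
        dw2.w.value[...] = np.array([[1.0], [0.0]], np.float32)
        pw2.w.value[...] = np.array([[1.0]], np.float32)
        for bn in (bn1, bn2):
            bn.running_mean[...] = 0.0
            bn.running_var[...] = 1.0 - bn.eps  # so 1/sqrt(var+eps) == 1
        x = np.array([[[1.0], [2.0], [3.0], [4.0]]], np.float32)
        out = head.forward(x, training=False)
        np.testing.assert_allclose(out[0, :, 0], [6.0, 10.0, 14.0, 8.0],
                                   rtol=1e-6)


class TestNetwork:
    def test_pooling_halves_length(self):
        pool = nn.AvgPool1d(2)
        x = np.arange(2 * 128 * 3, dtype=np.float32).reshape(2, 128, 3)
        assert pool.forward(x).shape == (2, 64, 3)
        odd = np.zeros((1, 151, 3), np.float32)
        assert pool.forward(odd).shape == (1, 75, 3)

    @pytest.mark.parametrize("preset,K", [("ucihar", 6), ("unimib", 17),
                                          ("wisdm", 6)])
    def test_presets_build_and_classify(self, preset, K):
        spec = load_preset(preset)["network"]
        model = build_network(spec)
        x = np.random.default_rng(0).normal(
            size=(3, spec.input_shape[0], spec.input_shape[1]))
        probs = softmax(model.forward(x))
        assert probs.shape == (3, K)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all() and (probs <= 1).all()

    def test_build_determinism(self, tiny_spec):
        a = build_network(tiny_spec)
        b = build_network(tiny_spec)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_variable_length_inputs_run(self, tiny_spec):
        model = build_network(tiny_spec)
        for T in (16, 32, 100):
            x = np.zeros((2, T, 3), np.float32)
            assert model.forward(x).shape == (2, 4)

    def test_branch_length_mismatch_names_both_lengths(self):
        spec = network_spec_from_hyperparameters(
            input_shape=(32, 3), n_blocks=2, filters=4,
            kernel_sizes=[2, 3, 4], dilations=[1], dropout=0.0, n_classes=3)
        spec.skip_pool_size = 4   # deliberately inconsistent
        with pytest.raises(ValueError, match="16.*8|8.*16"):
            build_network(spec)

    def test_predict_tie_breaks_to_lowest_index(self, tiny_spec):
        model = build_network(tiny_spec)
        probs = np.full((2, 4), 0.25)
        assert probs.argmax(axis=1).tolist() == [0, 0]
        p, labels = model.predict(np.zeros((2, 32, 3)))
        assert p.shape == (2, 4)
        np.testing.assert_array_equal(labels, p.argmax(axis=1))

    def test_eval_predictions_repeatable(self, tiny_spec):
        model = build_network(tiny_spec)
        x = np.random.default_rng(1).normal(size=(4, 32, 3))
        p1, l1 = model.predict(x)
        p2, l2 = model.predict(x)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(l1, l2)

    def test_checkpoint_round_trip(self, tmp_path, tiny_spec):
        model = build_network(tiny_spec)
        x = np.random.default_rng(2).normal(size=(3, 32, 3))
        before = model.predict_proba(x)
        save_checkpoint(model, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt")
        np.testing.assert_allclose(back.predict_proba(x), before, atol=1e-6)

    def test_checkpoint_spec_mismatch_raises(self, tmp_path, tiny_spec):
        model = build_network(tiny_spec)
        save_checkpoint(model, tmp_path / "ckpt")
        other = network_spec_from_hyperparameters(
            input_shape=(32, 3), n_blocks=2, filters=16,
            kernel_sizes=[2, 3, 4], dilations=[1, 2], dropout=0.05,
            n_classes=4)
        import json
        sidecar = tmp_path / "ckpt.json"
        sidecar.write_text(json.dumps({"network_spec": other.to_dict()}))
        with pytest.raises(ValueError, match="mismatch"):
            load_checkpoint(tmp_path / "ckpt")


class TestReceptiveField:
    def test_single_conv_examples(self):
        assert conv_chain_receptive_field([(3, 2)]) == 5
        assert conv_chain_receptive_field([(3, 1)]) == 3
        assert conv_chain_receptive_field([(1, 1), (1, 4)]) == 1

    def test_pooling_scales_later_increments(self):
        # conv k=3 then pool/2 then conv k=3: 3 + 1 + 2*2 = 8
        assert conv_chain_receptive_field([(3, 1), (3, 1)],
                                          pools=[(1, 2)]) == 8

    def test_doubling_dilations_grows_field(self, tiny_spec):
        base = receptive_field(tiny_spec)
        doubled = network_spec_from_hyperparameters(
            input_shape=(32, 3), n_blocks=2, filters=8,
            kernel_sizes=[2, 3, 4], dilations=[1, 2, 4], dropout=0.05,
            n_classes=4)
        assert receptive_field(doubled) > base

    def test_kernel_one_gives_field_one(self):
        assert conv_chain_receptive_field([(1, d) for d in (1, 2, 4, 8)]) == 1
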