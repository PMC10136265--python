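"""Activations, gate equations, forward passes and the training contract."""
import math

import numpy as np
import pytest

from aptanomaly.autoencoders import (
    LSTMAEParams,
    LSTMAutoencoder,
    LSTMCellParams,
    TrainingConfig,
    VanillaAE,
    VanillaAEParams,
    build_network,
    load_model,
    lstm_cell_step,
    reconstruct,
    save_model,
    sigmoid,
    tanh_act,
    train_autoencoder,
    vanilla_forward,
)
from aptanomaly.errors import TrainingDivergenceError, ValidationError
from aptanomaly.signal_model import Quality, Segment, SegmentDataset


class TestActivations:
    def test_sigmoid_values(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(math.log(3)) == pytest.approx(0.75, abs=1e-12)
        assert sigmoid(500.0) == pytest.approx(1.0)
        assert sigmoid(-500.0) == pytest.approx(0.0, abs=1e-12)

    def test_sigmoid_monotone_and_bounded(self, rng):
        z = np.sort(rng.standard_normal(100) * 10)
        s = sigmoid(z)
        assert np.all(np.diff(s) >= 0)
        assert np.all((s > 0) & (s < 1))

    def test_tanh_values_and_oddness(self, rng):
        assert tanh_act(0.0) == 0.0
        assert tanh_act(math.log(2)) == pytest.approx(0.6, abs=1e-12)
        z = rng.standard_normal(50)
        np.testing.assert_allclose(tanh_act(-z), -tanh_act(z), atol=1e-15)


def random_cell(rng, H, F):
    return LSTMCellParams(
        Wfx=rng.standard_normal((H, F)), Wix=rng.standard_normal((H, F)),
        Wox=rng.standard_normal((H, F)), Wcx=rng.standard_normal((H, F)),
        Wfh=rng.standard_normal((H, H)), Wih=rng.standard_normal((H, H)),
        Woh=rng.standard_normal((H, H)), Wch=rng.standard_normal((H, H)),
        bf=rng.standard_normal(H), bi=rng.standard_normal(H),
        bo=rng.standard_normal(H), bc=rng.standard_normal(H),
    )


def scalar_loop_cell_step(p, x, h_prev, c_prev):
    """Independent scalar re-evaluation of the gate equations, one unit at
    a time — no vectorized shortcuts shared with the implementation."""
    H, F = p.hidden_size, p.input_size
    h_t = np.zeros(H)
    c_t = np.zeros(H)
    for j in range(H):
        zf = p.bf[j]; zi = p.bi[j]; zo = p.bo[j]; zc = p.bc[j]
        for k in range(F):
            zf += p.Wfx[j, k] * x[k]
            zi += p.Wix[j, k] * x[k]
            zo += p.Wox[j, k] * x[k]
            zc += p.Wcx[j, k] * x[k]
        for k in range(H):
            zf += p.Wfh[j, k] * h_prev[k]
            zi += p.Wih[j, k] * h_prev[k]
            zo += p.Woh[j, k] * h_prev[k]
            zc += p.Wch[j, k] * h_prev[k]
        f = 1.0 / (1.0 + math.exp(-zf))
        i = 1.0 / (1.0 + math.exp(-zi))
        o = 1.0 / (1.0 + math.exp(-zo))
        g = math.tanh(zc)
        c_t[j] = f * c_prev[j] + i * g
        h_t[j] = o * math.tanh(c_t[j])
    return h_t, c_t


class TestLSTMCell:
    def test_zero_parameters_closed_form(self):
        """All weights/biases zero: every gate is 1/2, the candidate 0, so
        c_t = c_prev / 2 and h_t = tanh(c_t) / 2."""
        H, F = 3, 2
        p = LSTMCellParams(*(np.zeros((H, F)) for _ in range(4)),
                           *(np.zeros((H, H)) for _ in range(4)),
                           *(np.zeros(H) for _ in range(4)))
        x = np.ones(F)
        c_prev = np.array([0.0, 1.0, -2.0])
        h, c = lstm_cell_step(p, x, np.zeros(H), c_prev)
        np.testing.assert_allclose(c, 0.5 * c_prev, atol=1e-15)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev), atol=1e-15)
        assert h[0] == 0.0

    def test_large_forget_bias_saturates(self, rng):
        p = random_cell(rng, 2, 2)
        p.bf[:] = 50.0
        c_prev = np.array([1.0, -1.0])
        # with f ~= 1 the memory survives intact: c_t ~= c_prev + i*g
        _, c = lstm_cell_step(p, np.zeros(2), np.zeros(2), c_prev)
        i = sigmoid(p.bi)
        g = np.tanh(p.bc)
        np.testing.assert_allclose(c, c_prev + i * g, atol=1e-12)

    def test_agrees_with_scalar_loop_oracle(self, rng):
        worst = 0.0
        for _ in range(100):
            H = int(rng.integers(1, 5))
            F = int(rng.integers(1, 5))
            p = random_cell(rng, H, F)
            x = rng.standard_normal(F)
            h0 = rng.standard_normal(H)
            c0 = rng.standard_normal(H)
            h, c = lstm_cell_step(p, x, h0, c0)
            ho, co = scalar_loop_cell_step(p, x, h0, c0)
            worst = max(worst, np.max(np.abs(h - ho)), np.max(np.abs(c - co)))
        assert worst < 1e-12

    def test_shape_mismatch_rejected(self, rng):
        p = random_cell(rng, 3, 2)
        with pytest.raises(ValidationError):
            lstm_cell_step(p, np.zeros(3), np.zeros(3), np.zeros(3))

    def test_packed_layer_matches_cell_steps(self, rng):
        """The batched gate-stacked layer equals step-by-step cell evaluation."""
        from aptanomaly.autoencoders.lstm import LSTMLayer
        layer = LSTMLayer(2, 4)
        layer.initialize(rng)
        layer.b = rng.standard_normal(16)
        X = rng.standard_normal((1, 6, 2))
        out = layer.forward(X)
        p = layer.cell_params()
        h = np.zeros(4); c = np.zeros(4)
        for t in range(6):
            h, c = lstm_cell_step(p, X[0, t], h, c)
            np.testing.assert_allclose(out[0, t], h, atol=1e-12)


class TestVanillaForward:
    def test_zero_weights_emit_decoder_bias(self, rng):
        c = rng.standard_normal(4)
        p = VanillaAEParams(We=np.zeros((2, 4)), be=np.zeros(2),
                            Wd=np.zeros((4, 2)), bd=c)
        _, x_hat = vanilla_forward(p, rng.standard_normal(4))
        np.testing.assert_array_equal(x_hat, c)

    def test_identity_network(self):
        n = 3
        p = VanillaAEParams(We=np.eye(n), be=np.zeros(n), Wd=np.eye(n),
                            bd=np.zeros(n), encoder_activation="identity")
        x = np.array([1.0, -2.0, 0.5])
        z, x_hat = vanilla_forward(p, x)
        np.testing.assert_array_equal(x_hat, x)
        np.testing.assert_array_equal(z, x)

    def test_matches_manual_matrix_arithmetic(self, rng):
        M, N = 3, 6
        p = VanillaAEParams(We=rng.standard_normal((M, N)),
                            be=rng.standard_normal(M),
                            Wd=rng.standard_normal((N, M)),
                            bd=rng.standard_normal(N))
        x = rng.standard_normal(N)
        z, x_hat = vanilla_forward(p, x)
        z_ref = 1.0 / (1.0 + np.exp(-(p.We @ x + p.be)))
        np.testing.assert_allclose(z, z_ref, atol=1e-12)
        np.testing.assert_allclose(x_hat, p.Wd @ z_ref + p.bd, atol=1e-12)

    def test_shape_validation(self):
        with pytest.raises(ValidationError):
            VanillaAEParams(We=np.zeros((2, 4)), be=np.zeros(3),
                            Wd=np.zeros((4, 2)), bd=np.zeros(4))


def toy_dataset(rng, n=20, L=24, constant=None):
    segs = []
    for i in range(n):
        vals = np.full(L, constant) if constant is not None else \
            np.sin(np.linspace(0, 3, L) + rng.uniform(0, 2)) + \
            0.05 * rng.standard_normal(L)
        segs.append(Segment(f"s{i}", "c", vals, Quality.NORMAL))
    return SegmentDataset(segs, segment_length=L, role="train")


class TestTraining:
    @pytest.mark.parametrize("kind", ["vanilla", "ulstm", "blstm"])
    def test_loss_decreases_and_determinism(self, rng, kind):
        ds = toy_dataset(rng)
        cfg = TrainingConfig(max_epochs=4, seed=11)
        net1 = train_autoencoder(kind, ds, cfg)
        assert net1.loss_trace[-1] < net1.loss_trace[0]
        net2 = train_autoencoder(kind, ds, cfg)
        for (k1, v1), (k2, v2) in zip(sorted(net1.parameters().items()),
                                      sorted(net2.parameters().items())):
            assert k1 == k2
            np.testing.assert_array_equal(v1, v2)

    def test_constant_zero_segments_reach_tiny_loss(self, rng):
        ds = toy_dataset(rng, n=10, L=12, constant=0.0)
        net = train_autoencoder("vanilla", ds,
                                TrainingConfig(max_epochs=200, seed=0,
                                               learning_rate=1e-2))
        assert net.loss_trace[-1] < 1e-6

    def test_empty_training_set_rejected(self):
        ds = SegmentDataset([], segment_length=5, role="train")
        with pytest.raises(ValidationError, match="empty"):
            train_autoencoder("vanilla", ds, TrainingConfig(max_epochs=1))

    def test_divergence_reports_epoch(self, rng):
        ds = toy_dataset(rng, n=6, L=10)
        with pytest.raises(TrainingDivergenceError) as exc:
            train_autoencoder("vanilla", ds,
                              TrainingConfig(max_epochs=50, learning_rate=1e160))
        assert exc.value.epoch >= 1

    @pytest.mark.parametrize("kind", ["vanilla", "ulstm", "blstm"])
    def test_reconstruction_length_conserved(self, rng, kind):
        ds = toy_dataset(rng, n=8, L=16)
        net = train_autoencoder(kind, ds, TrainingConfig(max_epochs=1, seed=3))
        out = reconstruct(net, ds)
        assert out.shape == (8, 16)

    def test_length_mismatch_rejected(self, rng):
        ds = toy_dataset(rng, n=4, L=16)
        net = train_autoencoder("vanilla", ds, TrainingConfig(max_epochs=1))
        other = toy_dataset(rng, n=2, L=8)
        with pytest.raises(ValidationError):
            reconstruct(net, other)


class TestBLSTMSymmetry:
    def test_direction_symmetric_network_is_reversal_equivariant(self, rng):
        """With shared forward/backward parameters (and half-symmetric input
        weights downstream) the BLSTM AE commutes with time reversal, so a
        palindromic segment reconstructs to a palindrome."""
        net = LSTMAutoencoder(10, LSTMAEParams("bidirectional",
                                               outer_hidden=3, latent_hidden=2))
        net.initialize(rng)
        for _, layer in net.layers[:3]:
            # share parameters across directions
            layer.bwd.set_parameters(layer.fwd.parameters())
        # make every consumer of a concat treat the two halves identically
        for _, layer in net.layers[1:3]:
            for sub in (layer.fwd, layer.bwd):
                F = sub.input_size
                sub.Wx[F // 2:, :] = sub.Wx[:F // 2, :]
            layer.bwd.set_parameters(layer.fwd.parameters())
        out_layer = net.layers[3][1]
        F = out_layer.input_size
        out_layer.W[F // 2:] = out_layer.W[:F // 2]

        x = rng.standard_normal((1, 10))
        y = net.forward_batch(x)
        y_rev = net.forward_batch(x[:, ::-1])
        np.testing.assert_allclose(y_rev, y[:, ::-1], atol=1e-9)

        pal = np.concatenate([x[0, :5], x[0, :5][::-1]])[None, :]
        y_pal = net.forward_batch(pal)
        np.testing.assert_allclose(y_pal, y_pal[:, ::-1], atol=1e-9)


class TestArtifacts:
    @pytest.mark.parametrize("kind", ["vanilla", "ulstm", "blstm"])
    def test_save_load_round_trip_bit_exact(self, rng, kind, tmp_path):
        ds = toy_dataset(rng, n=6, L=12)
        net = train_autoencoder(kind, ds, TrainingConfig(max_epochs=1, seed=9))
        path = tmp_path / "model.h5"
        save_model(net, path)
        back = load_model(path)
        assert back.kind == kind and back.input_length == 12
        for k, v in net.parameters().items():
            np.testing.assert_array_equal(back.parameters()[k], v)
        assert back.loss_trace == net.loss_trace
        assert back.training_config == net.training_config
        np.testing.assert_array_equal(back.forward_batch(ds.matrix),
                                      net.forward_batch(ds.matrix))
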