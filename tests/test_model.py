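import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scvgatae.autograd import Tensor, glorot
from scvgatae.config import RunConfig
from scvgatae.graph import CellGraph
from scvgatae.model import (
    VGATAE,
    attention_coefficients,
    decode_inner_product,
    gat_layer,
    kl_divergence,
    normalize_adjacency,
)


def _path_graph(n):
    A = np.zeros((n, n))
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1.0
    return A


class TestNormalizeAdjacency:
    def test_single_edge_with_self_loops(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(
            normalize_adjacency(A), [[0.5, 0.5], [0.5, 0.5]], atol=1e-12
        )

    def test_symmetry_preserved(self, rng):
        A = rng.random((6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        An = normalize_adjacency(A)
        np.testing.assert_allclose(An, An.T, atol=1e-12)

    def test_zero_degree_node_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        with pytest.raises(ValueError, match="zero-degree"):
            normalize_adjacency(A, add_self_loops=False)


class TestEncoder:
    def test_zero_weights_give_zero_posterior(self, rng):
        cfg = RunConfig(hidden_dim=4, latent_dim=2)
        model = VGATAE(3, cfg, rng)
        for p in model.params.values():
            p.data[:] = 0.0
        graph = CellGraph(_path_graph(5), 1)
        _, mu, log_sigma, _ = model.forward(rng.random((5, 3)), graph,
                                            training=False)
        np.testing.assert_array_equal(mu.data, 0.0)
        np.testing.assert_array_equal(log_sigma.data, 0.0)

    def test_hand_computed_two_hop_propagation(self):
        # 3-node path graph, 2 features, 1-column weights set by hand
        A = _path_graph(3)
        An = normalize_adjacency(A)  # self-loops on
        Y = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        W0 = np.array([[1.0], [2.0]])
        W1 = np.array([[3.0]])
        H = np.maximum(An @ Y @ W0, 0.0)
        expected_mu = An @ H @ W1
        cfg = RunConfig(hidden_dim=1, latent_dim=1)
        model = VGATAE(2, cfg, np.random.default_rng(0))
        model.params["W0"].data = W0
        model.params["W1"].data = W1
        _, mu, _, _ = model.forward(Y, CellGraph(A, 1), training=False)
        np.testing.assert_allclose(mu.data, expected_mu, atol=1e-8)

    def test_permutation_equivariance(self, rng):
        n = 10
        A = _path_graph(n) + np.eye(n, k=3)[:n, :n]
        A = (A + A.T).clip(0, 1)
        np.fill_diagonal(A, 0.0)
        Y = rng.random((n, 4))
        cfg = RunConfig(hidden_dim=6, latent_dim=3)
        model = VGATAE(4, cfg, np.random.default_rng(1))
        recon, mu, _, _ = model.forward(Y, CellGraph(A, 1), training=False)
        perm = rng.permutation(n)
        recon_p, mu_p, _, _ = model.forward(
            Y[perm], CellGraph(A[np.ix_(perm, perm)], 1), training=False
        )
        np.testing.assert_allclose(mu_p.data, mu.data[perm], atol=1e-10)
        np.testing.assert_allclose(recon_p.data, recon.data[perm], atol=1e-10)


class TestReparameterize:
    def test_eval_mode_returns_mean(self, rng):
        mu = Tensor(rng.random((4, 3)))
        Z, eps = VGATAE.reparameterize(mu, Tensor(np.zeros((4, 3))), None, False)
        assert eps is None
        np.testing.assert_array_equal(Z.data, mu.data)

    def test_zero_sigma_limit_returns_mean(self, rng):
        mu = Tensor(rng.random((4, 3)))
        log_sigma = Tensor(np.full((4, 3), -745.0))  # exp underflows to 0
        Z, _ = VGATAE.reparameterize(mu, log_sigma, np.random.default_rng(0), True)
        np.testing.assert_array_equal(Z.data, mu.data)

    def test_seeded_draws_are_identical(self, rng):
        mu = Tensor(rng.random((5, 2)))
        ls = Tensor(rng.random((5, 2)))
        Z1, _ = VGATAE.reparameterize(mu, ls, np.random.default_rng(7), True)
        Z2, _ = VGATAE.reparameterize(mu, ls, np.random.default_rng(7), True)
        np.testing.assert_array_equal(Z1.data, Z2.data)

    def test_sample_mean_centered_on_mu(self):
        mu = Tensor(np.zeros((100_000, 1)))
        ls = Tensor(np.zeros((100_000, 1)))  # sigma = 1
        Z, _ = VGATAE.reparameterize(mu, ls, np.random.default_rng(3), True)
        dev = (Z.data - mu.data).mean()
        assert abs(dev) < 3.0 / np.sqrt(100_000)


class TestGatLayer:
    def test_isolated_node_attends_to_itself(self, rng):
        H = rng.random((3, 2))
        W = rng.random((2, 2))
        a = rng.random(4)
        mask = np.eye(3, dtype=bool)
        attn = attention_coefficients(H, mask, W, a)
        np.testing.assert_allclose(np.diag(attn), 1.0)
        out = gat_layer(Tensor(H), mask, Tensor(W),
                        Tensor(a.reshape(-1, 1)), activation="identity")
        np.testing.assert_allclose(out.data, H @ W, atol=1e-12)

    def test_identical_features_give_uniform_attention(self):
        H = np.ones((4, 2))
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        a = np.array([1.0, -1.0, 0.5, 0.5])
        mask = np.ones((4, 4), dtype=bool)
        attn = attention_coefficients(H, mask, W, a)
        np.testing.assert_allclose(attn, 0.25, atol=1e-12)

    def test_attention_matches_hand_evaluation(self, rng):
        H = rng.random((3, 2))
        W = rng.random((2, 2))
        a = rng.random(4)
        mask = (_path_graph(3) + np.eye(3)).astype(bool)
        attn = attention_coefficients(H, mask, W, a, slope=0.2)
        HW = H @ W
        e = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                concat = np.concatenate([HW[i], HW[j]])
                v = a @ concat
                e[i, j] = v if v > 0 else 0.2 * v
        expected = np.zeros((3, 3))
        for i in range(3):
            nbrs = np.flatnonzero(mask[i])
            w = np.exp(e[i, nbrs])
            expected[i, nbrs] = w / w.sum()
        np.testing.assert_allclose(attn, expected, atol=1e-8)

    def test_attention_rows_sum_to_one(self, rng):
        H = rng.random((6, 3))
        mask = rng.random((6, 6)) < 0.4
        np.fill_diagonal(mask, True)
        attn = attention_coefficients(H, mask, rng.random((3, 4)), rng.random(8))
        np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-8)


class TestDecoders:
    def test_gat_decoder_zero_input_zero_params_gives_zero(self, rng):
        cfg = RunConfig(hidden_dim=3, latent_dim=2)
        model = VGATAE(4, cfg, rng)
        for name in ("dec_b1", "dec_b2"):
            model.params[name].data[:] = 0.0
        mask = np.ones((5, 5), dtype=bool)
        out = model.decode(Tensor(np.zeros((5, 2))), mask)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)
        assert out.data.shape == (5, 4)

    def test_single_node_collapses_to_dense_layers(self, rng):
        cfg = RunConfig(hidden_dim=3, latent_dim=2)
        model = VGATAE(4, cfg, np.random.default_rng(0))
        mask = np.ones((1, 1), dtype=bool)
        Z = rng.random((1, 2))
        out = model.decode(Tensor(Z), mask)
        p = model.params
        h = Z @ p["dec_W1"].data + p["dec_b1"].data
        h = np.where(h > 0, h, np.expm1(h))
        expected = h @ p["dec_W2"].data + p["dec_b2"].data
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_inner_product_of_zero_latent_is_half(self):
        out = decode_inner_product(Tensor(np.zeros((4, 2))))
        np.testing.assert_allclose(out.data, 0.5)
        np.testing.assert_allclose(out.data, out.data.T)

    def test_inner_product_hand_value(self):
        Z = Tensor(np.array([[1.0], [2.0]]))
        out = decode_inner_product(Z)
        assert out.data[0, 1] == pytest.approx(1 / (1 + np.exp(-2.0)))


class TestLoss:
    @pytest.fixture
    def model(self):
        return VGATAE(3, RunConfig(hidden_dim=4, latent_dim=2),
                      np.random.default_rng(0))

    def test_perfect_reconstruction_has_zero_mse(self, model, rng):
        Y = rng.random((5, 3))
        _, value = model.loss(Y, Tensor(Y.copy()), Tensor(np.zeros((5, 2))),
                              Tensor(np.zeros((5, 2))))
        assert value.mse == 0.0

    def test_standard_normal_posterior_has_zero_kl(self, model, rng):
        Y = rng.random((5, 3))
        _, value = model.loss(Y, Tensor(Y.copy()), Tensor(np.zeros((5, 2))),
                              Tensor(np.zeros((5, 2))))
        assert value.kl == 0.0

    def test_kl_spot_value_half(self, model, rng):
        # one cell, mu=[1,0], sigma=[1,1] -> KL = 0.5
        Y = rng.random((1, 3))
        _, value = model.loss(Y, Tensor(Y.copy()),
                              Tensor(np.array([[1.0, 0.0]])),
                              Tensor(np.zeros((1, 2))))
        assert value.kl == pytest.approx(0.5)

    def test_total_is_weighted_sum(self, rng):
        cfg = RunConfig(hidden_dim=4, latent_dim=2, loss_alpha=2.0, loss_beta=3.0)
        model = VGATAE(3, cfg, np.random.default_rng(0))
        Y = rng.random((4, 3))
        recon = Tensor(rng.random((4, 3)))
        mu, ls = Tensor(rng.random((4, 2))), Tensor(rng.random((4, 2)))
        _, value = model.loss(Y, recon, mu, ls)
        assert value.total == pytest.approx(2.0 * value.mse + 3.0 * value.kl)

    def test_mse_is_per_cell_average(self, model, rng):
        Y = np.zeros((4, 3))
        recon = Tensor(np.ones((4, 3)))
        _, value = model.loss(Y, recon, Tensor(np.zeros((4, 2))),
                              Tensor(np.zeros((4, 2))))
        assert value.mse == pytest.approx(12.0 / 4.0)  # squared norm / n

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_kl_nonnegative_property(self, seed):
        r = np.random.default_rng(seed)
        mu = Tensor(r.standard_normal((6, 4)) * 3)
        ls = Tensor(r.standard_normal((6, 4)) * 2)
        assert kl_divergence(mu, ls).data >= 0.0


class TestGradients:
    def _finite_diff(self, f, param, idx, h=1e-6):
        old = param.data[idx]
        param.data[idx] = old + h
        up = f()
        param.data[idx] = old - h
        down = f()
        param.data[idx] = old
        return (up - down) / (2 * h)

    @pytest.mark.parametrize("pname,idx", [
        ("W0", (0, 0)), ("W1", (1, 0)), ("W2", (0, 1)),
        ("dec_W1", (0, 0)), ("dec_a1", (2, 0)), ("dec_b2", (1,)),
    ])
    def test_backprop_matches_finite_difference(self, pname, idx):
        # 5-node instance, deterministic draw shared across passes
        rng = np.random.default_rng(0)
        cfg = RunConfig(hidden_dim=3, latent_dim=2)
        model = VGATAE(4, cfg, rng)
        A = _path_graph(5)
        A[0, 4] = A[4, 0] = 1.0
        graph = CellGraph(A, 1)
        Y = np.random.default_rng(1).random((5, 4))
        eps = np.random.default_rng(2).standard_normal((5, 2))

        def loss_value():
            class FixedRng:
                def standard_normal(self, shape):
                    return eps
            recon, mu, ls, _ = model.forward(Y, graph, rng=FixedRng(),
                                             training=True)
            total, _ = model.loss(Y, recon, mu, ls)
            return total

        total = loss_value()
        for p in model.param_list():
            p.grad = None
        total.backward()
        analytic = model.params[pname].grad[idx]
        numeric = self._finite_diff(lambda: loss_value().data, model.params[pname], idx)
        assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        cfg = RunConfig(hidden_dim=4, latent_dim=2)
        m1 = VGATAE(3, cfg, np.random.default_rng(0))
        m1.save(tmp_path / "ckpt.npz")
        m2 = VGATAE(3, cfg, np.random.default_rng(99))
        m2.load(tmp_path / "ckpt.npz")
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)
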