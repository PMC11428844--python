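"""The variational graph attention autoencoder.

Encoder: a two-layer GCN over the symmetrically normalized cell graph that
outputs a Gaussian posterior (mu, log sigma) per cell; the two heads share
the first layer. A latent sample Z = mu + eps * sigma is drawn with the
reparameterization trick and decoded back to the PCA feature space by two
stacked graph-attention layers. An inner-product decoder (sigmoid of the
latent Gram matrix, reconstructing the cell graph itself) is kept as an
ablation variant, as is an all-attention encoder whose GCN layers are
replaced by GAT layers of the same dimensions.

Loss: alpha * reconstruction + beta * KL(N(mu, sigma^2) || N(0, I)), with the
reconstruction averaged per cell (1/n times the squared Frobenius norm) and
the KL term averaged over cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .autograd import Adam, Tensor, glorot, parameter
from .config import RunConfig
from .graph import CellGraph


def normalize_adjacency(A: np.ndarray, add_self_loops: bool = True) -> np.ndarray:
    """GCN normalization D^{-1/2} (A [+ I]) D^{-1/2}.

    Self-loops (on by default) keep each cell's own features in the
    propagation; without them a zero-diagonal graph would discard them.
    """
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("adjacency must be nonnegative")
    if add_self_loops:
        A = A + np.eye(A.shape[0])
    deg = A.sum(axis=1)
    if (deg == 0).any():
        raise ValueError("zero-degree node in adjacency")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return A * np.outer(d_inv_sqrt, d_inv_sqrt)


@dataclass
class LatentState:
    """Per-cell Gaussian posterior and the sampled embedding."""

    mu: np.ndarray
    log_sigma: np.ndarray
    Z: np.ndarray
    epsilon: Optional[np.ndarray]


@dataclass
class LossValue:
    total: float
    mse: float
    kl: float
    alpha_w: float
    beta_w: float


def gat_layer(H: Tensor, mask: np.ndarray, W: Tensor, a: Tensor,
              bias: Optional[Tensor] = None, activation: str = "identity",
              slope: float = 0.2) -> Tensor:
    """One graph-attention layer.

    Scores e_ij = LeakyReLU(a^T [W h_i || W h_j]) over the neighborhoods given
    by `mask` (boolean n x n, self-inclusion expected), softmax-normalized per
    row, then a weighted sum of transformed neighbor features.

    `a` has shape (2 * out_dim, 1): its first half scores the source cell, the
    second half the neighbor.
    """
    HW = H @ W  # n x f'
    f = W.shape[1]
    src = HW @ a[:f]          # n x 1
    dst = (HW @ a[f:]).T      # 1 x n
    e = (src + dst).leaky_relu(slope)
    attn = e.masked_softmax(mask)
    out = attn @ HW
    if bias is not None:
        out = out + bias
    if activation == "elu":
        return out.elu()
    if activation == "relu":
        return out.relu()
    if activation == "identity":
        return out
    raise ValueError(f"unknown activation {activation!r}")


def attention_coefficients(H: np.ndarray, mask: np.ndarray, W: np.ndarray,
                           a: np.ndarray, slope: float = 0.2) -> np.ndarray:
    """The attention matrix of a GAT layer, for inspection and testing."""
    HW = H @ W
    f = W.shape[1]
    a = np.asarray(a).reshape(-1)
    e = (HW @ a[:f])[:, None] + (HW @ a[f:])[None, :]
    e = np.where(e > 0, e, slope * e)
    neg = np.where(mask, e, -np.inf)
    expd = np.where(mask, np.exp(neg - neg.max(axis=1, keepdims=True)), 0.0)
    return expd / expd.sum(axis=1, keepdims=True)


class VGATAE:
    """Full model: encoder + reparameterization + decoder + loss."""

    def __init__(self, in_dim: int, cfg: RunConfig, rng: np.random.Generator):
        self.in_dim = in_dim
        self.hidden = cfg.hidden_dim
        self.latent = cfg.latent_dim
        self.slope = cfg.leaky_relu_slope
        self.decoder_kind = cfg.decoder
        self.encoder_kind = "gat" if cfg.ablation == "all_attention" else "gcn"
        self.reconstruction = cfg.reconstruction
        self.alpha_w = cfg.loss_alpha
        self.beta_w = cfg.loss_beta
        h, b, d = self.hidden, self.latent, in_dim

        self.params: dict[str, Tensor] = {}
        if self.encoder_kind == "gcn":
            self._add("W0", glorot((d, h), rng))
            self._add("W1", glorot((h, b), rng))
            self._add("W2", glorot((h, b), rng))
        else:  # all-attention encoder: GAT layers of identical dims
            self._add("enc_W0", glorot((d, h), rng))
            self._add("enc_a0", glorot((2 * h, 1), rng))
            self._add("enc_Wmu", glorot((h, b), rng))
            self._add("enc_amu", glorot((2 * b, 1), rng))
            self._add("enc_Wsig", glorot((h, b), rng))
            self._add("enc_asig", glorot((2 * b, 1), rng))
        if self.decoder_kind == "gat":
            self._add("dec_W1", glorot((b, h), rng))
            self._add("dec_a1", glorot((2 * h, 1), rng))
            self._add("dec_b1", parameter(np.zeros(h)))
            self._add("dec_W2", glorot((h, d), rng))
            self._add("dec_a2", glorot((2 * d, 1), rng))
            self._add("dec_b2", parameter(np.zeros(d)))
        elif self.decoder_kind != "inner_product":
            raise ValueError(f"unknown decoder {self.decoder_kind!r}")

    def _add(self, name: str, tensor: Tensor) -> None:
        self.params[name] = tensor

    def param_list(self) -> list:
        return list(self.params.values())

    # -- forward pieces ----------------------------------------------------

    def encode(self, Y: Tensor, A_norm: Tensor, mask: np.ndarray):
        if self.encoder_kind == "gcn":
            H = (A_norm @ Y @ self.params["W0"]).relu()
            mu = A_norm @ H @ self.params["W1"]
            log_sigma = A_norm @ H @ self.params["W2"]
        else:
            p = self.params
            H = gat_layer(Y, mask, p["enc_W0"], p["enc_a0"],
                          activation="relu", slope=self.slope)
            mu = gat_layer(H, mask, p["enc_Wmu"], p["enc_amu"],
                           activation="identity", slope=self.slope)
            log_sigma = gat_layer(H, mask, p["enc_Wsig"], p["enc_asig"],
                                  activation="identity", slope=self.slope)
        return mu, log_sigma

    @staticmethod
    def reparameterize(mu: Tensor, log_sigma: Tensor,
                       rng: Optional[np.random.Generator],
                       training: bool) -> tuple[Tensor, Optional[np.ndarray]]:
        """Z = mu + eps * sigma in training; Z = mu in evaluation."""
        if not training:
            return mu, None
        eps = rng.standard_normal(mu.shape)
        return mu + Tensor(eps) * log_sigma.exp(), eps

    def decode(self, Z: Tensor, mask: np.ndarray) -> Tensor:
        if self.decoder_kind == "inner_product":
            return decode_inner_product(Z)
        p = self.params
        H = gat_layer(Z, mask, p["dec_W1"], p["dec_a1"], p["dec_b1"],
                      activation="elu", slope=self.slope)
        return gat_layer(H, mask, p["dec_W2"], p["dec_a2"], p["dec_b2"],
                         activation="identity", slope=self.slope)

    def forward(self, Y: np.ndarray, graph: CellGraph,
                rng: Optional[np.random.Generator] = None,
                training: bool = True,
                add_self_loops: bool = True):
        """One full pass; returns (reconstruction, mu, log_sigma, Z) Tensors."""
        A_norm = Tensor(normalize_adjacency(graph.A, add_self_loops))
        mask = (graph.A != 0) | np.eye(graph.A.shape[0], dtype=bool)
        Yt = Tensor(Y)
        mu, log_sigma = self.encode(Yt, A_norm, mask)
        Z, eps = self.reparameterize(mu, log_sigma, rng, training)
        recon = self.decode(Z, mask)
        for t in (recon, mu, log_sigma):
            if not np.isfinite(t.data).all():
                raise FloatingPointError("non-finite values in forward pass")
        return recon, mu, log_sigma, Z

    def loss(self, target: np.ndarray, recon: Tensor, mu: Tensor,
             log_sigma: Tensor) -> tuple[Tensor, LossValue]:
        """Composite loss; `target` is Y for the GAT decoder and the cell
        graph A for the inner-product (graph-reconstructing) decoder."""
        n = mu.shape[0]
        diff = Tensor(target) - recon
        if self.reconstruction == "mae":
            rec = diff.abs().sum() * (1.0 / n)
        else:
            rec = diff.square().sum() * (1.0 / n)
        kl = kl_divergence(mu, log_sigma)
        total = self.alpha_w * rec + self.beta_w * kl
        value = LossValue(float(total.data), float(rec.data), float(kl.data),
                          self.alpha_w, self.beta_w)
        return total, value

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        np.savez(Path(path), **{k: v.data for k, v in self.params.items()})

    def load(self, path) -> None:
        with np.load(Path(path)) as archive:
            for k in self.params:
                self.params[k].data = archive[k]

    def state(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_state(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()


def decode_inner_product(Z: Tensor) -> Tensor:
    """sigmoid(Z Z^T): graph reconstruction from the latent Gram matrix."""
    return (Z @ Z.T).sigmoid()


def kl_divergence(mu: Tensor, log_sigma: Tensor) -> Tensor:
    """KL(N(mu, sigma^2) || N(0, I)) summed over latent dims, averaged over
    cells: (1/n) * 0.5 * sum(mu^2 + sigma^2 - 2*log sigma - 1)."""
    n = mu.shape[0]
    sigma_sq = (log_sigma * 2.0).exp()
    terms = mu.square() + sigma_sq - log_sigma * 2.0 - 1.0
    return terms.sum() * (0.5 / n)
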