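"""Mixed-neighbourhood graph convolutional encoder.

A standard graph convolution only mixes first-order neighbours per layer.
Here every layer aggregates over *all* neighbourhood orders 1..n at once:
for each order ``i`` the binarized i-step reachability matrix ``Abar^i``
(entry 1 wherever ``A^i`` is nonzero) is symmetrically normalised with a
self-loop, ``Atilde^i = Dtilde^-1/2 (Abar^i + I) Dtilde^-1/2``, and the layer
output is the concatenation over orders of ``relu(Atilde^i @ H @ W_i)``.
In the bipartite association graph odd orders reach heterogeneous
(circRNA<->drug) neighbours and even orders homogeneous ones, so the
concatenation mixes both views in every layer.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _autodiff as ad
from .config import RunConfig


def mixed_adjacency(A: np.ndarray, order: int) -> np.ndarray:
    """Binarized ``order``-step reachability matrix of a binary adjacency."""
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    A = np.asarray(A, dtype=float)
    power = np.linalg.matrix_power(A, order)
    return (power != 0).astype(float)


def normalize_adjacency(Abar: np.ndarray) -> np.ndarray:
    """Symmetric normalisation with self-loops: ``D^-1/2 (Abar + I) D^-1/2``."""
    Abar = np.asarray(Abar, dtype=float)
    if Abar.ndim != 2 or Abar.shape[0] != Abar.shape[1]:
        raise ValueError("adjacency must be square")
    with_loops = Abar + np.eye(Abar.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(with_loops.sum(axis=1))
    return d_inv_sqrt[:, None] * with_loops * d_inv_sqrt[None, :]


@dataclasses.dataclass
class EncoderState:
    """Trainable weights and fixed normalised adjacencies of the encoder.

    ``weights[l][i]`` is the trainable matrix of layer ``l`` and order
    ``i + 1``; the embedding width is ``len(orders) * per_order_dim``.
    """

    weights: list[list[np.ndarray]]
    adjacencies: list[np.ndarray]
    orders: list[int]
    per_order_dim: int

    @property
    def embedding_dim(self) -> int:
        return len(self.orders) * self.per_order_dim


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_encoder(
    A: np.ndarray, input_dim: int, config: RunConfig, rng: np.random.Generator
) -> EncoderState:
    """Build normalised adjacencies for orders 1..n and Xavier-init weights."""
    n = 1 if config.variant == "no_mn" else config.max_order
    orders = list(range(1, n + 1))
    adjacencies = [normalize_adjacency(mixed_adjacency(A, k)) for k in orders]
    weights: list[list[np.ndarray]] = []
    dim = input_dim
    for _ in range(config.num_mixed_layers):
        layer = [xavier_uniform(rng, dim, config.per_order_dim) for _ in orders]
        weights.append(layer)
        dim = len(orders) * config.per_order_dim
    return EncoderState(
        weights=weights, adjacencies=adjacencies, orders=orders,
        per_order_dim=config.per_order_dim,
    )


def encoder_forward_ad(
    state: EncoderState, X: ad.Tensor, params: list[list[ad.Tensor]]
) -> ad.Tensor:
    """Differentiable forward pass given weight tensors ``params``."""
    H = X
    for layer in params:
        branches = [
            ad.relu(ad.Tensor(At) @ H @ W) for At, W in zip(state.adjacencies, layer)
        ]
        H = ad.concat(branches, axis=1)
    return H


def encoder_forward(state: EncoderState, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass returning plain embeddings ``H``."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != state.adjacencies[0].shape[0]:
        raise ValueError(
            f"feature matrix has {X.shape[0]} rows but the graph has "
            f"{state.adjacencies[0].shape[0]} nodes"
        )
    params = [[ad.Tensor(W) for W in layer] for layer in state.weights]
    return encoder_forward_ad(state, ad.Tensor(X), params).value
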