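"""Graph contrastive objective in the deep-graph-infomax style.

A corrupted view of the graph keeps the adjacency but row-shuffles the
feature matrix.  A readout summarises node embeddings into a graph-level
vector ``s = sigmoid(mean_i H_i)`` and a bilinear critic
``Gamma(h, s) = sigmoid(h^T W s)`` scores how well a node embedding matches
the summary.  Two symmetric binary cross-entropy losses push real nodes
toward their own graph summary and corrupted nodes away from it (L2), and
vice versa against the corrupted summary (L3).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from . import _autodiff as ad

EPS = 1e-7


def corrupt(X: np.ndarray, seed: int) -> np.ndarray:
    """Row-shuffle the feature matrix with a seeded uniform permutation."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(X.shape[0])
    return np.asarray(X, dtype=float)[perm]


def readout(H: np.ndarray) -> np.ndarray:
    """Graph-level summary: sigmoid of the column-wise mean of H."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("readout requires a nonempty 2-D embedding matrix")
    return expit(H.mean(axis=0))


def discriminate(h: np.ndarray, s: np.ndarray, W: np.ndarray) -> float:
    """Bilinear critic ``sigmoid(h^T W s)`` in (0, 1)."""
    h = np.asarray(h, dtype=float)
    s = np.asarray(s, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape != (h.shape[0], s.shape[0]):
        raise ValueError(f"bilinear weight shape {W.shape} does not match ({h.shape[0]}, {s.shape[0]})")
    return float(expit(h @ W @ s))


def contrastive_losses_ad(
    H: ad.Tensor, H_corrupt: ad.Tensor, W: ad.Tensor
) -> tuple[ad.Tensor, ad.Tensor]:
    """Differentiable (L2, L3) given embeddings of the real and corrupted graph."""
    if H.shape != H_corrupt.shape:
        raise ValueError(f"embedding shape mismatch: {H.shape} vs {H_corrupt.shape}")
    n_nodes, k = H.shape
    s = ad.reshape(ad.sigmoid(ad.tmean(H, axis=0)), (k, 1))
    s_tilde = ad.reshape(ad.sigmoid(ad.tmean(H_corrupt, axis=0)), (k, 1))

    def bce(pos_logits: ad.Tensor, neg_logits: ad.Tensor) -> ad.Tensor:
        # -log(sigmoid(x)) = softplus(-x) and -log(1 - sigmoid(x)) = softplus(x),
        # evaluated in softplus form so saturated critic outputs keep gradients
        total = ad.tsum(ad.softplus(ad.neg(pos_logits))) + ad.tsum(ad.softplus(neg_logits))
        return (1.0 / (2.0 * n_nodes)) * total

    L2 = bce(H @ W @ s, H_corrupt @ W @ s)
    L3 = bce(H_corrupt @ W @ s_tilde, H @ W @ s_tilde)
    return L2, L3


def contrastive_losses(
    H: np.ndarray, H_corrupt: np.ndarray, W: np.ndarray
) -> tuple[float, float]:
    """Numeric (L2, L3) for given embeddings and bilinear weight."""
    L2, L3 = contrastive_losses_ad(ad.Tensor(H), ad.Tensor(H_corrupt), ad.Tensor(W))
    return L2.item(), L3.item()
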