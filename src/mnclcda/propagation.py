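"""Random walk with restart smoothing and initial feature-graph assembly.

Similarity matrices are noisy; propagating them with a random walk with
restart (RWR) mixes each node's similarity profile with its network
neighbourhood, retaining local signal while injecting global structure.
For node ``l`` the walk iterates ``r <- c * W_tilde @ r + (1 - c) * e_l``
where ``W_tilde`` is the column-normalised similarity matrix and ``e_l`` is
the l-th similarity row normalised to a distribution; the fixed point is the
closed form ``(1 - c) * (I - c W_tilde)^-1 e_l``.  With these normalisations
every output row is itself a probability distribution.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import RunConfig
from .similarity import SimilarityBundle


@dataclasses.dataclass
class FeatureGraph:
    """Bipartite adjacency and the block feature matrix fed to the encoder.

    ``A = [[0, Y], [Y^T, 0]]`` and ``X = [[Fc, Y], [Y^T, Fd]]`` where Fc, Fd
    are the RWR-smoothed circRNA and drug similarity matrices.
    """

    A: np.ndarray
    X: np.ndarray
    Fc: np.ndarray
    Fd: np.ndarray


def rwr(S: np.ndarray, c: float, tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Random walk with restart on a similarity matrix, all nodes at once.

    Returns a matrix whose l-th row is the converged visiting distribution of
    a walker restarting at node l.  Output rows sum to one.
    """
    if not 0.0 < c < 1.0:
        raise ValueError(f"restart probability must lie in (0,1), got {c}")
    S = np.asarray(S, dtype=float)
    if (S < 0).any():
        raise ValueError("similarity matrix must be nonnegative")
    row_sums = S.sum(axis=1)
    col_sums = S.sum(axis=0)
    if (row_sums <= 0).any() or (col_sums <= 0).any():
        bad = int(np.argmin(row_sums if (row_sums <= 0).any() else col_sums))
        raise ValueError(f"similarity matrix has a zero row/column (index {bad})")
    W = S / col_sums[None, :]          # column-stochastic transition matrix
    E = (S / row_sums[:, None]).T      # restart vectors as columns
    R = E.copy()
    for _ in range(max_iter):
        R_next = c * (W @ R) + (1.0 - c) * E
        delta = np.abs(R_next - R).sum(axis=0).max()
        R = R_next
        if delta < tol:
            break
    return R.T


def rwr_closed_form(S: np.ndarray, c: float) -> np.ndarray:
    """Dense linear-solve form of :func:`rwr`; reference for small problems."""
    S = np.asarray(S, dtype=float)
    W = S / S.sum(axis=0)[None, :]
    E = (S / S.sum(axis=1)[:, None]).T
    n = S.shape[0]
    R = (1.0 - c) * np.linalg.solve(np.eye(n) - c * W, E)
    return R.T


def pca2d_features(S: np.ndarray, n_components: int) -> np.ndarray:
    """Two-dimensional-PCA smoothing of a similarity matrix.

    Projects the rows of ``S`` onto the top ``n_components`` eigenvectors of
    the column covariance and back, giving a rank-reduced reconstruction of
    the same shape.  Used by the "no RWR" ablation variant in place of the
    random-walk smoothing.
    """
    S = np.asarray(S, dtype=float)
    centered = S - S.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / max(S.shape[0] - 1, 1)
    _, vecs = np.linalg.eigh(cov)
    V = vecs[:, -n_components:]
    return S @ V @ V.T


def build_feature_graph(
    bundle: SimilarityBundle, Y_train: np.ndarray, config: RunConfig
) -> FeatureGraph:
    """Assemble the bipartite adjacency A and initial feature matrix X."""
    Y = np.asarray(Y_train, dtype=float)
    nc, nd = Y.shape
    if bundle.CS.shape != (nc, nc) or bundle.DS.shape != (nd, nd):
        raise ValueError("similarity bundle and Y_train dimensions are inconsistent")
    if config.variant == "no_rwr":
        Fc = pca2d_features(bundle.CS, config.pca_components)
        Fd = pca2d_features(bundle.DS, config.pca_components)
    else:
        Fc = rwr(bundle.CS, config.restart_prob, config.rwr_tol, config.rwr_max_iter)
        Fd = rwr(bundle.DS, config.restart_prob, config.rwr_tol, config.rwr_max_iter)
    A = np.block([[np.zeros((nc, nc)), Y], [Y.T, np.zeros((nd, nd))]])
    X = np.block([[Fc, Y], [Y.T, Fd]])
    return FeatureGraph(A=A, X=X, Fc=Fc, Fd=Fd)
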