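"""Dual Laplacian-regularized least-squares link predictor.

Embeddings are turned into Gaussian kernels ``Kc`` (circRNA space) and
``Kd`` (drug space).  The predictor minimises

    L1 = || Kc Wc + (Kd Wd)^T - 2 Y_train ||_F^2
         + lambda_c tr(Wc^T Lc Wc) + lambda_d tr(Wd^T Ld Wd)

where Lc, Ld are symmetric normalised Laplacians of the kernels.  The
objective is a convex quadratic in each coefficient block, so alternating
the two closed-form solves

    Wc = (Kc Kc + lambda_c Lc)^-1 Kc (2 Y_train   - (Kd Wd)^T)
    Wd = (Kd Kd + lambda_d Ld)^-1 Kd (2 Y_train^T - (Kc Wc)^T)

is exact coordinate descent.  Final scores are
``A* = (Kc Wc + (Kd Wd)^T) / 2``, which targets ``Y_train``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from . import _autodiff as ad


@dataclasses.dataclass
class PredictorState:
    """Kernels, Laplacians, solved coefficients and the score matrix."""

    Kc: np.ndarray
    Kd: np.ndarray
    Lc: np.ndarray
    Ld: np.ndarray
    Wc: np.ndarray
    Wd: np.ndarray
    A_star: np.ndarray


def embedding_kernel(E: np.ndarray, gamma_h: float) -> np.ndarray:
    """Gaussian kernel ``K[i,j] = exp(-gamma_h ||E_i - E_j||^2)`` on embedding rows."""
    if gamma_h <= 0:
        raise ValueError("gamma_h must be > 0")
    E = np.asarray(E, dtype=float)
    if not np.isfinite(E).all():
        raise ValueError("embeddings contain non-finite values")
    K = ad.gaussian_kernel(ad.Tensor(E), gamma_h).value
    return (K + K.T) / 2.0


def normalized_laplacian(K: np.ndarray) -> np.ndarray:
    """Symmetric normalised Laplacian ``D^-1/2 (D - K) D^-1/2`` of a kernel."""
    K = np.asarray(K, dtype=float)
    d = K.sum(axis=1)
    if (d <= 0).any():
        raise ValueError(f"kernel row {int(np.argmin(d))} has non-positive sum")
    d_inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(K.shape[0]) - d_inv_sqrt[:, None] * K * d_inv_sqrt[None, :]
    return (L + L.T) / 2.0


def laprls_loss(
    Kc: np.ndarray,
    Kd: np.ndarray,
    Wc: np.ndarray,
    Wd: np.ndarray,
    Lc: np.ndarray,
    Ld: np.ndarray,
    Y_train: np.ndarray,
    lambda_c: float,
    lambda_d: float,
) -> float:
    """Evaluate the dual Laplacian-regularized least-squares objective."""
    R = Kc @ Wc + (Kd @ Wd).T - 2.0 * Y_train
    loss = (R**2).sum()
    loss += lambda_c * np.trace(Wc.T @ Lc @ Wc)
    loss += lambda_d * np.trace(Wd.T @ Ld @ Wd)
    return float(loss)


def _solve(M: np.ndarray, rhs: np.ndarray, jitter: float, name: str) -> np.ndarray:
    M = M + jitter * np.eye(M.shape[0])
    try:
        return scipy.linalg.solve(M, rhs, assume_a="sym")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - needs exact singularity
        raise np.linalg.LinAlgError(f"singular system while solving for {name}: {exc}")


def solve_wc(
    Kc: np.ndarray,
    Lc: np.ndarray,
    Kd: np.ndarray,
    Wd: np.ndarray,
    Y_train: np.ndarray,
    lambda_c: float,
    jitter: float = 0.0,
) -> np.ndarray:
    """Closed-form minimiser of L1 in Wc with Wd held fixed."""
    rhs = Kc @ (2.0 * Y_train - (Kd @ Wd).T)
    return _solve(Kc @ Kc + lambda_c * Lc, rhs, jitter, "Wc")


def solve_wd(
    Kd: np.ndarray,
    Ld: np.ndarray,
    Kc: np.ndarray,
    Wc: np.ndarray,
    Y_train: np.ndarray,
    lambda_d: float,
    jitter: float = 0.0,
) -> np.ndarray:
    """Closed-form minimiser of L1 in Wd with Wc held fixed."""
    rhs = Kd @ (2.0 * Y_train.T - (Kc @ Wc).T)
    return _solve(Kd @ Kd + lambda_d * Ld, rhs, jitter, "Wd")


def alternate_solve(
    Kc: np.ndarray,
    Kd: np.ndarray,
    Lc: np.ndarray,
    Ld: np.ndarray,
    Y_train: np.ndarray,
    lambda_c: float,
    lambda_d: float,
    sweeps: int = 2,
    jitter: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate the two closed-form solves; L1 is non-increasing per solve."""
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    nc, nd = Y_train.shape
    Wc = np.zeros((nc, nd))
    Wd = np.zeros((nd, nc))
    for _ in range(sweeps):
        Wc = solve_wc(Kc, Lc, Kd, Wd, Y_train, lambda_c, jitter)
        Wd = solve_wd(Kd, Ld, Kc, Wc, Y_train, lambda_d, jitter)
    return Wc, Wd


def score_matrix(Kc: np.ndarray, Wc: np.ndarray, Kd: np.ndarray, Wd: np.ndarray) -> np.ndarray:
    """Final association scores ``A* = (Kc Wc + (Kd Wd)^T) / 2``."""
    return (Kc @ Wc + (Kd @ Wd).T) / 2.0


def fit_predictor(
    Hc: np.ndarray,
    Hd: np.ndarray,
    Y_train: np.ndarray,
    gamma_h: float,
    lambda_c: float,
    lambda_d: float,
    sweeps: int = 2,
    jitter: float = 1e-6,
) -> PredictorState:
    """Kernels -> Laplacians -> alternating solves -> scores, in one call."""
    Kc = embedding_kernel(Hc, gamma_h)
    Kd = embedding_kernel(Hd, gamma_h)
    Lc = normalized_laplacian(Kc)
    Ld = normalized_laplacian(Kd)
    Wc, Wd = alternate_solve(Kc, Kd, Lc, Ld, Y_train, lambda_c, lambda_d, sweeps, jitter)
    return PredictorState(
        Kc=Kc, Kd=Kd, Lc=Lc, Ld=Ld, Wc=Wc, Wd=Wd,
        A_star=score_matrix(Kc, Wc, Kd, Wd),
    )


def laprls_loss_ad(
    Kc: ad.Tensor,
    Kd: ad.Tensor,
    Wc: np.ndarray,
    Wd: np.ndarray,
    Y_train: np.ndarray,
    lambda_c: float,
    lambda_d: float,
) -> ad.Tensor:
    """Differentiable L1 as a function of the kernels (coefficients fixed).

    The Laplacian penalty uses the identity
    ``tr(W^T L W) = tr(W^T W) - tr(W^T D^-1/2 K D^-1/2 W)`` so that the
    normalised Laplacian never has to be materialised in the graph.
    """
    R = Kc @ Wc + ad.transpose(Kd @ Wd) - 2.0 * Y_train

    def penalty(K: ad.Tensor, W: np.ndarray, lam: float) -> ad.Tensor:
        n = K.shape[0]
        d_inv_sqrt = ad.power(ad.tsum(K, axis=1), -0.5)
        Kn = K * ad.reshape(d_inv_sqrt, (n, 1)) * ad.reshape(d_inv_sqrt, (1, n))
        return lam * (float((W**2).sum()) - ad.tsum((Kn @ W) * ad.Tensor(W)))

    loss = ad.tsum(R * R)
    loss = loss + penalty(Kc, Wc, lambda_c) + penalty(Kd, Wd, lambda_d)
    return loss
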