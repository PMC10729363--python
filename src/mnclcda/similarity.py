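"""Similarity matrices: sequence, structure, interaction-profile, integrated.

Four similarity views feed the model:

* ``SC`` — circRNA sequence similarity, ``1 - lev(s_i, s_j)/(|s_i| + |s_j|)``
  with unit-cost Levenshtein distance ``lev``;
* ``SD`` — drug structural similarity, Tanimoto coefficient on binary
  topological fingerprints;
* ``GC``/``GD`` — Gaussian interaction-profile (GIP) kernels on the rows and
  columns of the training association matrix, with bandwidth set to the
  reciprocal mean squared profile norm;
* ``CS``/``DS`` — entrywise average of the biological and GIP similarity
  where the biological one is observed, the GIP value where it is missing.

GIP kernels are always computed from the *training* association matrix so
that held-out test associations never leak into the features.
"""

from __future__ import annotations

import dataclasses

import edlib
import numpy as np

from .data import AssociationDataset


@dataclasses.dataclass
class SimilarityBundle:
    """All pairwise similarity matrices for one training split."""

    SC: np.ndarray
    SD: np.ndarray
    GC: np.ndarray
    GD: np.ndarray
    CS: np.ndarray
    DS: np.ndarray
    r_c: float
    r_d: float


def sequence_similarity(s_i: str, s_j: str) -> float:
    """Levenshtein-based similarity ``1 - lev/(len_i + len_j)`` in [0, 1]."""
    if not s_i or not s_j:
        raise ValueError("sequence similarity is undefined for empty sequences")
    dist = edlib.align(s_i, s_j, task="distance")["editDistance"]
    return 1.0 - dist / (len(s_i) + len(s_j))


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b|; 0 for two all-zero vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def gip_kernel(profiles: np.ndarray, axis_label: str = "circ") -> tuple[np.ndarray, float]:
    """Gaussian interaction-profile kernel over the rows of ``profiles``.

    The bandwidth is ``r = 1 / mean_i ||profile_i||^2`` and
    ``K(i, j) = exp(-r * ||profile_i - profile_j||^2)``.  For drugs, pass the
    transposed association matrix so that profiles are its columns.
    """
    P = np.asarray(profiles, dtype=float)
    sq_norms = (P**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq <= 0:
        raise ValueError(
            f"GIP bandwidth undefined for {axis_label}: all interaction profiles are zero"
        )
    r = 1.0 / mean_sq
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(sq_dist, 0.0, out=sq_dist)
    K = np.exp(-r * sq_dist)
    return (K + K.T) / 2.0, float(r)


def integrate(S: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Average S and G where S is observed (nonzero); G elsewhere.

    The zero test identifies *missing* biological similarity: Levenshtein and
    Tanimoto similarities of real data are essentially never exactly zero, so
    an exact-zero entry means the corresponding annotation was absent.
    """
    S = np.asarray(S, dtype=float)
    G = np.asarray(G, dtype=float)
    if S.shape != G.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {G.shape}")
    return np.where(S != 0.0, (S + G) / 2.0, G)


def sequence_similarity_matrix(
    sequences: dict[str, str] | None, circ_ids: list[str]
) -> np.ndarray:
    """All-pairs sequence similarity aligned to ``circ_ids``.

    Rows/columns of circRNAs without a sequence are left zero (degraded mode,
    handled by :func:`integrate`).
    """
    n = len(circ_ids)
    SC = np.zeros((n, n))
    if not sequences:
        return SC
    for i, ci in enumerate(circ_ids):
        si = sequences.get(ci)
        if si is None:
            continue
        SC[i, i] = 1.0
        for j in range(i + 1, n):
            sj = sequences.get(circ_ids[j])
            if sj is None:
                continue
            SC[i, j] = SC[j, i] = sequence_similarity(si, sj)
    return SC


def structure_similarity_matrix(fingerprints: np.ndarray | None, n_drug: int) -> np.ndarray:
    """All-pairs Tanimoto similarity; unit diagonal even for empty fingerprints."""
    SD = np.zeros((n_drug, n_drug))
    if fingerprints is None:
        return SD
    fp = np.asarray(fingerprints, dtype=bool)
    np.fill_diagonal(SD, 1.0)
    for i in range(n_drug):
        for j in range(i + 1, n_drug):
            SD[i, j] = SD[j, i] = tanimoto(fp[i], fp[j])
    return SD


def build_similarity_bundle(dataset: AssociationDataset, Y_train: np.ndarray) -> SimilarityBundle:
    """Assemble SC, SD, GC, GD and the integrated CS, DS for one split."""
    Y_train = np.asarray(Y_train, dtype=float)
    if Y_train.shape != dataset.Y.shape:
        raise ValueError("Y_train shape does not match the dataset")
    GC, r_c = gip_kernel(Y_train, "circ")
    GD, r_d = gip_kernel(Y_train.T, "drug")
    SC = sequence_similarity_matrix(dataset.sequences, dataset.circ_ids)
    SD = structure_similarity_matrix(dataset.fingerprints, dataset.n_drug)
    CS = integrate(SC, GC)
    DS = integrate(SD, GD)
    return SimilarityBundle(SC=SC, SD=SD, GC=GC, GD=GD, CS=CS, DS=DS, r_c=r_c, r_d=r_d)
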