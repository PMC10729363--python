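"""Joint training of the encoder, contrastive critic and predictor.

The total objective is ``L = L1 + alpha * L2 + beta * L3``.  Each epoch:

1. forward the encoder on the feature graph to get embeddings ``H``;
2. compute embedding kernels ``Kc``, ``Kd``;
3. obtain ``Wc``, ``Wd`` by the exact alternating closed-form solves,
   treating the kernels as constants (the solves are exactly optimal given
   the kernels, so their gradient contribution through the optimality
   conditions vanishes to first order);
4. evaluate L1 with gradients flowing through the kernels into the encoder,
   and L2, L3 on a fresh feature corruption;
5. take an adaptive-moment (Adam) step with weight decay on the encoder and
   critic weights.

The "no_lr" ablation variant replaces steps 2-4 with an inner-product
decoder ``sigmoid(Hc Hd^T)`` trained by binary cross-entropy.
"""

from __future__ import annotations

import dataclasses
import pickle
from pathlib import Path
from typing import Any

import numpy as np

from . import _autodiff as ad
from .config import RunConfig
from .contrastive import contrastive_losses_ad, corrupt
from .data import AssociationDataset
from .encoder import EncoderState, encoder_forward_ad, init_encoder, xavier_uniform
from .predictor import (
    PredictorState,
    alternate_solve,
    fit_predictor,
    laprls_loss_ad,
    normalized_laplacian,
)
from .propagation import FeatureGraph, build_feature_graph
from .similarity import build_similarity_bundle


class AdamOptimizer:
    """Adaptive-moment estimation with coupled L2 weight decay."""

    def __init__(self, params: list[ad.Tensor], lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            grad = p.grad if p.grad is not None else np.zeros_like(p.value)
            grad = grad + self.weight_decay * p.value
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * grad**2
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p.value = p.value - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclasses.dataclass
class TrainedModel:
    """Everything needed to score associations and audit a training run."""

    config: RunConfig
    encoder: EncoderState
    discriminator: np.ndarray
    predictor: PredictorState | None
    H: np.ndarray
    n_circ: int
    n_drug: int
    history: list[dict[str, float]]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {"schema": 1, "model": self}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("schema") != 1:
            raise ValueError(f"unsupported model schema: {payload.get('schema')!r}")
        return payload["model"]


def _bce_loss_ad(Hc: ad.Tensor, Hd: ad.Tensor, Y_train: np.ndarray) -> ad.Tensor:
    """Full-matrix binary cross-entropy of the inner-product decoder.

    Evaluated on the logits (mean softplus(z) - y*z) so saturated entries
    keep gradients.
    """
    Z = Hc @ ad.transpose(Hd)
    loss = ad.tsum(ad.softplus(Z)) - ad.tsum(ad.Tensor(Y_train) * Z)
    return (1.0 / Y_train.size) * loss


def train(
    dataset: AssociationDataset,
    Y_train: np.ndarray | None = None,
    config: RunConfig | None = None,
    graph: FeatureGraph | None = None,
) -> TrainedModel:
    """Train the full model (or an ablation variant) on one training matrix.

    ``Y_train`` defaults to the dataset's full association matrix; during
    cross-validation pass the fold-masked matrix so that held-out positives
    influence neither the similarity bundle nor the feature graph.
    """
    config = config or RunConfig()
    Y_train = dataset.Y if Y_train is None else np.asarray(Y_train, dtype=float)
    if Y_train.sum() < 1:
        raise ValueError("training matrix must contain at least one positive entry")
    if graph is None:
        bundle = build_similarity_bundle(dataset, Y_train)
        graph = build_feature_graph(bundle, Y_train, config)
    nc, nd = Y_train.shape

    rng = config.stage_rng("init")
    encoder = init_encoder(graph.A, graph.X.shape[1], config, rng)
    k = encoder.embedding_dim
    disc_W = xavier_uniform(rng, k, k)

    params = [[ad.parameter(W) for W in layer] for layer in encoder.weights]
    disc = ad.parameter(disc_W)
    flat_params = [w for layer in params for w in layer] + [disc]
    opt = AdamOptimizer(flat_params, config.learning_rate, config.weight_decay)

    use_cl = config.variant != "no_cl" and (config.alpha > 0 or config.beta > 0)
    corruption_seed = config.stage_seed("corruption")
    X = graph.X
    history: list[dict[str, float]] = []

    for epoch in range(config.epochs):
        opt.zero_grad()
        Xt = ad.Tensor(X)
        H = encoder_forward_ad(encoder, Xt, params)
        Hc = ad.rows(H, 0, nc)
        Hd = ad.rows(H, nc, nc + nd)

        if config.variant == "no_lr":
            L1 = _bce_loss_ad(Hc, Hd, Y_train)
        else:
            Kc_t = ad.gaussian_kernel(Hc, config.gamma_h)
            Kd_t = ad.gaussian_kernel(Hd, config.gamma_h)
            Kc, Kd = Kc_t.value, Kd_t.value
            Lc = normalized_laplacian(Kc)
            Ld = normalized_laplacian(Kd)
            Wc, Wd = alternate_solve(
                Kc, Kd, Lc, Ld, Y_train, config.lambda_c, config.lambda_d,
                config.solver_sweeps, config.jitter,
            )
            L1 = laprls_loss_ad(Kc_t, Kd_t, Wc, Wd, Y_train,
                                config.lambda_c, config.lambda_d)

        if use_cl:
            X_tilde = corrupt(X, corruption_seed + epoch)
            H_tilde = encoder_forward_ad(encoder, ad.Tensor(X_tilde), params)
            L2, L3 = contrastive_losses_ad(H, H_tilde, disc)
            total = L1 + config.alpha * L2 + config.beta * L3
            l2_val, l3_val = L2.item(), L3.item()
        else:
            total = L1
            l2_val = l3_val = 0.0

        if not np.isfinite(total.item()):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        total.backward()
        opt.step()
        history.append({"L": total.item(), "L1": L1.item(), "L2": l2_val, "L3": l3_val})

    # freeze trained weights back into the encoder state and fit the predictor
    encoder.weights = [[w.value.copy() for w in layer] for layer in params]
    H_final = encoder_forward_ad(
        encoder, ad.Tensor(X),
        [[ad.Tensor(w.value) for w in layer] for layer in params],
    ).value
    predictor: PredictorState | None
    if config.variant == "no_lr":
        predictor = None
    else:
        predictor = fit_predictor(
            H_final[:nc], H_final[nc:], Y_train, config.gamma_h,
            config.lambda_c, config.lambda_d, config.solver_sweeps, config.jitter,
        )
    return TrainedModel(
        config=config, encoder=encoder, discriminator=disc.value.copy(),
        predictor=predictor, H=H_final, n_circ=nc, n_drug=nd, history=history,
    )


def predict(model: TrainedModel, dataset: AssociationDataset | None = None) -> np.ndarray:
    """Score matrix of a trained model; bit-for-bit repeatable."""
    if model.predictor is not None:
        return model.predictor.A_star.copy()
    Hc = model.H[: model.n_circ]
    Hd = model.H[model.n_circ :]
    return 1.0 / (1.0 + np.exp(-(Hc @ Hd.T)))
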