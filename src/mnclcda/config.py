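"""Run configuration for the MNCLCDA pipeline.

All tunable parameters of the method live in :class:`RunConfig`.  The defaults
are the settings reported to work best on the circRic/GDSC benchmark
(restart probability ``c = 0.3``, mixed-neighbourhood order ``n = 3``,
embedding-kernel bandwidth ``gamma_h = 2**-5``, Laplacian weights
``lambda_c = 2**-1`` and ``lambda_d = 2**-3``, Adam with learning rate 0.005
and weight decay 1e-5, Xavier initialisation).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Any

import numpy as np
import yaml

#: ablation variants selectable through :attr:`RunConfig.variant`
VARIANTS = ("full", "no_rwr", "no_mn", "no_cl", "no_lr")


@dataclasses.dataclass
class RunConfig:
    """Hyper-parameters and numerical settings of a single run.

    Parameters
    ----------
    restart_prob:
        Restart probability ``c`` of the random walk with restart, in (0, 1).
    max_order:
        Highest neighbourhood order ``n`` aggregated by the mixed-neighbourhood
        graph convolution.
    gamma_h:
        Bandwidth of the Gaussian kernel computed on the learned embeddings.
    lambda_c, lambda_d:
        Weights of the circRNA-side and drug-side Laplacian penalties in the
        least-squares objective.
    alpha, beta:
        Weights of the two contrastive loss terms in the total objective
        ``L = L1 + alpha*L2 + beta*L3``.
    per_order_dim:
        Output width of each per-order convolution branch; the embedding width
        is ``max_order * per_order_dim``.
    """

    restart_prob: float = 0.3
    max_order: int = 3
    gamma_h: float = 2.0 ** -5
    lambda_c: float = 2.0 ** -1
    lambda_d: float = 2.0 ** -3
    alpha: float = 0.5
    beta: float = 0.5
    per_order_dim: int = 64
    num_mixed_layers: int = 2
    epochs: int = 300
    learning_rate: float = 0.005
    weight_decay: float = 1e-5
    seed: int = 0
    rwr_tol: float = 1e-6
    rwr_max_iter: int = 100
    jitter: float = 1e-6
    threshold: float = 0.5
    solver_sweeps: int = 2
    fingerprint_bits: int = 2048
    pca_components: int = 2
    variant: str = "full"

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob < 1.0:
            raise ValueError(f"restart_prob must lie in (0,1), got {self.restart_prob}")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if self.gamma_h <= 0:
            raise ValueError("gamma_h must be > 0")
        for name in ("lambda_c", "lambda_d", "alpha", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.per_order_dim < 1 or self.num_mixed_layers < 1:
            raise ValueError("per_order_dim and num_mixed_layers must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    # -- seeding ---------------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        """Derive a deterministic per-stage seed from the root seed.

        Every source of randomness in the pipeline (fold plans, negative
        sampling, weight init, corruption shuffles) draws from a seed produced
        here, so one root seed fixes the whole run.
        """
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode()) % (2**31)])
        return int(ss.generate_state(1)[0] % (2**31))

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.stage_seed(stage))

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON (decided by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if data is None:
            data = {}
        return cls.from_dict(data)

    def replace(self, **changes: Any) -> "RunConfig":
        return dataclasses.replace(self, **changes)
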