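import numpy as np
import pytest

from mnclcda.config import RunConfig
from mnclcda.data import AssociationDataset
from mnclcda.synthetic import SyntheticSpec, generate


@pytest.fixture
def toy_dataset() -> AssociationDataset:
    """2x2 identity associations with sequences and fingerprints."""
    return AssociationDataset(
        circ_ids=["c1", "c2"],
        drug_ids=["d1", "d2"],
        Y=np.array([[1.0, 0.0], [0.0, 1.0]]),
        sequences={"c1": "ACGT", "c2": "ACGA"},
        fingerprints=np.array([[1, 1, 0], [1, 0, 1]], dtype=float),
    )


@pytest.fixture
def small_planted():
    """Desk-scale planted dataset small enough for training inside unit tests."""
    spec = SyntheticSpec(Nc=20, Nd=14, groups=2, seed=7)
    dataset, truth = generate(spec)
    return dataset, truth


@pytest.fixture
def small_config() -> RunConfig:
    return RunConfig(epochs=25, per_order_dim=8, num_mixed_layers=1, seed=3)


def levenshtein_dp(a: str, b: str) -> int:
    """Independent dynamic-programming edit-distance oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def auc_bruteforce(scores, labels) -> float:
    """Pairwise-comparison AUC oracle with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
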