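"""Synthetic benchmark generator with planted block structure.

Real circRNA-drug benchmarks couple three data channels: associations,
host-gene sequences and drug fingerprints.  The generator plants a shared
group structure across all three so each similarity channel is genuinely
informative about the association matrix: circRNAs and drugs are assigned
to one of ``g`` groups; a circRNA-drug pair is associated with probability
``p_in`` when their groups match and ``p_out`` otherwise; sequences are
per-group prototypes with i.i.d. substitutions; fingerprints are per-group
prototype bit vectors with i.i.d. bit flips.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .data import AssociationDataset

_ALPHABET = np.array(list("ACGT"))


@dataclasses.dataclass
class SyntheticSpec:
    """Generation parameters; defaults give a desk-scale planted benchmark."""

    Nc: int = 60
    Nd: int = 40
    groups: int = 3
    p_in: float = 0.3
    p_out: float = 0.02
    seq_len: int = 120
    mutation_rate: float = 0.1
    fp_bits: int = 64
    fp_flip_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.groups > min(self.Nc, self.Nd):
            raise ValueError("more groups than circRNAs or drugs")
        for name in ("p_in", "p_out", "mutation_rate", "fp_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if not self.p_in > self.p_out:
            raise ValueError("planted signal requires p_in > p_out")


def _mutate(prototype: np.ndarray, rate: float, rng: np.random.Generator) -> str:
    seq = prototype.copy()
    mask = rng.random(len(seq)) < rate
    if mask.any():
        seq[mask] = _ALPHABET[rng.integers(0, 4, size=int(mask.sum()))]
    return "".join(seq)


def generate(spec: SyntheticSpec) -> tuple[AssociationDataset, dict]:
    """Generate a dataset plus the ground-truth group assignments."""
    rng = np.random.default_rng(spec.seed)
    circ_groups = rng.integers(0, spec.groups, size=spec.Nc)
    drug_groups = rng.integers(0, spec.groups, size=spec.Nd)

    match = circ_groups[:, None] == drug_groups[None, :]
    prob = np.where(match, spec.p_in, spec.p_out)
    Y = (rng.random((spec.Nc, spec.Nd)) < prob).astype(float)

    seq_protos = [_ALPHABET[rng.integers(0, 4, size=spec.seq_len)] for _ in range(spec.groups)]
    fp_protos = [rng.integers(0, 2, size=spec.fp_bits) for _ in range(spec.groups)]

    circ_ids = [f"circ{i:03d}" for i in range(spec.Nc)]
    drug_ids = [f"drug{j:03d}" for j in range(spec.Nd)]
    sequences = {
        cid: _mutate(seq_protos[g], spec.mutation_rate, rng)
        for cid, g in zip(circ_ids, circ_groups)
    }
    fingerprints = np.empty((spec.Nd, spec.fp_bits))
    for j, g in enumerate(drug_groups):
        flips = rng.random(spec.fp_bits) < spec.fp_flip_rate
        fingerprints[j] = np.where(flips, 1 - fp_protos[g], fp_protos[g])

    dataset = AssociationDataset(
        circ_ids=circ_ids, drug_ids=drug_ids, Y=Y,
        sequences=sequences, fingerprints=fingerprints,
    )
    truth = {
        "circ_groups": circ_groups.tolist(),
        "drug_groups": drug_groups.tolist(),
        "spec": dataclasses.asdict(spec),
    }
    return dataset, truth


def shuffle_labels(dataset: AssociationDataset, seed: int) -> AssociationDataset:
    """Null control: permute all entries of Y, destroying the planted signal."""
    rng = np.random.default_rng(seed)
    flat = dataset.Y.flatten()
    rng.shuffle(flat)
    return AssociationDataset(
        circ_ids=list(dataset.circ_ids), drug_ids=list(dataset.drug_ids),
        Y=flat.reshape(dataset.Y.shape),
        sequences=dict(dataset.sequences) if dataset.sequences else None,
        fingerprints=None if dataset.fingerprints is None else dataset.fingerprints.copy(),
    )


def write_dataset(dataset: AssociationDataset, truth: dict | None, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as association CSV, FASTA, fingerprint CSV, truth JSON."""
    import json

    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    assoc = out_dir / "associations.csv"
    pd.DataFrame(dataset.Y.astype(int), index=dataset.circ_ids,
                 columns=dataset.drug_ids).to_csv(assoc)
    paths["associations"] = assoc
    if dataset.sequences:
        fasta = out_dir / "sequences.fasta"
        with open(fasta, "w") as fh:
            for cid in dataset.circ_ids:
                if cid in dataset.sequences:
                    fh.write(f">{cid}\n{dataset.sequences[cid]}\n")
        paths["sequences"] = fasta
    if dataset.fingerprints is not None:
        fp = out_dir / "fingerprints.csv"
        pd.DataFrame(dataset.fingerprints.astype(int), index=dataset.drug_ids).to_csv(fp)
        paths["fingerprints"] = fp
    if truth is not None:
        truth_path = out_dir / "truth.json"
        truth_path.write_text(json.dumps(truth, indent=2))
        paths["truth"] = truth_path
    return paths


def fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write the tiny toy instances used throughout the unit tests."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    identity = out_dir / "identity_2x2.csv"
    identity.write_text(",d1,d2\nc1,1,0\nc2,0,1\n")
    paths["identity_2x2"] = identity

    toy32 = out_dir / "toy_3x2.csv"
    toy32.write_text(",d1,d2\nc1,1,0\nc2,0,1\nc3,1,1\n")
    paths["toy_3x2"] = toy32

    fasta = out_dir / "toy.fasta"
    fasta.write_text(">c1\nACGT\n>c2\nACGA\n>c3\nTTTT\n")
    paths["toy_fasta"] = fasta

    fp = out_dir / "toy_fingerprints.csv"
    fp.write_text("id,b0,b1,b2\nd1,1,1,0\nd2,1,0,1\n")
    paths["toy_fingerprints"] = fp
    return paths
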