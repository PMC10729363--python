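"""Input/output for association tables, sequences, drug structures and results.

The association table is a dense id-labelled CSV/TSV (rows = circRNAs,
columns = drugs) rather than a sparse triplet list: benchmark-scale matrices
are small and explicit labels prevent orientation mistakes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclasses.dataclass
class AssociationDataset:
    """A circRNA x drug binary association matrix with optional annotations.

    ``Y[i, j] == 1`` records that circRNA ``circ_ids[i]`` is associated with
    the sensitivity of drug ``drug_ids[j]``.  Sequences are host-gene
    nucleotide strings over {A, C, G, T, N}; fingerprints are binary bit
    vectors aligned to ``drug_ids``.
    """

    circ_ids: list[str]
    drug_ids: list[str]
    Y: np.ndarray
    sequences: dict[str, str] | None = None
    fingerprints: np.ndarray | None = None
    smiles: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.validate()

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    @property
    def n_drug(self) -> int:
        return len(self.drug_ids)

    def validate(self) -> None:
        if len(set(self.circ_ids)) != len(self.circ_ids):
            raise ValidationError("duplicate circRNA ids")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValidationError("duplicate drug ids")
        if self.Y.ndim != 2 or self.Y.shape != (len(self.circ_ids), len(self.drug_ids)):
            raise ValidationError(
                f"Y shape {self.Y.shape} does not match ids "
                f"({len(self.circ_ids)} x {len(self.drug_ids)})"
            )
        if self.Y.size == 0:
            raise ValidationError("empty association matrix")
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValidationError("association matrix entries must be 0 or 1")
        if self.sequences is not None:
            unknown = set(self.sequences) - set(self.circ_ids)
            if unknown:
                raise ValidationError(f"sequences for unknown circRNA ids: {sorted(unknown)}")
        if self.fingerprints is not None:
            fp = np.asarray(self.fingerprints)
            if fp.shape[0] != len(self.drug_ids):
                raise ValidationError(
                    f"fingerprint rows ({fp.shape[0]}) != number of drugs ({len(self.drug_ids)})"
                )
            if not np.isin(fp, (0, 1)).all():
                raise ValidationError("fingerprints must be binary")
        if self.smiles is not None:
            unknown = set(self.smiles) - set(self.drug_ids)
            if unknown:
                raise ValidationError(f"SMILES for unknown drug ids: {sorted(unknown)}")


def read_association_table(path: str | Path, dialect: str = "csv") -> AssociationDataset:
    """Read an id-labelled binary association table.

    First row holds drug ids, first column circRNA ids, body cells 0/1.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"association table {path} has an empty body")
    circ_ids = [str(i) for i in df.index]
    drug_ids = [str(c) for c in df.columns]
    Y = np.empty(df.shape, dtype=float)
    for i, cid in enumerate(circ_ids):
        for j, did in enumerate(drug_ids):
            cell = str(df.iat[i, j]).strip()
            if cell not in ("0", "1"):
                raise FormatError(
                    f"non-binary cell {cell!r} at row {cid!r}, column {did!r} in {path}"
                )
            Y[i, j] = float(cell)
    return AssociationDataset(circ_ids=circ_ids, drug_ids=drug_ids, Y=Y)


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read FASTA sequences; ids are headers up to the first whitespace.

    Sequences are uppercased and U is mapped to T so RNA and DNA input are
    interchangeable for edit-distance purposes.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        if record.id in out:
            raise FormatError(f"duplicate FASTA header {record.id!r} in {path}")
        if not seq:
            raise FormatError(f"empty sequence for record {record.id!r} in {path}")
        out[record.id] = seq
    if not out:
        raise FormatError(f"no FASTA records found in {path}")
    return out


def _fingerprint_from_smiles(smiles: str, drug_id: str, n_bits: int) -> np.ndarray:
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormatError(f"unparseable SMILES for drug {drug_id!r}: {smiles!r}")
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=float)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


def read_drug_structures(
    path: str | Path,
    drug_ids: list[str] | None = None,
    n_bits: int = 2048,
) -> tuple[np.ndarray, dict[str, str] | None]:
    """Read drug structures as id,SMILES pairs or an explicit 0/1 matrix.

    A two-column file (id, SMILES) is converted to topological path-based
    fingerprints; a wider file is taken as a precomputed binary fingerprint
    matrix with drug-id row labels.  Rows are aligned to ``drug_ids`` when
    given.  Returns ``(fingerprints, smiles_map_or_None)``.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    ids = [str(i) for i in df.index]
    if drug_ids is not None:
        missing = set(drug_ids) - set(ids)
        if missing:
            raise ValidationError(f"structures missing for drugs: {sorted(missing)}")
        order = drug_ids
    else:
        order = ids
    if df.shape[1] == 1:
        smiles = {i: str(v).strip() for i, v in zip(ids, df.iloc[:, 0])}
        rows = [_fingerprint_from_smiles(smiles[i], i, n_bits) for i in order]
        return np.vstack(rows), {i: smiles[i] for i in order}
    mat = df.astype(float).to_numpy()
    if not np.isin(mat, (0.0, 1.0)).all():
        raise FormatError(f"fingerprint matrix {path} contains non-binary values")
    lengths = {len(row) for row in mat}
    if len(lengths) != 1:
        raise FormatError("fingerprint rows have inconsistent lengths")
    index = {i: k for k, i in enumerate(ids)}
    return mat[[index[i] for i in order]], None


def write_outputs(
    scores: np.ndarray,
    metrics: Mapping[str, float] | None,
    out_dir: str | Path,
    circ_ids: list[str],
    drug_ids: list[str],
) -> dict[str, Path]:
    """Write the score matrix (labelled CSV) and a metrics JSON to ``out_dir``.

    Round-tripping the score table through :func:`read_score_table` reproduces
    the values to 1e-12.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    score_path = out_dir / "scores.csv"
    pd.DataFrame(np.asarray(scores, dtype=float), index=circ_ids, columns=drug_ids).to_csv(
        score_path, float_format="%.17g"
    )
    paths["scores"] = score_path
    if metrics is not None:
        metrics_path = out_dir / "metrics.json"
        metrics_path.write_text(json.dumps({k: float(v) for k, v in metrics.items()}, indent=2))
        paths["metrics"] = metrics_path
    return paths


def read_score_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_ranked_list(rows: list[tuple[int, str, float]], path: str | Path) -> None:
    """Write a ranked candidate list as TSV with columns rank, circRNA, score."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("rank\tcircRNA\tscore\n")
        for rank, cid, score in rows:
            fh.write(f"{rank}\t{cid}\t{score:.17g}\n")
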