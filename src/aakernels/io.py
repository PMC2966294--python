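"""Sequence, label-table and Gram-matrix I/O.

Peptide binding data arrives as a TSV of peptides with either measured
IC50 affinities or explicit ±1 labels. Following the usual convention for
MHC class I binding data, peptides with IC50 strictly greater than 500
(nM) are non-binders and all others — including exactly 500 — binders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .descriptors import STANDARD_ALPHABET, Alphabet
from .gram import GramMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Sequence",
    "LabeledDataset",
    "read_fasta",
    "write_fasta",
    "read_peptide_table",
    "write_peptide_table",
    "label_from_ic50",
    "write_gram",
    "read_gram",
]

IC50_THRESHOLD = 500.0


@dataclass(frozen=True)
class Sequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass
class LabeledDataset:
    """Sequences with ±1 labels, optional IC50 values and group/family ids."""

    sequences: list[Sequence]
    labels: np.ndarray
    ic50: np.ndarray | None = None
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in length")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 or -1")
        if self.ic50 is not None:
            self.ic50 = np.asarray(self.ic50, dtype=float)
            if len(self.ic50) != len(self.sequences):
                raise ValueError("ic50 and sequences differ in length")
        if self.groups is not None and len(self.groups) != len(self.sequences):
            raise ValueError("groups and sequences differ in length")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def residues(self) -> list[str]:
        return [s.residues for s in self.sequences]


def read_fasta(
    path: str | Path,
    alphabet: Alphabet | None = None,
    on_invalid: str = "drop",
) -> list[Sequence]:
    """Read a FASTA file into Sequence records (ids up to first whitespace).

    With an alphabet given, records containing other residues are either
    dropped with a warning (``on_invalid="drop"``, the default) or rejected
    with an error (``"error"``). Residues are uppercased.
    """
    if on_invalid not in ("drop", "error"):
        raise ValueError("on_invalid must be 'drop' or 'error'")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if alphabet is not None:
            bad = sorted({c for c in residues if c not in alphabet})
            if bad:
                msg = f"{path}: record {rec.id!r} has residues outside the alphabet: {bad}"
                if on_invalid == "error":
                    raise ValueError(msg)
                logger.warning("%s — record dropped", msg)
                continue
        out.append(Sequence(rec.id, residues))
    return out


def write_fasta(path: str | Path, seqs: list[Sequence]) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def label_from_ic50(ic50: float, threshold: float = IC50_THRESHOLD) -> int:
    """−1 (non-binder) iff IC50 strictly exceeds the threshold, else +1."""
    return -1 if ic50 > threshold else 1


def read_peptide_table(path: str | Path, threshold: float = IC50_THRESHOLD) -> LabeledDataset:
    """Read a peptide TSV with columns ``peptide`` and ``ic50`` or ``label``.

    With an ``ic50`` column, labels are derived via the threshold rule;
    an explicit ``label`` column (±1) is passed through. An optional ``id``
    column names the peptides.
    """
    df = pd.read_csv(path, sep="\t")
    if "peptide" not in df.columns:
        raise ValueError(f"{path}: missing required column 'peptide'")
    ids = df["id"].astype(str).tolist() if "id" in df.columns else [
        f"pep{i}" for i in range(len(df))
    ]
    seqs = [Sequence(i, str(p).upper()) for i, p in zip(ids, df["peptide"])]
    if "ic50" in df.columns:
        ic50 = pd.to_numeric(df["ic50"], errors="coerce")
        if ic50.isna().any():
            row = int(ic50.index[ic50.isna()][0]) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric IC50 at line {row}")
        ic50 = ic50.to_numpy(dtype=float)
        labels = np.where(ic50 > threshold, -1, 1)
        return LabeledDataset(seqs, labels, ic50=ic50)
    if "label" in df.columns:
        labels = df["label"].astype(int).to_numpy()
        return LabeledDataset(seqs, labels)
    raise ValueError(f"{path}: need an 'ic50' or 'label' column")


def write_peptide_table(path: str | Path, ds: LabeledDataset) -> None:
    data = {"id": [s.id for s in ds.sequences], "peptide": ds.residues}
    if ds.ic50 is not None:
        data["ic50"] = ds.ic50
    data["label"] = ds.labels
    if ds.groups is not None:
        data["family"] = ds.groups
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_gram(path: str | Path, gm: GramMatrix) -> None:
    """Write a Gram matrix as TSV (header row of ids) plus a config sidecar."""
    import json

    df = pd.DataFrame(gm.values, index=gm.ids, columns=gm.ids)
    df.to_csv(path, sep="\t", float_format="%.17g")
    Path(str(path) + ".json").write_text(json.dumps(gm.spec, indent=2) + "\n")


def read_gram(path: str | Path, atol: float = 1e-8) -> GramMatrix:
    import json

    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: Gram matrix is not square")
    if np.abs(values - values.T).max() > atol:
        raise ValueError(f"{path}: Gram matrix is not symmetric")
    sidecar = Path(str(path) + ".json")
    spec = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return GramMatrix(ids=ids, values=values, spec=spec)
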