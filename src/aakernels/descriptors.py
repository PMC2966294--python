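"""Amino-acid descriptor encodings.

Every kernel in this package compares residues through a feature map
``Ψ: Σ → R^D`` assigning each amino acid a vector of numeric descriptors.
Three physico-chemical descriptor sets ship with the package:

``unit``
    The :math:`|Σ|`-dimensional one-hot encoding. Distinct letters are
    orthogonal, so substring kernels built on it reduce to exact matching.
``pca``
    A 5-dimensional principal-component descriptor set. The shipped table
    (``data/pca_synthetic.tsv``) is a synthetic stand-in computed once as the
    first five principal components of the standardized BLOSUM50 rows; it
    plays the role of a published PCA-of-AAIndex-properties set.
``zscale``
    The classic 3-component z-scales (hydrophilicity, steric bulk,
    electronic properties).
``blosum50``
    Each residue encoded by its 20-entry row of the BLOSUM50 substitution
    matrix (via biopython), so similar residues get similar rows.

Descriptor scales are heterogeneous; :func:`standardize_encoding` z-scores
each coordinate across the alphabet, which matters for RBF distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from importlib import resources
from pathlib import Path

import numpy as np

#: One-letter codes of the 20 standard amino acids, in the fixed
#: alphabetical order used for feature indexing throughout the package.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

BUILTIN_ENCODINGS = ("unit", "pca", "zscale", "blosum50")

#: Builtin descriptor sets standardized by default (the unit encoding is not).
DEFAULT_STANDARDIZE = {"unit": False, "pca": True, "zscale": True, "blosum50": True}


class EncodingError(ValueError):
    """Raised for unknown encodings, malformed tables or illegal letters."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of single-character residue codes."""

    letters: str = STANDARD_AA

    def __post_init__(self) -> None:
        if len(self.letters) < 2:
            raise EncodingError("alphabet needs at least two letters")
        if len(set(self.letters)) != len(self.letters):
            raise EncodingError("alphabet letters must be unique")

    def __len__(self) -> int:
        return len(self.letters)

    def __iter__(self):
        return iter(self.letters)

    def __contains__(self, letter: str) -> bool:
        return letter in self.letters

    def index(self, letter: str) -> int:
        try:
            return self.letters.index(letter)
        except ValueError:
            raise EncodingError(f"letter {letter!r} not in alphabet {self.letters!r}") from None

    def indices(self, s: str) -> np.ndarray:
        """Integer codes of every letter of ``s`` (vectorized lookup)."""
        return np.fromiter((self.index(c) for c in s), dtype=np.intp, count=len(s))


STANDARD_ALPHABET = Alphabet()


@dataclass
class AAEncoding:
    """A feature map Ψ from residue letters to D-dimensional vectors."""

    name: str
    alphabet: Alphabet
    vectors: dict[str, np.ndarray]
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [a for a in self.alphabet if a not in self.vectors]
        if missing:
            raise EncodingError(f"encoding {self.name!r} lacks vectors for {missing}")
        dims = {len(v) for v in self.vectors.values()}
        if len(dims) != 1:
            raise EncodingError(f"encoding {self.name!r} has ragged vector lengths {sorted(dims)}")
        self.vectors = {a: np.asarray(v, dtype=float) for a, v in self.vectors.items()}

    @property
    def dim(self) -> int:
        return len(next(iter(self.vectors.values())))

    @cached_property
    def matrix(self) -> np.ndarray:
        """|Σ| × D matrix of letter vectors, rows in alphabet order."""
        return np.vstack([self.vectors[a] for a in self.alphabet])

    @cached_property
    def dot_table(self) -> np.ndarray:
        """dot_table[i, j] = ⟨Ψ(a_i), Ψ(a_j)⟩."""
        return self.matrix @ self.matrix.T

    @cached_property
    def dist2_table(self) -> np.ndarray:
        """dist2_table[i, j] = ‖Ψ(a_i) − Ψ(a_j)‖²."""
        d = self.dot_table.diagonal()
        t = d[:, None] + d[None, :] - 2.0 * self.dot_table
        return np.maximum(t, 0.0)

    def dot(self, a: str, b: str) -> float:
        return float(self.dot_table[self.alphabet.index(a), self.alphabet.index(b)])

    def dist2(self, a: str, b: str) -> float:
        return float(self.dist2_table[self.alphabet.index(a), self.alphabet.index(b)])


def _read_table(lines, source: str) -> dict[str, np.ndarray]:
    vectors: dict[str, np.ndarray] = {}
    width = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        letter, values = parts[0], parts[1:]
        if width is None:
            width = len(values)
        if len(values) != width or width == 0:
            raise EncodingError(f"{source}: ragged row at line {lineno}")
        try:
            vectors[letter] = np.array([float(v) for v in values])
        except ValueError:
            raise EncodingError(f"{source}: non-numeric entry at line {lineno}") from None
    return vectors


def load_encoding_table(path: str | Path, alphabet: Alphabet = STANDARD_ALPHABET) -> AAEncoding:
    """Load a descriptor table from a TSV file (letter, then numeric columns).

    Rows may appear in any order; lines starting with ``#`` are comments.
    """
    path = Path(path)
    with open(path) as fh:
        vectors = _read_table(fh, str(path))
    missing = [a for a in alphabet if a not in vectors]
    if missing:
        raise EncodingError(f"{path}: table missing letter(s) {missing}")
    vectors = {a: vectors[a] for a in alphabet}
    return AAEncoding(name=path.stem, alphabet=alphabet, vectors=vectors)


def _builtin_table(fname: str) -> dict[str, np.ndarray]:
    text = resources.files("aakernels.data").joinpath(fname).read_text()
    return _read_table(text.splitlines(), fname)


def load_builtin_encoding(name: str, alphabet: Alphabet = STANDARD_ALPHABET) -> AAEncoding:
    """Return one of the builtin encodings: unit, pca, zscale or blosum50.

    Vectors are returned raw (unstandardized); the blosum50 vectors are the
    exact BLOSUM50 rows restricted to the alphabet. See
    :func:`get_encoding` for the standardize-by-default convenience.
    """
    if name not in BUILTIN_ENCODINGS:
        raise EncodingError(
            f"unknown encoding {name!r}; valid options: {', '.join(BUILTIN_ENCODINGS)}"
        )
    if name == "unit":
        eye = np.eye(len(alphabet))
        vectors = {a: eye[i] for i, a in enumerate(alphabet)}
    elif name == "blosum50":
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM50")
        for a in alphabet:
            if a not in m.alphabet:
                raise EncodingError(f"letter {a!r} not covered by BLOSUM50")
        vectors = {a: np.array([float(m[a][b]) for b in alphabet]) for a in alphabet}
    else:
        fname = "pca_synthetic.tsv" if name == "pca" else "zscale.tsv"
        table = _builtin_table(fname)
        missing = [a for a in alphabet if a not in table]
        if missing:
            raise EncodingError(f"builtin {name!r} missing letter(s) {missing}")
        vectors = {a: table[a] for a in alphabet}
    return AAEncoding(name=name, alphabet=alphabet, vectors=vectors)


def standardize_encoding(enc: AAEncoding) -> AAEncoding:
    """Z-score each descriptor coordinate across the alphabet's letters.

    Constant coordinates are set to zero instead of dividing by zero. The
    unit encoding is returned unchanged: its orthogonality is the point.
    """
    if enc.name == "unit":
        return enc
    m = enc.matrix
    mu = m.mean(axis=0)
    sd = m.std(axis=0)
    scaled = np.where(sd > 0, (m - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    vectors = {a: scaled[i] for i, a in enumerate(enc.alphabet)}
    return AAEncoding(name=enc.name, alphabet=enc.alphabet, vectors=vectors, normalized=True)


def get_encoding(
    name: str,
    alphabet: Alphabet = STANDARD_ALPHABET,
    standardize: bool | None = None,
) -> AAEncoding:
    """Builtin encoding with the default standardization policy applied.

    ``standardize=None`` applies the package default: physico-chemical sets
    (pca, zscale, blosum50) are standardized, the unit encoding is not.
    """
    enc = load_builtin_encoding(name, alphabet)
    if standardize is None:
        standardize = DEFAULT_STANDARDIZE[name]
    return standardize_encoding(enc) if standardize else enc


def encode_sequence(x: str, enc: AAEncoding) -> np.ndarray:
    """Concatenate Ψ(x₁),…,Ψ(x_L) into one length-L·D vector."""
    for pos, letter in enumerate(x):
        if letter not in enc.alphabet:
            raise EncodingError(f"unknown letter {letter!r} at position {pos} of {x!r}")
    idx = enc.alphabet.indices(x)
    return enc.matrix[idx].ravel()
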