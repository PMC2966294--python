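"""Gram-matrix machinery shared by all kernels.

A :class:`GramMatrix` carries the symmetric kernel matrix, the sequence ids
it was computed over, and a provenance mapping recording the kernel
configuration, so a matrix written to disk can be traced back to its spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GramMatrix:
    ids: list[str]
    values: np.ndarray
    spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("Gram matrix shape does not match number of ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_psd(self, rtol: float = 1e-8) -> bool:
        """Check min eigenvalue ≥ −rtol · max eigenvalue (numerical PSD)."""
        w = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        return bool(w[0] >= -rtol * max(w[-1], 0.0) - 1e-300)


def normalize_gram(K: np.ndarray) -> np.ndarray:
    """Cosine-normalize: K[i,j] / sqrt(K[i,i] K[j,j]), diagonal exactly 1.

    Rows with a non-positive diagonal (possible for degenerate feature maps,
    e.g. an empty mutation neighbourhood) are left at zero off-diagonal.
    """
    d = np.diag(K).copy()
    ok = d > 0
    scale = np.where(ok, np.sqrt(np.where(ok, d, 1.0)), np.inf)
    Kn = K / np.outer(scale, scale)
    np.fill_diagonal(Kn, 1.0)
    return Kn


def gram_matrix(seqs, kernel, normalize: bool = True, ids=None, spec=None) -> GramMatrix:
    """Compute the kernel matrix of ``kernel`` over ``seqs``.

    ``kernel`` is either a callable k(x, y) or an object with a vectorized
    ``.gram(list_of_sequences)`` method (used when available). Sequences may
    be plain strings or objects with a ``residues`` attribute.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("cannot compute a Gram matrix over an empty sequence list")
    residues = [getattr(s, "residues", s) for s in seqs]
    if ids is None:
        ids = [getattr(s, "id", f"seq{i}") for i, s in enumerate(seqs)]
    if hasattr(kernel, "gram"):
        K = np.asarray(kernel.gram(residues), dtype=float)
    else:
        n = len(residues)
        K = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                K[i, j] = K[j, i] = kernel(residues[i], residues[j])
    K = (K + K.T) / 2.0
    if normalize:
        K = normalize_gram(K)
    meta = dict(spec or getattr(kernel, "describe", lambda: {})())
    meta["normalized"] = bool(normalize)
    return GramMatrix(ids=list(ids), values=K, spec=meta)
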