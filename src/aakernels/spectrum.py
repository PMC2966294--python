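"""l-mer content kernels without positional information.

The spectrum kernel is the inner product of l-mer count vectors. It can
equivalently be written as a sum over all pairs of windows (one from each
sequence) of an exact-match indicator; replacing that indicator with a
linear/poly/RBF substring kernel yields the enhanced variants, of which the
spectrum-RBF kernel is the headline case. The pairwise formulation costs
O(|x|·|x′|) substring comparisons per kernel value — quadratic, and only
practical for short sequences, but it is the reference semantics the faster
kernels (mismatch, profile) approximate.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import scipy.sparse as sp

from .descriptors import STANDARD_ALPHABET, Alphabet
from .substring import SubstringKernelSpec, window_values

__all__ = [
    "spectrum_features",
    "spectrum_kernel",
    "spectrum_rbf_kernel",
    "SpectrumKernel",
    "SpectrumSubstringKernel",
    "features_gram",
]


def _check_length(x: str, l: int) -> None:
    if l < 1:
        raise ValueError("l must be >= 1")
    if len(x) < l:
        raise ValueError(f"sequence of length {len(x)} shorter than l={l}")


def spectrum_features(x: str, l: int) -> Counter:
    """Sparse l-mer count vector: counts[s] = occurrences of s in x."""
    _check_length(x, l)
    return Counter(x[i : i + l] for i in range(len(x) - l + 1))


def spectrum_kernel(x: str, y: str, l: int) -> float:
    """Inner product of the two l-mer count vectors."""
    fx, fy = spectrum_features(x, l), spectrum_features(y, l)
    if len(fy) < len(fx):
        fx, fy = fy, fx
    return float(sum(c * fy[s] for s, c in fx.items()))


def spectrum_rbf_kernel(
    x: str,
    y: str,
    l: int,
    spec: SubstringKernelSpec,
    alphabet: Alphabet | None = None,
) -> float:
    """Pairwise-formulation spectrum kernel with a generalized substring kernel.

    Sums k_sub over *all* window pairs (i in x, j in y); with an RBF
    substring spec this is the spectrum-RBF kernel, which recovers the plain
    spectrum kernel as σ → 0 (injective encoding). An exact spec is allowed
    and reproduces the spectrum kernel by definition. Cost O(|x|·|y|·l).
    """
    _check_length(x, l)
    _check_length(y, l)
    if spec.kind == "exact":
        return spectrum_kernel(x, y, l)
    enc = spec.encoding
    ab = enc.alphabet
    ix, iy = ab.indices(x), ab.indices(y)
    table = enc.dist2_table if spec.kind == "rbf" else enc.dot_table
    nx, ny = len(x) - l + 1, len(y) - l + 1
    W = np.zeros((nx, ny))
    for p in range(l):
        W += table[np.ix_(ix[p : p + nx], iy[p : p + ny])]
    if spec.kind == "rbf":
        vals = window_values(0.0, W, l, spec)
    else:
        vals = window_values(W, 0.0, l, spec)
    return float(vals.sum())


def features_gram(feature_maps: list[Counter | dict]) -> np.ndarray:
    """Gram matrix of sparse feature maps via a CSR inner product."""
    keys = {}
    rows, cols, data = [], [], []
    for i, fm in enumerate(feature_maps):
        for s, w in fm.items():
            j = keys.setdefault(s, len(keys))
            rows.append(i)
            cols.append(j)
            data.append(float(w))
    F = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(feature_maps), max(len(keys), 1))
    )
    return np.asarray((F @ F.T).todense(), dtype=float)


class SpectrumKernel:
    """Plain spectrum kernel of order l (variable-length sequences)."""

    def __init__(self, l: int):
        self.l = l

    def __call__(self, x: str, y: str) -> float:
        return spectrum_kernel(x, y, self.l)

    def gram(self, seqs: list[str]) -> np.ndarray:
        return features_gram([spectrum_features(s, self.l) for s in seqs])

    def describe(self) -> dict:
        return {"kernel": "spectrum", "l": self.l}


class SpectrumSubstringKernel:
    """Spectrum kernel in the all-window-pairs form, generalized substring comparison."""

    def __init__(self, l: int, spec: SubstringKernelSpec):
        self.l = l
        self.spec = spec

    def __call__(self, x: str, y: str) -> float:
        return spectrum_rbf_kernel(x, y, self.l, self.spec)

    def gram(self, seqs: list[str]) -> np.ndarray:
        n = len(seqs)
        K = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                K[i, j] = K[j, i] = self(seqs[i], seqs[j])
        return K

    def describe(self) -> dict:
        return {
            "kernel": "spectrum-" + self.spec.kind,
            "l": self.l,
            "encoding": self.spec.encoding.name if self.spec.encoding else None,
            "sigma": self.spec.sigma if self.spec.kind == "rbf" else None,
            "degree": self.spec.degree if self.spec.kind == "poly" else None,
        }
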