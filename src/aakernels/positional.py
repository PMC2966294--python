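"""Position-aware kernels for sequences of fixed length L.

The weighted degree (WD) kernel sums, over substring lengths l = 1..d and
every position i, a comparison of the two length-l windows starting at i:

    k(x, y) = Σ_l β_l Σ_i k_sub(x[i:i+l], y[i:i+l])

With the exact-match substring comparison this is the classic WD kernel
(counting co-occurring substrings at the same position); plugging in the
linear/poly/RBF substring kernels yields the WD-linear/WD-poly/WD-RBF
kernels. With an injective encoding, WD-RBF at σ → 0 recovers the classic
WD kernel.

The flat kernels are the non-substring baselines: a polynomial or RBF
kernel applied to the whole sequence's concatenated descriptor vector,
ignoring substring structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import STANDARD_ALPHABET, AAEncoding, Alphabet, encode_sequence
from .substring import SubstringKernelSpec, window_values

__all__ = [
    "WDParams",
    "FlatKernelParams",
    "default_wd_weights",
    "wd_kernel",
    "flat_kernel",
    "WDKernel",
    "FlatKernel",
]


def default_wd_weights(d: int) -> np.ndarray:
    """Standard WD weighting β_l = 2(d−l+1)/(d(d+1)), summing to 1."""
    l = np.arange(1, d + 1)
    return 2.0 * (d - l + 1) / (d * (d + 1))


@dataclass(frozen=True)
class WDParams:
    max_degree: int = 5
    weights: tuple[float, ...] | None = None
    substring_spec: SubstringKernelSpec = field(default_factory=SubstringKernelSpec)

    def __post_init__(self) -> None:
        if self.max_degree < 1:
            raise ValueError("max_degree must be >= 1")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != self.max_degree:
                raise ValueError("weights length must equal max_degree")
            if (w < 0).any() or not (w > 0).any():
                raise ValueError("weights must be non-negative with at least one positive")

    @property
    def beta(self) -> np.ndarray:
        if self.weights is None:
            return default_wd_weights(self.max_degree)
        return np.asarray(self.weights, dtype=float)


@dataclass(frozen=True)
class FlatKernelParams:
    kind: str = "rbf"
    encoding: AAEncoding | None = None
    degree: int = 2
    offset: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("poly", "rbf"):
            raise ValueError("flat kernel kind must be 'poly' or 'rbf'")
        if self.encoding is None:
            raise ValueError("flat kernels require an encoding")
        if self.kind == "rbf" and not self.sigma > 0:
            raise ValueError("sigma must be positive")


def _alphabet_of(spec: SubstringKernelSpec, fallback: Alphabet) -> Alphabet:
    return spec.encoding.alphabet if spec.encoding is not None else fallback


def _position_tables(spec: SubstringKernelSpec, alphabet: Alphabet) -> np.ndarray:
    """|Σ|×|Σ| per-position comparison table for the substring spec.

    exact → mismatch indicator (so a window matches iff its sum is 0);
    rbf → squared descriptor distance; linear/poly → descriptor dot product.
    """
    if spec.kind == "exact":
        return 1.0 - np.eye(len(alphabet))
    if spec.kind == "rbf":
        return spec.encoding.dist2_table
    return spec.encoding.dot_table


def _window_transform(W: np.ndarray, l: int, spec: SubstringKernelSpec) -> np.ndarray:
    if spec.kind == "exact":
        return (W == 0).astype(float)
    if spec.kind == "rbf":
        return window_values(0.0, W, l, spec)
    return window_values(W, 0.0, l, spec)


def wd_kernel(x: str, y: str, params: WDParams, alphabet: Alphabet | None = None) -> float:
    """WD kernel between two equal-length sequences."""
    if len(x) != len(y):
        raise ValueError(f"WD kernels require fixed length: got {len(x)} and {len(y)}")
    L = len(x)
    if params.max_degree > L:
        raise ValueError(f"max_degree {params.max_degree} exceeds sequence length {L}")
    spec = params.substring_spec
    ab = _alphabet_of(spec, alphabet or STANDARD_ALPHABET)
    table = _position_tables(spec, ab)
    v = table[ab.indices(x), ab.indices(y)]
    cum = np.concatenate([[0.0], np.cumsum(v)])
    total = 0.0
    for l, beta in enumerate(params.beta, start=1):
        if beta == 0.0:
            continue
        W = cum[l:] - cum[:-l]  # window sums, one per start position
        total += beta * _window_transform(W, l, spec).sum()
    return float(total)


def flat_kernel(x: str, y: str, params: FlatKernelParams) -> float:
    """Whole-sequence poly/RBF kernel on concatenated descriptor vectors."""
    if len(x) != len(y):
        raise ValueError(f"flat kernels require equal length: got {len(x)} and {len(y)}")
    ex = encode_sequence(x, params.encoding)
    ey = encode_sequence(y, params.encoding)
    if params.kind == "poly":
        return float((ex @ ey / len(x) + params.offset) ** params.degree)
    d2 = float(((ex - ey) ** 2).sum())
    return float(np.exp(-d2 / (2.0 * params.sigma**2)))


class WDKernel:
    """WD kernel with a vectorized Gram computation.

    The Gram path builds, per sequence position, the N×N table of pairwise
    per-position comparisons, accumulates window sums by cumulative sums
    over positions, and applies the substring-kernel transform per length.
    """

    def __init__(self, params: WDParams | None = None, alphabet: Alphabet | None = None):
        self.params = params or WDParams()
        self.alphabet = _alphabet_of(self.params.substring_spec, alphabet or STANDARD_ALPHABET)

    def __call__(self, x: str, y: str) -> float:
        return wd_kernel(x, y, self.params, self.alphabet)

    def gram(self, seqs: list[str]) -> np.ndarray:
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"WD kernels require fixed length; got lengths {sorted(lengths)}")
        L = lengths.pop()
        if self.params.max_degree > L:
            raise ValueError(f"max_degree {self.params.max_degree} exceeds sequence length {L}")
        spec = self.params.substring_spec
        table = _position_tables(spec, self.alphabet)
        S = np.vstack([self.alphabet.indices(s) for s in seqs])
        n = len(seqs)
        cum = np.zeros((L + 1, n, n))
        for p in range(L):
            cum[p + 1] = cum[p] + table[np.ix_(S[:, p], S[:, p])]
        K = np.zeros((n, n))
        for l, beta in enumerate(self.params.beta, start=1):
            if beta == 0.0:
                continue
            for i in range(L - l + 1):
                K += beta * _window_transform(cum[i + l] - cum[i], l, spec)
        return K

    def describe(self) -> dict:
        spec = self.params.substring_spec
        return {
            "kernel": "wd",
            "max_degree": self.params.max_degree,
            "weights": list(map(float, self.params.beta)),
            "substring": spec.kind,
            "encoding": spec.encoding.name if spec.encoding else None,
            "sigma": spec.sigma if spec.kind == "rbf" else None,
            "degree": spec.degree if spec.kind == "poly" else None,
        }


class FlatKernel:
    """Non-substring poly/RBF baseline with a vectorized Gram computation."""

    def __init__(self, params: FlatKernelParams):
        self.params = params

    def __call__(self, x: str, y: str) -> float:
        return flat_kernel(x, y, self.params)

    def gram(self, seqs: list[str]) -> np.ndarray:
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"flat kernels require fixed length; got lengths {sorted(lengths)}")
        L = lengths.pop()
        E = np.vstack([encode_sequence(s, self.params.encoding) for s in seqs])
        G = E @ E.T
        if self.params.kind == "poly":
            return (G / L + self.params.offset) ** self.params.degree
        sq = np.diag(G)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * G, 0.0)
        return np.exp(-d2 / (2.0 * self.params.sigma**2))

    def describe(self) -> dict:
        p = self.params
        return {
            "kernel": f"flat-{p.kind}",
            "encoding": p.encoding.name,
            "sigma": p.sigma if p.kind == "rbf" else None,
            "degree": p.degree if p.kind == "poly" else None,
            "offset": p.offset if p.kind == "poly" else None,
        }
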