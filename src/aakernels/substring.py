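"""Kernels on fixed-length amino-acid substrings.

Classic string kernels compare two l-mers with an exact-match indicator.
Here that indicator is generalized to a kernel over descriptor encodings:

- ``exact``:   k(u, v) = 1 if u = v else 0
- ``linear``:  k(u, v) = Σ_p ⟨Ψ(u_p), Ψ(v_p)⟩
- ``poly``:    k(u, v) = (Σ_p ⟨Ψ(u_p), Ψ(v_p)⟩ / l + c)^d   (inhomogeneous;
  the inner sum is divided by l so degree and offset keep a
  length-independent meaning)
- ``rbf``:     k(u, v) = exp(−Σ_p ‖Ψ(u_p) − Ψ(v_p)‖² / (2σ²))

With an injective encoding the RBF variant interpolates between exact
matching (σ → 0) and the all-ones kernel (σ → ∞), which is what lets every
enhanced string kernel degrade to its classic counterpart by configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .descriptors import AAEncoding, EncodingError

KINDS = ("exact", "linear", "poly", "rbf")


@dataclass(frozen=True)
class SubstringKernelSpec:
    """Which kernel compares two l-mers, with its parameters.

    ``kind="exact"`` ignores the encoding; ``degree``/``offset`` apply to
    the polynomial kernel and ``sigma`` to the RBF kernel.
    """

    kind: str = "exact"
    encoding: AAEncoding | None = None
    degree: int = 2
    offset: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind != "exact" and self.encoding is None:
            raise ValueError(f"kind {self.kind!r} requires an encoding")
        if self.kind == "rbf" and not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.kind == "poly" and (self.degree < 1 or self.offset < 0):
            raise ValueError("poly requires degree >= 1 and offset >= 0")


def window_values(dot_sum, dist2_sum, l: int, spec: SubstringKernelSpec):
    """Kernel value(s) for window(s) given summed per-position tables.

    ``dot_sum`` is Σ_p ⟨Ψ(u_p),Ψ(v_p)⟩ and ``dist2_sum`` Σ_p ‖Ψ(u_p)−Ψ(v_p)‖²;
    both may be scalars or arrays. Not defined for kind="exact".
    """
    if spec.kind == "linear":
        return dot_sum
    if spec.kind == "poly":
        return (dot_sum / l + spec.offset) ** spec.degree
    if spec.kind == "rbf":
        return np.exp(-dist2_sum / (2.0 * spec.sigma**2))
    raise ValueError(f"no window value for kind {spec.kind!r}")


def k_substring(u: str, v: str, spec: SubstringKernelSpec) -> float:
    """Kernel between two equal-length substrings under ``spec``."""
    if len(u) != len(v):
        raise ValueError(f"substring length mismatch: {len(u)} vs {len(v)}")
    if spec.kind == "exact":
        return 1.0 if u == v else 0.0
    enc = spec.encoding
    iu, iv = enc.alphabet.indices(u), enc.alphabet.indices(v)
    if spec.kind == "rbf":
        return float(window_values(0.0, enc.dist2_table[iu, iv].sum(), len(u), spec))
    return float(window_values(enc.dot_table[iu, iv].sum(), 0.0, len(u), spec))


def substring_feature_dim(spec: SubstringKernelSpec, l: int) -> float:
    """Dimension of the feature space induced on l-mers.

    exact → |Σ|^l (one indicator per string); linear → D^l (one feature per
    choice of exactly one descriptor per position); poly → C(D·l + d, d),
    the monomial count of an inhomogeneous degree-d polynomial in the D·l
    concatenated descriptors; rbf → ``math.inf``.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    if spec.kind == "exact":
        if spec.encoding is None:
            raise ValueError("exact feature dimension needs an encoding for |Σ|")
        return float(len(spec.encoding.alphabet) ** l)
    if spec.kind == "linear":
        return float(spec.encoding.dim**l)
    if spec.kind == "poly":
        return float(math.comb(spec.encoding.dim * l + spec.degree, spec.degree))
    return math.inf
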