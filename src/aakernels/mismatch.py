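"""(l,m)-mismatch kernels and their descriptor-enhanced variants.

A window u of length l contributes to the feature coordinate of every
l-mer s within Hamming distance m of u (its mismatch neighbourhood
N_(l,m)). The plain mismatch kernel counts those contributions; the
enhanced feature map weights each contribution by a substring kernel
k_sub(u, s), so similar substrings contribute more than dissimilar ones.
With an RBF substring kernel this is the mismatch-RBF kernel, which
recovers the plain mismatch kernel as σ → ∞ (every weight tends to 1).

Kernel values are computed by a depth-l traversal of the (l,m)-mismatch
tree: each tree path spells a feature string s, and only branches with at
least one live window (mismatch budget not yet exhausted) in either
sequence are expanded.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .descriptors import STANDARD_ALPHABET, Alphabet
from .spectrum import features_gram, spectrum_features
from .substring import SubstringKernelSpec, window_values

__all__ = [
    "MismatchParams",
    "mismatch_neighborhood",
    "mismatch_features",
    "mismatch_rbf_features",
    "mismatch_kernel",
    "MismatchKernel",
]


@dataclass(frozen=True)
class MismatchParams:
    l: int = 5
    m: int = 1
    substring_spec: SubstringKernelSpec = field(default_factory=SubstringKernelSpec)

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError("l must be >= 1")
        if not 0 <= self.m <= self.l:
            raise ValueError("m must satisfy 0 <= m <= l")


def _alphabet_of(params: MismatchParams, alphabet: Alphabet | None) -> Alphabet:
    spec = params.substring_spec
    if spec.encoding is not None:
        return spec.encoding.alphabet
    return alphabet or STANDARD_ALPHABET


def mismatch_neighborhood(
    s: str, params: MismatchParams, alphabet: Alphabet | None = None
) -> set[str]:
    """All l-mers differing from ``s`` in at most m positions (includes s)."""
    if len(s) != params.l:
        raise ValueError(f"expected an l-mer of length {params.l}, got {len(s)}")
    ab = _alphabet_of(params, alphabet)
    out = {s}
    for k in range(1, params.m + 1):
        for positions in itertools.combinations(range(params.l), k):
            alternatives = [[a for a in ab if a != s[p]] for p in positions]
            for combo in itertools.product(*alternatives):
                t = list(s)
                for p, a in zip(positions, combo):
                    t[p] = a
                out.add("".join(t))
    return out


def _window_weight(u: str, s: str, spec: SubstringKernelSpec) -> float:
    from .substring import k_substring

    return k_substring(u, s, spec)


def mismatch_features(
    x: str, params: MismatchParams, alphabet: Alphabet | None = None
) -> Counter:
    """counts[s] = number of windows of x whose neighbourhood contains s."""
    if params.substring_spec.kind != "exact":
        raise ValueError("mismatch_features requires an exact substring spec; "
                         "use mismatch_rbf_features for enhanced variants")
    if len(x) < params.l:
        raise ValueError(f"sequence of length {len(x)} shorter than l={params.l}")
    if params.m == 0:
        return spectrum_features(x, params.l)
    ab = _alphabet_of(params, alphabet)
    counts: Counter = Counter()
    for i in range(len(x) - params.l + 1):
        for s in mismatch_neighborhood(x[i : i + params.l], params, ab):
            counts[s] += 1
    return counts


def mismatch_rbf_features(
    x: str, params: MismatchParams, alphabet: Alphabet | None = None
) -> Counter:
    """Neighbourhood feature map weighted by substring similarity.

    counts[s] = Σ_windows [u ∈ N(s)] · k_sub(u, s); the Hamming gate is
    symmetric, so membership is enumerated from each window's own
    neighbourhood.
    """
    spec = params.substring_spec
    if spec.kind == "exact":
        raise ValueError("mismatch_rbf_features requires a linear/poly/rbf substring spec")
    if len(x) < params.l:
        raise ValueError(f"sequence of length {len(x)} shorter than l={params.l}")
    ab = _alphabet_of(params, alphabet)
    counts: Counter = Counter()
    for i in range(len(x) - params.l + 1):
        u = x[i : i + params.l]
        for s in mismatch_neighborhood(u, params, ab):
            counts[s] += _window_weight(u, s, spec)
    return counts


def _features(x: str, params: MismatchParams, ab: Alphabet) -> Counter:
    if params.substring_spec.kind == "exact":
        return mismatch_features(x, params, ab)
    return mismatch_rbf_features(x, params, ab)


def mismatch_kernel(
    x: str,
    y: str,
    params: MismatchParams,
    alphabet: Alphabet | None = None,
    return_stats: bool = False,
):
    """Mismatch kernel ⟨Φ(x), Φ(y)⟩ via mismatch-tree traversal.

    Per tree node each live window carries its mismatch count and, for
    enhanced specs, running descriptor dot-product and squared-distance
    sums, so the leaf weight k_sub(window, s) needs no re-scan. With
    ``return_stats`` the number of expanded leaves is also returned.
    """
    spec = params.substring_spec
    ab = _alphabet_of(params, alphabet)
    l, m = params.l, params.m
    for seq in (x, y):
        if len(seq) < l:
            raise ValueError(f"sequence of length {len(seq)} shorter than l={l}")
    cx = np.vstack([ab.indices(x[i : i + l]) for i in range(len(x) - l + 1)])
    cy = np.vstack([ab.indices(y[j : j + l]) for j in range(len(y) - l + 1)])
    exact = spec.kind == "exact"
    if exact:
        dot_t = dist_t = np.zeros((len(ab), len(ab)))
    else:
        dot_t = spec.encoding.dot_table
        dist_t = spec.encoding.dist2_table
    n_letters = len(ab)
    stats = {"leaves": 0}

    def leaf_sum(entries) -> float:
        if exact:
            return float(len(entries))
        return float(
            sum(window_values(dot, 0.0, l, spec) if spec.kind != "rbf"
                else window_values(0.0, d2, l, spec)
                for _, _, dot, d2 in entries)
        )

    def traverse(depth: int, xs, ys) -> float:
        if depth == l:
            stats["leaves"] += 1
            return leaf_sum(xs) * leaf_sum(ys)
        total = 0.0
        for a in range(n_letters):
            nxs = _advance(xs, cx, a, depth)
            if not nxs:
                continue
            nys = _advance(ys, cy, a, depth)
            if not nys:
                continue
            total += traverse(depth + 1, nxs, nys)
        return total

    def _advance(entries, codes, a, depth):
        out = []
        for w, mm, dot, d2 in entries:
            c = codes[w, depth]
            nmm = mm + (c != a)
            if nmm > m:
                continue
            out.append((w, nmm, dot + dot_t[c, a], d2 + dist_t[c, a]))
        return out

    init_x = [(w, 0, 0.0, 0.0) for w in range(len(cx))]
    init_y = [(w, 0, 0.0, 0.0) for w in range(len(cy))]
    value = traverse(0, init_x, init_y)
    if return_stats:
        return value, stats
    return value


class MismatchKernel:
    """(l,m)-mismatch kernel; pairwise values use the mismatch tree, Gram
    matrices use explicit sparse feature maps (one neighbourhood expansion
    per sequence instead of per pair)."""

    def __init__(self, params: MismatchParams, alphabet: Alphabet | None = None):
        self.params = params
        self.alphabet = _alphabet_of(params, alphabet)

    def __call__(self, x: str, y: str) -> float:
        return mismatch_kernel(x, y, self.params, self.alphabet)

    def features(self, x: str) -> Counter:
        return _features(x, self.params, self.alphabet)

    def gram(self, seqs: list[str]) -> np.ndarray:
        return features_gram([self.features(s) for s in seqs])

    def describe(self) -> dict:
        spec = self.params.substring_spec
        return {
            "kernel": "mismatch" + ("" if spec.kind == "exact" else "-" + spec.kind),
            "l": self.params.l,
            "m": self.params.m,
            "encoding": spec.encoding.name if spec.encoding else None,
            "sigma": spec.sigma if spec.kind == "rbf" else None,
        }
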