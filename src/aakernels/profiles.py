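"""Profile kernels: neighbourhoods defined by position-specific profiles.

Where the mismatch kernel gates a window's contributions by Hamming
distance, the profile kernel gates them by the window's own position
specific scoring profile p(x_i, k): an l-mer s belongs to the positional
mutation neighbourhood of the window starting at i when

    Σ_{p=1..l} −log p(x_{i+p−1}, s_p) < δ

with δ the neighbourhood radius (a.k.a. τ in parts of the literature; the
two are treated as the same quantity here). Zero probabilities are floored
at a small ε before the log. The inequality is strict, so δ = 0 yields an
empty neighbourhood and an all-zero feature map.

The enhanced (profile-RBF) feature map additionally weights each
contribution by a substring kernel between the window and s, exactly as in
the mismatch-RBF kernel. Profiles are *consumed*, never computed, from a
simple TSV or a PSI-BLAST ASCII PSSM.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .descriptors import STANDARD_ALPHABET, Alphabet
from .spectrum import features_gram
from .substring import SubstringKernelSpec, k_substring

__all__ = [
    "SequenceProfile",
    "ProfileParams",
    "positional_mutation_neighborhood",
    "profile_features",
    "profile_rbf_features",
    "profile_kernel",
    "ProfileKernel",
    "read_profile_tsv",
    "write_profile_tsv",
    "read_pssm",
]


@dataclass
class SequenceProfile:
    """A sequence plus its per-position probability distribution over Σ."""

    sequence: str
    probs: np.ndarray
    alphabet: Alphabet = STANDARD_ALPHABET
    id: str = "profile"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        L = len(self.sequence)
        if self.probs.shape != (L, len(self.alphabet)):
            raise ValueError(
                f"profile shape {self.probs.shape} does not match "
                f"sequence length {L} x alphabet size {len(self.alphabet)}"
            )
        if (self.probs < 0).any():
            raise ValueError("profile probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("profile rows must each sum to 1 (within 1e-6)")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProfileParams:
    l: int = 5
    delta: float = 7.5
    substring_spec: SubstringKernelSpec = field(default_factory=SubstringKernelSpec)
    floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError("l must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not self.floor > 0:
            raise ValueError("floor must be positive")

    @property
    def tau(self) -> float:
        """Alias for delta (the radius is called τ in parts of the literature)."""
        return self.delta


def _neglog(prof: SequenceProfile, params: ProfileParams) -> np.ndarray:
    return -np.log(np.maximum(prof.probs, params.floor))


def _window_neighborhood(cost: np.ndarray, letters: str, delta: float):
    """DFS with branch-and-bound over an l × |Σ| cost matrix.

    Yields (string, total_cost) for every string with Σ cost < delta;
    partial sums already ≥ delta are pruned (costs are non-negative).
    """
    l = cost.shape[0]
    order = [np.argsort(cost[p]) for p in range(l)]  # cheap letters first

    def rec(p: int, acc: float, prefix: list[str]):
        if p == l:
            yield "".join(prefix), acc
            return
        for k in order[p]:
            nacc = acc + cost[p, k]
            if nacc >= delta:
                break  # letters sorted by cost: the rest only get worse
            prefix.append(letters[k])
            yield from rec(p + 1, nacc, prefix)
            prefix.pop()

    yield from rec(0, 0.0, [])


def positional_mutation_neighborhood(
    prof: SequenceProfile, i: int, params: ProfileParams
) -> set[str]:
    """All l-mers with Σ_p −log p(x_{i+p}, s_p) < δ for the window at i."""
    if not 0 <= i <= len(prof) - params.l:
        raise ValueError(f"window [{i}, {i + params.l}) outside profile of length {len(prof)}")
    cost = _neglog(prof, params)[i : i + params.l]
    return {s for s, _ in _window_neighborhood(cost, prof.alphabet.letters, params.delta)}


def profile_features(prof: SequenceProfile, params: ProfileParams) -> Counter:
    """counts[s] = number of windows whose mutation neighbourhood contains s."""
    if params.substring_spec.kind != "exact":
        raise ValueError("profile_features requires an exact substring spec; "
                         "use profile_rbf_features for enhanced variants")
    return _profile_features(prof, params, weighted=False)


def profile_rbf_features(prof: SequenceProfile, params: ProfileParams) -> Counter:
    """Neighbourhood feature map weighted by k_sub(window, s)."""
    if params.substring_spec.kind == "exact":
        raise ValueError("profile_rbf_features requires a linear/poly/rbf substring spec")
    return _profile_features(prof, params, weighted=True)


def _profile_features(prof: SequenceProfile, params: ProfileParams, weighted: bool) -> Counter:
    if len(prof) < params.l:
        raise ValueError(f"profile of length {len(prof)} shorter than l={params.l}")
    cost = _neglog(prof, params)
    counts: Counter = Counter()
    letters = prof.alphabet.letters
    for i in range(len(prof) - params.l + 1):
        window = prof.sequence[i : i + params.l]
        for s, _ in _window_neighborhood(cost[i : i + params.l], letters, params.delta):
            if weighted:
                counts[s] += k_substring(window, s, params.substring_spec)
            else:
                counts[s] += 1
    return counts


def profile_kernel(p1: SequenceProfile, p2: SequenceProfile, params: ProfileParams) -> float:
    """Inner product of the (plain or enhanced) profile feature maps."""
    weighted = params.substring_spec.kind != "exact"
    f1 = _profile_features(p1, params, weighted)
    f2 = _profile_features(p2, params, weighted)
    if len(f2) < len(f1):
        f1, f2 = f2, f1
    return float(sum(w * f2[s] for s, w in f1.items()))


class ProfileKernel:
    """Profile kernel over SequenceProfile inputs (plain or enhanced)."""

    def __init__(self, params: ProfileParams):
        self.params = params

    def __call__(self, p1: SequenceProfile, p2: SequenceProfile) -> float:
        return profile_kernel(p1, p2, self.params)

    def features(self, prof: SequenceProfile) -> Counter:
        weighted = self.params.substring_spec.kind != "exact"
        return _profile_features(prof, self.params, weighted)

    def gram(self, profiles: list[SequenceProfile]) -> np.ndarray:
        return features_gram([self.features(p) for p in profiles])

    def describe(self) -> dict:
        spec = self.params.substring_spec
        return {
            "kernel": "profile" + ("" if spec.kind == "exact" else "-" + spec.kind),
            "l": self.params.l,
            "delta": self.params.delta,
            "encoding": spec.encoding.name if spec.encoding else None,
            "sigma": spec.sigma if spec.kind == "rbf" else None,
        }


# ---------------------------------------------------------------------------
# profile I/O


def read_profile_tsv(path: str | Path, alphabet: Alphabet = STANDARD_ALPHABET) -> SequenceProfile:
    """Read a profile TSV: header of letters, one probability row per position.

    An optional leading ``residue`` column supplies the sequence; otherwise
    the per-row argmax letter is used.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty profile file")
    header = lines[0].split("\t")
    has_residue = header[0].lower() == "residue"
    letters = header[1:] if has_residue else header
    if list(letters) != list(alphabet.letters):
        raise ValueError(f"{path}: header letters {letters} do not match alphabet")
    rows, residues = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if has_residue:
            residues.append(parts[0])
            parts = parts[1:]
        try:
            rows.append([float(v) for v in parts])
        except ValueError:
            raise ValueError(f"{path}: non-numeric probability at line {lineno}") from None
    probs = np.array(rows)
    if not has_residue:
        residues = [alphabet.letters[k] for k in probs.argmax(axis=1)]
    return SequenceProfile("".join(residues), probs, alphabet, id=path.stem)


def write_profile_tsv(path: str | Path, prof: SequenceProfile) -> None:
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(prof.alphabet.letters) + "\n")
        for res, row in zip(prof.sequence, prof.probs):
            fh.write(res + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_pssm(path: str | Path, alphabet: Alphabet = STANDARD_ALPHABET) -> SequenceProfile:
    """Read a PSI-BLAST ASCII PSSM and return its percentage columns as a profile.

    The 20 weighted-observation percentage columns are divided by 100 and
    renormalized per row (all-zero rows fall back to uniform).
    """
    path = Path(path)
    rows, residues, file_letters = [], [], None
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if file_letters is None:
                # header row: 40 letters (scores then percentages)
                if len(parts) >= 40 and all(len(p) == 1 and p.isalpha() for p in parts[:40]):
                    file_letters = parts[20:40]
                continue
            if len(parts) >= 42 and parts[0].isdigit():
                residues.append(parts[1])
                rows.append([float(v) for v in parts[22:42]])
    if file_letters is None or not rows:
        raise ValueError(f"{path}: not a recognizable PSI-BLAST ASCII PSSM")
    perc = np.array(rows) / 100.0
    # reorder file columns into alphabet order
    order = [file_letters.index(a) for a in alphabet.letters]
    perc = perc[:, order]
    sums = perc.sum(axis=1, keepdims=True)
    uniform = np.full(len(alphabet), 1.0 / len(alphabet))
    probs = np.where(sums > 0, perc / np.where(sums > 0, sums, 1.0), uniform)
    return SequenceProfile("".join(residues), probs, alphabet, id=path.stem)
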