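# Methods

## Model

All kernels in this package are built from one primitive: a comparison of
two equal-length substrings u, v ∈ Σ^l through a residue feature map
Ψ: Σ → R^D. Four substring kernels are supported:

| kind    | definition                                                   | feature dim |
|---------|--------------------------------------------------------------|-------------|
| exact   | 1 if u = v else 0                                            | \|Σ\|^l     |
| linear  | Σ_p ⟨Ψ(u_p), Ψ(v_p)⟩                                         | D^l for the product form; the implemented sum corresponds to concatenated per-position descriptors |
| poly    | (Σ_p ⟨Ψ(u_p), Ψ(v_p)⟩ / l + c)^d                             | C(D·l + d, d) |
| rbf     | exp(−Σ_p ‖Ψ(u_p) − Ψ(v_p)‖² / (2σ²))                          | ∞           |

The string kernels then arise by where and how substrings are compared:

- **WD kernel** (fixed length L): Σ_{l=1..d} β_l Σ_i k_sub(x[i:i+l], y[i:i+l]).
  Same-position windows only; a sum of kernels, hence a valid kernel.
- **Spectrum kernel** (any lengths): inner product of l-mer count vectors,
  equivalently a sum of k_sub over *all* window pairs. The pairwise form
  costs O(|x|·|x′|·l) per value and is retained deliberately: it is the
  reference semantics, practical only for short sequences.
- **Mismatch kernel**: a window u contributes to feature string s iff
  Hamming(u, s) ≤ m; the enhanced map weights that contribution by
  k_sub(u, s). Values are computed by a depth-l mismatch-tree traversal in
  which each live window carries its mismatch count plus running
  descriptor dot/distance sums, so leaf weights need no re-scan. Gram
  matrices instead use explicit sparse feature maps (one neighbourhood
  expansion per sequence) and a CSR inner product.
- **Profile kernel**: the gate is the positional mutation neighbourhood —
  s counts for the window at i iff Σ_p −log p(x_{i+p}, s_p) < δ, with the
  per-position probabilities taken from an externally supplied profile
  (TSV or PSI-BLAST ASCII PSSM; profile *generation* is out of scope).
  Neighbourhood enumeration is depth-first with branch-and-bound pruning
  (letters sorted by cost per position; partial sums ≥ δ cut).

Recovery limits tie the enhanced kernels to the classic ones and are
tested directly: with any injective encoding, WD-RBF and spectrum-RBF →
their classic counterparts as σ → 0; mismatch-RBF and profile-RBF (whose
gates do not depend on σ) → the plain counting kernels as σ → ∞.

## Conventions the literature leaves open

- **RBF parameterization** is exp(−d²/(2σ²)). Both common conventions
  satisfy the stated σ limits; σ is a model-selection parameter, so the
  choice only relabels the grid.
- **Polynomial substring kernel** is inhomogeneous with the inner sum
  divided by l, so degree d and offset c keep a length-independent
  meaning; defaults d = 2, c = 1.
- **WD weights** default to the standard β_l = 2(d−l+1)/(d(d+1)) (sums to
  1, downweights long substrings); default maximum degree 5. Uniform
  weights are available by passing them explicitly.
- **δ vs τ**: the profile neighbourhood radius appears under both symbols
  in the literature; they are treated as the same quantity (`delta`, alias
  `tau`), strict inequality `< δ` kept verbatim — δ = 0 therefore yields
  an empty feature map, and Gram normalization leaves such all-zero rows
  at zero rather than dividing by zero.
- **Zero-probability floor** ε = 10⁻¹⁰ before −log, since real PSSMs
  contain zeros and the cost is otherwise undefined.
- **IC50 labeling**: strictly greater than 500 ⇒ non-binder; exactly 500
  is a binder.
- **Descriptor standardization** (per-coordinate z-scoring across the
  alphabet) defaults to on for pca/zscale/blosum50 and off for unit,
  because RBF distances are scale-sensitive and the raw sets have wildly
  different coordinate scales; `load_builtin_encoding` always returns raw
  vectors (blosum50 rows bit-exact), `get_encoding` applies the policy.
- **Gram normalization** (cosine, diagonal exactly 1) defaults to on for
  SVM use.

## Descriptor sets

`unit` is the |Σ|-dimensional one-hot basis. `zscale` is the classic
3-component z-scale set (hydrophilicity, steric bulk, electronic
properties) shipped as a data file. `pca` is a 5-component set shipped in
`data/pca_synthetic.tsv`; it is a synthetic stand-in — the first five
principal components of the standardized BLOSUM50 rows, frozen once with a
deterministic sign convention — playing the role of a published
PCA-derived property set. No kernel's correctness depends on which table
is used; the tables only change which residues count as similar.
`blosum50` takes each residue's 20-entry BLOSUM50 row via biopython.

## Evaluation harness

SVMs use scikit-learn's precomputed-kernel SVC. The protocol is
two-times-nested stratified cross-validation (5 outer, 5 inner folds by
default): the inner loop selects (kernel hyperparameter, C) by mean inner
auROC — ties keep the first point in documented grid order — the model is
refit on the outer-training portion, and the outer-test auROC is recorded.
Gram matrices are computed once and subset per fold; the leakage guard
test verifies that permuting outer-test labels never changes the selected
hyperparameters. The default C grid is {0.01, 0.1, 1, 10, 100}.

auROC is the Mann–Whitney statistic (ties counted half). ROC50 — the ROC
area up to the 50th false positive, normalized so a perfect ranking scores
1 — is computed as the Mann–Whitney statistic between all positives and
the 50 highest-scoring negatives, which is equivalent to walking the
ranking and stopping at the 50th false positive (negatives tied at the
boundary contribute identically, so the selection is well defined); with
≤ 50 negatives it equals auROC. The paired kernel comparison is a
one-sided binomial sign test with ties excluded.

Learning curves hold out 30% for testing per repeat and subsample each
training size (default ladder 20, 31, 50, 80, 128, 204, 324, 516, 822,
1308) from the remainder with stratification, model-selecting by inner CV
at each size.

## Synthetic data

The generators are pure functions of (spec, seed) and define the study
conditions under which the library's claims are demonstrated.

**Binding task.** Nonamer peptides (length 9, the dominant binder length
for MHC class I), half binders. Binders draw their three anchor residues
(positions 2, 5, 9) from a softmax over a standardized descriptor
coordinate, P(a) ∝ exp(5 · effect · z(a)) with z the first standardized
z-scale coordinate by default; all other positions, and non-binders
entirely, are uniform. The sharpness 5 is calibrated so that at a moderate
effect of 0.6 the planted structure is learnable but not saturated: the
property-aware WD-RBF kernel then shows its largest advantage at very
small training sets, the behaviour the library exists to demonstrate, with
the plain WD kernel closing most of the gap by a few hundred examples.
IC50 values are log-normal around class-conditional medians (binders ≈ 20
nM, non-binders ≈ 4000 nM, clipped to stay on the correct side of 500) so
the threshold logic is exercised end to end.

What this emulates — and what it does not: labels depend on anchor
positions through descriptor space, so position-aware and property-aware
kernels both have a real signal to find. Real allele-specific binding
motifs, residue correlations, and measurement noise in IC50 assays are not
modelled; passing tests show the machinery detects planted structure of
this kind, not that any kernel will reach a particular accuracy on real
MHC binding benchmarks.

**Family task.** Each of k families grows from a uniform-random ancestor
of length 40–60; members are copies mutated per position at a given rate,
with replacements drawn ∝ exp(−‖Ψ(a)−Ψ(b)‖²/2) — conservative in
descriptor space, so family identity survives in l-mer content most
visibly to similarity-graded kernels. Real domain families share motifs
and length structure this does not attempt to match. The canned
`family_content_study` uses mutation rate 0.7 because lower rates let
every kernel saturate at auROC 1.0, leaving nothing to compare.

**Profiles.** Row i is ∝ exp(−concentration · ‖Ψ(x_i)−Ψ(k)‖²/d̄²) with a
mild multiplicative gamma jitter, renormalized; concentration → ∞ gives
deterministic profiles, under which the profile kernel provably collapses
to the spectrum kernel (tested).

## Problem sizes

The shipped studies run at desk scale: the binding study uses n = 480
peptides per seed (20 seeds, training sizes 20 and 324, σ grid {0.5, 1, 2},
C grid {0.1, 1, 10}), the family study n = 60 sequences with l = 3.
These sizes were chosen so the full suite and the acceptance script each
complete in minutes while leaving the compared effects well away from
floor and ceiling.

## Known limitations

- spectrum-RBF is quadratic in sequence length per kernel value; use the
  mismatch-RBF or profile-RBF kernels for anything beyond short sequences.
- The mismatch tree recursion is correct for any m but not specially
  optimized for m ≥ 2.
- Encodings must be injective for the σ → 0 recovery to hold exactly;
  standardization preserves injectivity for the shipped sets.
- The harness assumes binary labels; multi-class protein-family work goes
  through one-vs-rest label construction.
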