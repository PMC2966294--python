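"""Compare amino-acid substrings through descriptor encodings.

Builds the builtin encodings and shows how the RBF substring kernel scores
a conservative substitution (I→L, both large hydrophobics) against a
radical one (I→D, hydrophobic → negatively charged) — the distinction
exact-match string kernels cannot see.
"""

from aakernels import SubstringKernelSpec, get_encoding, k_substring, load_builtin_encoding

for name in ("unit", "pca", "zscale", "blosum50"):
    enc = load_builtin_encoding(name)
    print(f"{name:9s} dim={enc.dim}")

enc = get_encoding("zscale")  # standardized 3-component z-scales
rbf = SubstringKernelSpec("rbf", encoding=enc, sigma=1.0)

for u, v in [("ILK", "ILK"), ("ILK", "LLK"), ("ILK", "DLK")]:
    print(f"k_rbf({u}, {v}) = {k_substring(u, v, rbf):.4f}")

# Expected: identical substrings score 1; the conservative I->L substitution
# stays close to 1; the radical I->D substitution drops much lower. With the
# unit encoding all three mismatching pairs would score identically.
unit = SubstringKernelSpec("rbf", encoding=load_builtin_encoding("unit"), sigma=1.0)
print(f"unit encoding: k_rbf(ILK, LLK) = {k_substring('ILK', 'LLK', unit):.4f}, "
      f"k_rbf(ILK, DLK) = {k_substring('ILK', 'DLK', unit):.4f}")
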