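import math

import numpy as np
import pytest

from aakernels import (
    Alphabet,
    ProfileKernel,
    ProfileParams,
    SequenceProfile,
    SubstringKernelSpec,
    gram_matrix,
    k_substring,
    positional_mutation_neighborhood,
    profile_features,
    profile_kernel,
    profile_rbf_features,
    read_profile_tsv,
    read_pssm,
    spectrum_features,
    spectrum_kernel,
    write_profile_tsv,
)

from conftest import all_lmers, random_seqs

ABCD = Alphabet("ABCD")


def deterministic_profile(seq, alphabet=ABCD):
    probs = np.zeros((len(seq), len(alphabet)))
    for i, c in enumerate(seq):
        probs[i, alphabet.index(c)] = 1.0
    return SequenceProfile(seq, probs, alphabet)


def uniform_profile(seq, alphabet=ABCD):
    n = len(alphabet)
    return SequenceProfile(seq, np.full((len(seq), n), 1.0 / n), alphabet)


def random_profile(rng, seq, alphabet=ABCD):
    probs = rng.dirichlet(np.full(len(alphabet), 0.7), size=len(seq))
    return SequenceProfile(seq, probs, alphabet)


def dense_profile_kernel(p1, p2, params):
    kern = ProfileKernel(params)
    f1, f2 = kern.features(p1), kern.features(p2)
    return sum(f1[s] * f2[s] for s in all_lmers(p1.alphabet, params.l))


class TestNeighborhood:
    def test_deterministic_profile_yields_own_lmer(self):
        prof = deterministic_profile("ABCD")
        params = ProfileParams(l=2, delta=5.0)
        assert positional_mutation_neighborhood(prof, 0, params) == {"AB"}
        assert positional_mutation_neighborhood(prof, 2, params) == {"CD"}

    def test_uniform_profile_large_delta_gives_all(self):
        prof = uniform_profile("AAAA")
        delta = 2 * math.log(4) + 1e-9
        params = ProfileParams(l=2, delta=delta)
        assert positional_mutation_neighborhood(prof, 0, params) == set(all_lmers(ABCD, 2))

    def test_strict_inequality_at_equality_boundary(self):
        """Uniform 4-letter profile, l=2, δ = 2·log4: every string costs
        exactly δ, and the strict '< δ' leaves the neighbourhood empty."""
        prof = uniform_profile("AAAA")
        params = ProfileParams(l=2, delta=2 * np.log(4.0))
        assert positional_mutation_neighborhood(prof, 0, params) == set()

    def test_out_of_range_window_rejected(self):
        prof = uniform_profile("AAAA")
        with pytest.raises(ValueError, match="window"):
            positional_mutation_neighborhood(prof, 3, ProfileParams(l=2, delta=1.0))

    def test_monotone_in_delta(self):
        rng = np.random.default_rng(0)
        prof = random_profile(rng, "ABCDABCD")
        params_small = ProfileParams(l=2, delta=1.0)
        params_large = ProfileParams(l=2, delta=3.0)
        for i in range(len(prof) - 1):
            small = positional_mutation_neighborhood(prof, i, params_small)
            large = positional_mutation_neighborhood(prof, i, params_large)
            assert small <= large


class TestFeatures:
    def test_deterministic_profile_equals_spectrum(self):
        prof = deterministic_profile("ABCDDCBA")
        f = profile_features(prof, ProfileParams(l=2, delta=5.0))
        assert f == spectrum_features("ABCDDCBA", 2)

    def test_delta_zero_gives_empty_features(self):
        rng = np.random.default_rng(1)
        prof = random_profile(rng, "ABCD")
        assert profile_features(prof, ProfileParams(l=2, delta=0.0)) == {}

    def test_uniform_profile_counts_all_windows(self):
        prof = uniform_profile("AAAAA")
        delta = 2 * math.log(4) + 1e-6
        f = profile_features(prof, ProfileParams(l=2, delta=delta))
        n_windows = len(prof) - 1
        assert f == {s: n_windows for s in all_lmers(ABCD, 2)}

    def test_entrywise_monotone_in_delta(self):
        rng = np.random.default_rng(2)
        prof = random_profile(rng, "ABCDABCDAB")
        f1 = profile_features(prof, ProfileParams(l=2, delta=1.5))
        f2 = profile_features(prof, ProfileParams(l=2, delta=4.0))
        assert all(f2[s] >= c for s, c in f1.items())

    def test_rbf_features_sigma_to_infinity(self, abcd_toy_encoding):
        rng = np.random.default_rng(3)
        prof = random_profile(rng, "ABCDDA")
        spec = SubstringKernelSpec("rbf", encoding=abcd_toy_encoding, sigma=1e6)
        plain = profile_features(prof, ProfileParams(l=2, delta=3.0))
        weighted = profile_rbf_features(prof, ProfileParams(l=2, delta=3.0, substring_spec=spec))
        assert set(plain) == set(weighted)
        for s in plain:
            assert weighted[s] == pytest.approx(plain[s], abs=1e-6)

    def test_deterministic_rbf_equals_spectrum_any_sigma(self, abcd_toy_encoding):
        prof = deterministic_profile("ABCDDCBA")
        spec = SubstringKernelSpec("rbf", encoding=abcd_toy_encoding, sigma=0.37)
        f = profile_rbf_features(prof, ProfileParams(l=2, delta=5.0, substring_spec=spec))
        assert f == spectrum_features("ABCDDCBA", 2)

    def test_uniform_rbf_entries_are_window_similarities(self, abcd_toy_encoding):
        prof = uniform_profile("ABCD")
        spec = SubstringKernelSpec("rbf", encoding=abcd_toy_encoding, sigma=1.0)
        delta = 2 * math.log(4) + 1e-6
        f = profile_rbf_features(prof, ProfileParams(l=2, delta=delta, substring_spec=spec))
        windows = ["AB", "BC", "CD"]
        for s in all_lmers(ABCD, 2):
            expected = sum(k_substring(w, s, spec) for w in windows)
            assert f[s] == pytest.approx(expected, abs=1e-12)


class TestKernel:
    def test_deterministic_profiles_degenerate_to_spectrum(self):
        rng = np.random.default_rng(4)
        for x, y in zip(random_seqs(rng, 5, 8, ABCD), random_seqs(rng, 5, 8, ABCD)):
            k = profile_kernel(
                deterministic_profile(x), deterministic_profile(y),
                ProfileParams(l=2, delta=5.0),
            )
            assert k == spectrum_kernel(x, y, 2)

    def test_self_kernel_nonnegative(self):
        rng = np.random.default_rng(5)
        prof = random_profile(rng, "ABCDAB")
        assert profile_kernel(prof, prof, ProfileParams(l=2, delta=2.0)) >= 0.0

    @pytest.mark.parametrize("kind", ["exact", "linear", "rbf"])
    @pytest.mark.parametrize("l", [1, 2, 3])
    def test_matches_dense_feature_oracle(self, abcd_toy_encoding, kind, l):
        rng = np.random.default_rng(6)
        spec = (SubstringKernelSpec("exact") if kind == "exact"
                else SubstringKernelSpec(kind, encoding=abcd_toy_encoding, sigma=0.8))
        params = ProfileParams(l=l, delta=2.5 * l, substring_spec=spec)
        for _ in range(5):
            p1 = random_profile(rng, "".join(rng.choice(list("ABCD"), size=8)))
            p2 = random_profile(rng, "".join(rng.choice(list("ABCD"), size=7)))
            assert profile_kernel(p1, p2, params) == pytest.approx(
                dense_profile_kernel(p1, p2, params), abs=1e-9
            )

    def test_gram_psd(self, abcd_toy_encoding):
        rng = np.random.default_rng(7)
        profs = [random_profile(rng, "".join(rng.choice(list("ABCD"), size=8)))
                 for _ in range(12)]
        spec = SubstringKernelSpec("rbf", encoding=abcd_toy_encoding, sigma=1.0)
        kern = ProfileKernel(ProfileParams(l=2, delta=3.0, substring_spec=spec))
        gm = gram_matrix(profs, kern, normalize=False, ids=[p.id for p in profs])
        w = np.linalg.eigvalsh(gm.values)
        assert w.min() >= -1e-8 * w.max()


class TestProfileIO:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        prof = random_profile(rng, "ABCDAB")
        path = tmp_path / "p.tsv"
        write_profile_tsv(path, prof)
        back = read_profile_tsv(path, ABCD)
        assert back.sequence == prof.sequence
        assert np.abs(back.probs - prof.probs).max() < 1e-9

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SequenceProfile("AB", np.array([[0.5, 0.2, 0.1, 0.1], [0.25] * 4]), ABCD)
        with pytest.raises(ValueError, match="non-negative"):
            SequenceProfile("AB", np.array([[1.2, -0.2, 0.0, 0.0], [0.25] * 4]), ABCD)

    def test_pssm_reader_percentages(self, tmp_path):
        # minimal PSI-BLAST ASCII PSSM: header of 40 letters, then rows with
        # position, residue, 20 scores, 20 percentages, 2 trailing stats
        letters = "ARNDCQEGHILKMFPSTWYV"
        header = "   " + " ".join(letters) + "  " + " ".join(letters)
        rows = []
        for pos, res in enumerate("AC", start=1):
            scores = " ".join(["0"] * 20)
            perc = ["0"] * 20
            perc[letters.index(res)] = "80"
            perc[letters.index("G")] = "20"
            rows.append(f"{pos} {res} {scores} {' '.join(perc)} 1.0 0.5")
        text = "\nLast position-specific scoring matrix computed\n" + header + "\n" + "\n".join(rows) + "\n"
        path = tmp_path / "toy.pssm"
        path.write_text(text)
        prof = read_pssm(path)
        assert prof.sequence == "AC"
        a_idx = prof.alphabet.index("A")
        g_idx = prof.alphabet.index("G")
        assert prof.probs[0, a_idx] == pytest.approx(0.8)
        assert prof.probs[0, g_idx] == pytest.approx(0.2)
        assert np.abs(prof.probs.sum(axis=1) - 1).max() < 1e-9
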