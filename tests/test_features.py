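import itertools
from functools import lru_cache

import numpy as np
import pytest

from lncfuse.features import (
    _MIN_LOOP,
    _PAIR_SCORE,
    TranscriptFeaturizer,
    feature_names,
    feature_vector,
    find_orfs,
    kmer_frequencies,
    orf_features,
    structure_features,
)

STOPS = {"TAA", "TAG", "TGA"}


def random_seq(rng, length):
    return "".join(rng.choice(list("ATCG"), size=length))


# ---------------------------------------------------------------------------
# k-mer frequencies


def kmer_oracle(seq):
    """Independent dictionary-count implementation of the 84 components."""
    out = []
    L = len(seq)
    for k in (1, 2, 3):
        a_k = 1.0 / 4 ** (3 - k)
        s_k = L - k + 1
        for word in itertools.product("ATCG", repeat=k):
            w = "".join(word)
            c = sum(1 for i in range(s_k) if seq[i : i + k] == w)
            out.append(a_k * c / s_k)
    return np.array(out)


class TestKmer:
    def test_homopolymer_values(self):
        f = kmer_frequencies("AAAA")
        names = feature_names()
        assert f[names.index("kmer_A")] == pytest.approx(1 / 16)
        assert f[names.index("kmer_AA")] == pytest.approx(0.25)
        assert f[names.index("kmer_AAA")] == pytest.approx(1.0)

    def test_one_mer_components_sum_to_weight(self, rng):
        for _ in range(20):
            f = kmer_frequencies(random_seq(rng, int(rng.integers(3, 200))))
            assert f[:4].sum() == pytest.approx(1 / 16)

    def test_dimension(self):
        assert len(kmer_frequencies("ATCGATCG")) == 84

    def test_matches_counting_oracle(self, rng):
        for _ in range(300):
            seq = random_seq(rng, int(rng.integers(3, 80)))
            np.testing.assert_allclose(kmer_frequencies(seq), kmer_oracle(seq), atol=1e-15)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="k-mers undefined"):
            kmer_frequencies("AT")


# ---------------------------------------------------------------------------
# ORFs


def orf_oracle(seq, min_codons):
    """Enumerate all in-frame ATG..stop spans, then apply the greedy rule."""
    taken = []
    for frame in range(3):
        codons = [(i, seq[i : i + 3]) for i in range(frame, len(seq) - 2, 3)]
        candidates = []
        for ci, (pos, cod) in enumerate(codons):
            if cod != "ATG":
                continue
            for pos2, cod2 in codons[ci + 1 :]:
                if cod2 in STOPS:
                    candidates.append((pos, pos2 + 3))
                    break
        last_end = -1
        for start, end in candidates:
            if start >= last_end and (end - start) // 3 >= min_codons:
                taken.append((start, end))
                last_end = end
            elif start >= last_end:
                last_end = end  # short ORF still advances the scan
    return sorted(taken)


class TestOrfs:
    def test_single_orf(self):
        o = find_orfs("ATGAAATAA", min_codons=2)
        assert o.n == 1 and o.lengths == [9]
        assert o.orfs[0].frame == 0

    def test_no_atg(self):
        o = find_orfs("CCCCCC")
        assert o.n == 0
        assert orf_features("CCCCCC", o) == (0, 0.0, 0.0)

    def test_two_nonoverlapping(self):
        o = find_orfs("ATGTAAATGTAA", min_codons=2)
        assert o.n == 2 and o.lengths == [6, 6]

    def test_short_orfs_discarded(self):
        assert find_orfs("ATGTAAATGTAA", min_codons=3).n == 0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(150):
            seq = random_seq(rng, int(rng.integers(10, 300)))
            got = sorted((o.start, o.end) for o in find_orfs(seq, min_codons=2).orfs)
            assert got == orf_oracle(seq, 2)

    def test_orf_feature_arithmetic(self):
        # one 30-nt ORF in a 100-nt sequence
        seq = "C" * 40 + "ATG" + "GCT" * 8 + "TAA" + "C" * 30
        assert len(seq) == 100
        integ, cov, norf = orf_features(seq, min_codons=5)
        assert (integ, cov, norf) == (1, 0.3, 0.01)


# ---------------------------------------------------------------------------
# structure


@lru_cache(maxsize=None)
def _bf(seq, i, j):
    """Exhaustive (pairs, score) maximisation, lexicographic."""
    if j - i < _MIN_LOOP + 1:
        return (0, 0)
    best = _bf(seq, i + 1, j)
    for k in range(i + _MIN_LOOP + 1, j + 1):
        w = _PAIR_SCORE.get((seq[i], seq[k]))
        if w is None:
            continue
        inner = _bf(seq, i + 1, k - 1)
        right = _bf(seq, k + 1, j)
        cand = (1 + inner[0] + right[0], w + inner[1] + right[1])
        best = max(best, cand)
    return best


def pairing_oracle(seq):
    return _bf(seq, 0, len(seq) - 1)


class TestStructure:
    def test_gc_content(self):
        assert structure_features("ATCG")[1] == 0.5

    def test_no_complementary_bases(self):
        n_pairs, gc, nmfe = structure_features("AAAAAA")
        assert (n_pairs, nmfe) == (0, 0.0)

    def test_hairpin_example(self):
        n_pairs, gc, nmfe = structure_features("GGGAAACCC")
        assert n_pairs == 3
        assert nmfe == pytest.approx(-1.0)  # proxy MFE -9 over 9 nt

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(120):
            seq = random_seq(rng, int(rng.integers(5, 13)))
            n_pairs, gc, nmfe = structure_features(seq)
            bp, score = pairing_oracle(seq)
            assert n_pairs == bp
            assert nmfe == pytest.approx(-score / len(seq))

    def test_gc_plus_at_is_one(self, rng):
        for _ in range(50):
            seq = random_seq(rng, int(rng.integers(1, 50)))
            gc = structure_features(seq)[1]
            at = (seq.count("A") + seq.count("T")) / len(seq)
            assert gc + at == pytest.approx(1.0)

    def test_unknown_engine_errors(self):
        with pytest.raises(ValueError, match="engine"):
            structure_features("ATCGATCG", engine="quantum")


# ---------------------------------------------------------------------------
# combined vector


class TestFeatureVector:
    def test_dimension_is_90(self, strong_dataset):
        pos, neg = strong_dataset
        for t in (pos[0], neg[0]):
            assert feature_vector(t).shape == (90,)
        assert len(feature_names()) == 90

    def test_concatenation_contract(self):
        seq = "ATGAAATAA" * 10
        v = feature_vector(seq, min_codons=2)
        np.testing.assert_allclose(v[:84], kmer_frequencies(seq))
        assert tuple(v[84:87]) == orf_features(seq, min_codons=2)
        np.testing.assert_allclose(v[87:90], structure_features(seq))

    def test_deterministic(self):
        seq = "ATCGATCGGGAAACCC"
        np.testing.assert_array_equal(feature_vector(seq), feature_vector(seq))

    def test_featurizer_transform(self):
        X = ["ATCGATCG" * 4, "GGCCATGG" * 4]
        F = TranscriptFeaturizer().fit(X).transform(X)
        assert F.shape == (2, 90)
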