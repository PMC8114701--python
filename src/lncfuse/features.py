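"""Classical 90-dimensional transcript features.

The vector concatenates, in fixed order:

* 84 weighted k-mer frequencies for k = 1, 2, 3 (4 + 16 + 64 forms,
  lexicographic A<T<C<G within each k).  With a stride-1 window there are
  ``s_k = L - k + 1`` matches; the frequency of form j is
  ``f_j = a_k * c_j / s_k`` with the scale-equalising weight
  ``a_k = 1 / 4**(3 - k)`` (so the four 1-mer components sum to 1/16, etc.);
* 3 open-reading-frame features: integrity ``int`` (1 iff at least one
  complete ATG..stop ORF), coverage ``cov = sum(l_m) / L`` and normalized
  count ``nORF = n / L``;
* 3 secondary-structure features: the number of base pairs of an optimal
  structure, G+C content ``(NG+NC)/L``, and normalized minimum free energy
  ``nMFE = MFE / L``.

ORFs come from an internal three-forward-frame finder (transcripts are
sense-strand cDNA).  The default structure engine is a Nussinov
maximum-base-pairing fold (pairs A-T, G-C, G-T wobble; minimum hairpin loop
3 nt) with the per-pair energy proxy ``MFE = -(3*#GC + 2*#AT + 1*#GT)``;
these proxy energies are on an arbitrary scale and deliberately do not
reproduce a thermodynamic folding program.  An external engine adapter that
parses RNAfold output is available for fidelity.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from lncfuse.encoders import vocabulary
from lncfuse.io import Transcript

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: pair scores of the internal energy proxy (symmetric)
_PAIR_SCORE = {
    ("G", "C"): 3,
    ("C", "G"): 3,
    ("A", "T"): 2,
    ("T", "A"): 2,
    ("G", "T"): 1,
    ("T", "G"): 1,
}
_MIN_LOOP = 3  # minimum unpaired nucleotides in a hairpin loop


def _as_seq(t: "Transcript | str") -> str:
    return t.seq if isinstance(t, Transcript) else t


# ---------------------------------------------------------------------------
# k-mer frequencies


def kmer_frequencies(t: "Transcript | str", ks: Sequence[int] = (1, 2, 3)) -> np.ndarray:
    """Weighted k-mer frequency vector over the given word lengths.

    Forms are ordered lexicographically (A<T<C<G) within each k, k
    ascending; the full default gives the 84 components for k = 1, 2, 3.
    Requires ``L >= max(ks)``.
    """
    seq = _as_seq(t)
    L = len(seq)
    if L < max(ks):
        raise ValueError(f"sequence length {L} < {max(ks)}; k-mers undefined")
    parts = []
    for k in ks:
        s_k = L - k + 1
        a_k = 1.0 / 4 ** (3 - k)
        counts = {w: 0 for w in vocabulary(k)}
        for i in range(s_k):
            counts[seq[i : i + k]] += 1
        parts.append(a_k * np.array(list(counts.values()), dtype=float) / s_k)
    return np.concatenate(parts)


def kmer_feature_names(ks: Sequence[int] = (1, 2, 3)) -> list[str]:
    return [f"kmer_{w}" for k in ks for w in vocabulary(k)]


# ---------------------------------------------------------------------------
# open reading frames


@dataclass
class Orf:
    start: int  #: 0-based index of the A of ATG
    end: int  #: exclusive index just past the stop codon
    frame: int  #: 0, 1 or 2

    @property
    def length(self) -> int:
        """ORF length in nt, stop codon included."""
        return self.end - self.start


@dataclass
class OrfSet:
    orfs: list[Orf]

    @property
    def n(self) -> int:
        return len(self.orfs)

    @property
    def lengths(self) -> list[int]:
        return [o.length for o in self.orfs]


def find_orfs(t: "Transcript | str", min_codons: int = 30) -> OrfSet:
    """Find complete ORFs in the three forward reading frames.

    Within a frame the scan is greedy: the first ATG after the previous
    ORF's stop opens an ORF that runs to the next in-frame stop; an ATG
    with no downstream in-frame stop yields no ORF (integrity requires
    both ends).  ORFs shorter than ``min_codons`` codons (stop included)
    are discarded.  ORFs within one frame never overlap.
    """
    seq = _as_seq(t)
    L = len(seq)
    orfs: list[Orf] = []
    for frame in range(3):
        pos = frame
        while pos + 3 <= L:
            if seq[pos : pos + 3] == "ATG":
                q = pos + 3
                while q + 3 <= L and seq[q : q + 3] not in STOP_CODONS:
                    q += 3
                if q + 3 <= L:  # found an in-frame stop
                    if (q + 3 - pos) // 3 >= min_codons:
                        orfs.append(Orf(start=pos, end=q + 3, frame=frame))
                    pos = q + 3
                    continue
                break  # no stop downstream: nothing more in this frame
            pos += 3
    return OrfSet(orfs=orfs)


def orf_features(t: "Transcript | str", o: OrfSet | None = None, min_codons: int = 30) -> tuple[int, float, float]:
    """ORF integrity, coverage and normalized count: (int, cov, nORF)."""
    seq = _as_seq(t)
    if o is None:
        o = find_orfs(seq, min_codons=min_codons)
    L = len(seq)
    integ = 1 if o.n >= 1 else 0
    cov = sum(o.lengths) / L
    norf = o.n / L
    return integ, cov, norf


# ---------------------------------------------------------------------------
# secondary structure


def _nussinov_value(seq: str) -> tuple[int, int]:
    """(max base pairs, best proxy score among max-pair structures).

    Nussinov dynamic program maximising the pair count, with the proxy
    energy score as lexicographic tie-break.  Values are packed as
    ``pairs * SCALE + score`` so the whole table stays one int64 matrix and
    the k-split maximisation vectorises; no traceback is needed because
    both quantities are recoverable from the packed optimum.
    """
    L = len(seq)
    if L < _MIN_LOOP + 2:
        return 0, 0
    SCALE = 4 * L  # score < 3 * L / 2 < SCALE
    base = np.fromiter((ord(c) for c in seq), dtype=np.int64, count=L)
    pairable = np.zeros((L, L), dtype=np.int64)
    for (a, b), w in _PAIR_SCORE.items():
        pairable += np.where(
            (base[:, None] == ord(a)) & (base[None, :] == ord(b)), SCALE + w, 0
        )
    dp = np.zeros((L, L), dtype=np.int64)
    for span in range(_MIN_LOOP + 1, L):
        i = np.arange(0, L - span)
        j = i + span
        best = np.maximum(dp[i + 1, j], dp[i, j - 1])
        pair_val = pairable[i, j]
        closed = dp[i + 1, j - 1] + pair_val
        best = np.maximum(best, np.where(pair_val > 0, closed, -1))
        # bifurcation: dp[i, k] + dp[k+1, j] for i <= k < j
        for idx in range(len(i)):
            ii, jj = i[idx], j[idx]
            k = np.arange(ii, jj)
            split = dp[ii, k] + dp[k + 1, jj]
            best[idx] = max(best[idx], int(split.max()))
        dp[i, j] = best
    packed = int(dp[0, L - 1])
    return packed // SCALE, packed % SCALE


def _rnafold_engine(seq: str) -> tuple[int, float]:
    """External engine: fold with RNAfold and parse pairs + energy."""
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError(
            "RNAfold not found on PATH; use engine='internal' instead"
        )
    proc = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    )
    line = proc.stdout.strip().splitlines()[-1]
    struct, _, energy = line.partition(" ")
    n_pairs = struct.count("(")
    mfe = float(energy.strip().strip("()"))
    return n_pairs, mfe


def structure_features(
    t: "Transcript | str", engine: str = "internal"
) -> tuple[int, float, float]:
    """Structure features (n_pairs, gc, nmfe) of a transcript.

    ``gc = (NG + NC) / L`` always; pairing and energy come from the chosen
    engine.  Sequences too short to form a hairpin get n_pairs = 0 and
    nmfe = 0.
    """
    seq = _as_seq(t)
    L = len(seq)
    if L < 1:
        raise ValueError("empty sequence")
    gc = (seq.count("G") + seq.count("C")) / L
    if L < _MIN_LOOP + 2:
        return 0, gc, 0.0
    if engine == "internal":
        n_pairs, score = _nussinov_value(seq)
        mfe = -float(score)
    elif engine == "external":
        n_pairs, mfe = _rnafold_engine(seq)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return n_pairs, gc, mfe / L


# ---------------------------------------------------------------------------
# combined vector


def feature_names() -> list[str]:
    return kmer_feature_names() + [
        "orf_int",
        "orf_cov",
        "orf_norm",
        "n_pairs",
        "gc",
        "nmfe",
    ]


def feature_vector(
    t: "Transcript | str", min_codons: int = 30, engine: str = "internal"
) -> np.ndarray:
    """The 90-dimensional feature vector [84 k-mer | 3 ORF | 3 structure]."""
    seq = _as_seq(t)
    if len(seq) < 6:
        raise ValueError(f"sequence length {len(seq)} < 6")
    kmer = kmer_frequencies(seq)
    integ, cov, norf = orf_features(seq, min_codons=min_codons)
    n_pairs, gc, nmfe = structure_features(seq, engine=engine)
    return np.concatenate([kmer, [integ, cov, norf, n_pairs, gc, nmfe]])


class TranscriptFeaturizer(BaseEstimator, TransformerMixin):
    """Sklearn transformer computing the 90-dim vector per sequence.

    Feeds classical (shallow) classifiers; the deep models consume the raw
    encodings instead.
    """

    def __init__(self, min_codons: int = 30, engine: str = "internal"):
        self.min_codons = min_codons
        self.engine = engine

    def fit(self, X, y=None):
        self.feature_names_ = feature_names()
        return self

    def transform(self, X) -> np.ndarray:
        return np.stack(
            [feature_vector(t, self.min_codons, self.engine) for t in X]
        )
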