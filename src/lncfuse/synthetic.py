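"""Synthetic mRNA-like and lncRNA-like transcript generator.

Emulates the two transcript classes with controllable separability so the
full pipeline is testable without downloads:

* **mRNA-like** (negative class, label 0): each sequence hosts exactly one
  long in-frame open reading frame (ATG ... stop) whose interior codons are
  drawn with a 3-periodic composition bias, surrounded by i.i.d. background
  bases.  The ORF covers ``orf_frac_mrna`` of the sequence.
* **lncRNA-like** (positive class, label 1): pure background sequences of at
  least 201 nt (the defining length threshold for lncRNAs) whose base
  composition is offset by ``gc_shift`` relative to the mRNA background.

Setting ``periodicity_strength=0`` degenerates the mRNA-like class to pure
background (no ORF is embedded): together with ``gc_shift=0`` the two
classes are then statistically identical, giving an exact null for
permutation-style checks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from lncfuse.io import LNCRNA, MRNA, Transcript

BASES = "ATCG"
STOP_CODONS = ("TAA", "TAG", "TGA")

# Per-codon-position base preferences (A, T, C, G) used to induce a
# 3-periodic composition inside embedded ORFs. Loosely: purine-biased first
# position, A/T-biased second, G/C-biased wobble position.
_POS_PREFS = np.array(
    [
        [0.35, 0.10, 0.15, 0.40],
        [0.40, 0.35, 0.15, 0.10],
        [0.10, 0.15, 0.40, 0.35],
    ]
)


@dataclass
class SynthConfig:
    """Generation parameters; defaults are the strong-effect condition.

    Attributes
    ----------
    n_pos, n_neg : int
        Number of lncRNA-like / mRNA-like sequences.
    len_range : (int, int)
        Inclusive sequence-length range in nt; the minimum must be >= 201
        for the lncRNA-like class.
    orf_frac_mrna : float
        Target fraction of each mRNA-like sequence covered by its ORF.
    gc_shift : float
        G+C composition offset of the lncRNA-like background relative to
        the 0.5 G+C mRNA background.
    periodicity_strength : float in [0, 1]
        Mixture weight of the codon-position preference inside ORFs; 0
        disables the ORF entirely (pure background null).
    seed : int
        Generation is deterministic given the seed.
    """

    n_pos: int = 400
    n_neg: int = 400
    len_range: tuple[int, int] = (210, 400)
    orf_frac_mrna: float = 0.9
    gc_shift: float = 0.1
    periodicity_strength: float = 0.9
    seed: int = 0

    def validated(self) -> "SynthConfig":
        lo, hi = self.len_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid len_range {self.len_range}")
        for name in ("orf_frac_mrna", "periodicity_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= 0.5 + self.gc_shift <= 1.0:
            raise ValueError(f"gc_shift {self.gc_shift} leaves [0, 1] G+C")
        return self


#: named effect presets for the command line
EFFECT_PRESETS = {
    "none": dict(orf_frac_mrna=0.0, gc_shift=0.0, periodicity_strength=0.0),
    "weak": dict(orf_frac_mrna=0.5, gc_shift=0.02, periodicity_strength=0.3),
    "strong": dict(orf_frac_mrna=0.9, gc_shift=0.1, periodicity_strength=0.9),
}


def _sense_codon_table() -> list[str]:
    return [
        "".join(c)
        for c in itertools.product(BASES, repeat=3)
        if "".join(c) not in STOP_CODONS
    ]


_SENSE_CODONS = _sense_codon_table()


def _codon_probs(strength: float) -> np.ndarray:
    """Mixture (1-s)*uniform + s*positional-preference over sense codons."""
    pref = np.array(
        [
            _POS_PREFS[0, BASES.index(c[0])]
            * _POS_PREFS[1, BASES.index(c[1])]
            * _POS_PREFS[2, BASES.index(c[2])]
            for c in _SENSE_CODONS
        ]
    )
    pref /= pref.sum()
    n = len(_SENSE_CODONS)
    return (1.0 - strength) / n + strength * pref


def _background(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def gen_mrna_like(cfg: SynthConfig) -> list[Transcript]:
    """Generate mRNA-like sequences (label 0), one embedded ORF each.

    The ORF is ``ATG + sense codons + stop`` with total length the largest
    multiple of 3 not exceeding ``orf_frac_mrna * L`` (at least 3 codons),
    placed uniformly at random; flanks are background.  With
    ``periodicity_strength == 0`` no ORF is embedded (pure background).

    Raises
    ------
    ValueError
        If the requested length cannot host a 3-codon ORF.
    """
    cfg = cfg.validated()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.len_range
    strength = cfg.periodicity_strength
    if strength > 0.0 and int(cfg.orf_frac_mrna * lo) < 9:
        raise ValueError(
            f"len_range minimum {lo} too short to host an ORF covering "
            f"{cfg.orf_frac_mrna:.2f} of the sequence (need >= 9 nt)"
        )
    codon_p = _codon_probs(strength)
    out = []
    for i in range(cfg.n_neg):
        length = int(rng.integers(lo, hi + 1))
        if strength == 0.0:
            seq = _background(rng, length, gc=0.5)
        else:
            orf_nt = min(3 * (int(cfg.orf_frac_mrna * length) // 3), length)
            orf_nt = max(orf_nt, 9)
            n_interior = orf_nt // 3 - 2
            interior = rng.choice(_SENSE_CODONS, size=n_interior, p=codon_p)
            stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
            orf = "ATG" + "".join(interior) + stop
            start = int(rng.integers(0, length - orf_nt + 1))
            seq = (
                _background(rng, start, gc=0.5)
                + orf
                + _background(rng, length - start - orf_nt, gc=0.5)
            )
        out.append(Transcript(id=f"mrna_{i}", seq=seq, label=MRNA))
    return out


def gen_lncrna_like(cfg: SynthConfig) -> list[Transcript]:
    """Generate lncRNA-like background sequences (label 1), all >= 201 nt.

    Raises
    ------
    ValueError
        If ``len_range`` allows sequences shorter than 201 nt.
    """
    cfg = cfg.validated()
    if cfg.len_range[0] < 201:
        raise ValueError(
            f"lncRNA-like sequences must be >= 201 nt; len_range minimum "
            f"{cfg.len_range[0]} is too short"
        )
    # independent stream from the mRNA generator
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    lo, hi = cfg.len_range
    gc = 0.5 + cfg.gc_shift
    out = []
    for i in range(cfg.n_pos):
        length = int(rng.integers(lo, hi + 1))
        out.append(
            Transcript(id=f"lnc_{i}", seq=_background(rng, length, gc), label=LNCRNA)
        )
    return out


def gen_dataset(cfg: SynthConfig) -> tuple[list[Transcript], list[Transcript]]:
    """Generate (positives, negatives) = (lncRNA-like, mRNA-like)."""
    return gen_lncrna_like(cfg), gen_mrna_like(cfg)


def config_for_effect(effect: str, **overrides) -> SynthConfig:
    """Build a :class:`SynthConfig` from a named effect preset."""
    if effect not in EFFECT_PRESETS:
        raise ValueError(f"unknown effect {effect!r}; choose from {sorted(EFFECT_PRESETS)}")
    return replace(SynthConfig(**EFFECT_PRESETS[effect]), **overrides)
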