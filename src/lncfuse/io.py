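"""Transcript records, FASTA input/output and stratified dataset splitting.

Sequences are normalised to the DNA alphabet {A,T,C,G}: ``U`` is mapped to
``T`` (cDNA convention) and lowercase is folded to uppercase.  Records with
ambiguous IUPAC codes (``N``, ``R``, ...) cannot be represented by either
encoding style and are dropped with a warning by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ATCG")
#: characters accepted in raw input (before normalisation)
ACCEPTED_RAW = frozenset("ATCGUatcgu")

LNCRNA = 1  #: positive class: long noncoding RNA
MRNA = 0  #: negative class: messenger RNA


@dataclass
class Transcript:
    """A validated nucleotide sequence with an optional class label.

    Parameters
    ----------
    id : str
        Record identifier.
    seq : str
        Nucleotide sequence over {A,T,C,G} (use :meth:`from_raw` to
        normalise arbitrary input).
    label : int or None
        1 for lncRNA, 0 for mRNA, None if unknown.
    """

    id: str
    seq: str
    label: int | None = None

    @property
    def length(self) -> int:
        return len(self.seq)

    @classmethod
    def from_raw(cls, id: str, seq: str, label: int | None = None) -> "Transcript":
        """Build a transcript from raw sequence text (U->T, case folded)."""
        return cls(id=id, seq=normalize_seq(seq), label=label)


def normalize_seq(seq: str) -> str:
    """Fold case and map U to T. Does not validate the alphabet."""
    return seq.upper().replace("U", "T")


def validate(t: Transcript, policy: str = "drop_record") -> Transcript | None:
    """Validate a transcript's alphabet.

    Parameters
    ----------
    t : Transcript
    policy : {"reject", "drop_record"}
        ``reject`` raises on the first invalid character (naming its
        position); ``drop_record`` returns None and logs a warning.

    Returns
    -------
    Transcript or None
        The unchanged transcript if valid, else None under ``drop_record``.
    """
    if policy not in ("reject", "drop_record"):
        raise ValueError(f"unknown policy {policy!r}")
    for pos, ch in enumerate(t.seq):
        if ch not in VALID_BASES:
            if policy == "reject":
                raise ValueError(
                    f"invalid character {ch!r} at position {pos} in record {t.id!r}"
                )
            logger.warning(
                "dropping record %r: invalid character %r at position %d",
                t.id,
                ch,
                pos,
            )
            return None
    if t.length < 1:
        if policy == "reject":
            raise ValueError(f"empty sequence in record {t.id!r}")
        logger.warning("dropping record %r: empty sequence", t.id)
        return None
    return t


def read_fasta(
    path: str | Path,
    label: int | None = None,
    policy: str = "drop_record",
    dedup: bool = False,
) -> list[Transcript]:
    """Read a FASTA file into a list of transcripts, in file order.

    Sequences are normalised (U->T, uppercased) and validated under
    ``policy``.  ``dedup=True`` removes records whose sequence was already
    seen (first occurrence kept).

    Raises
    ------
    ValueError
        If the file contains no FASTA records, or on invalid characters
        when ``policy="reject"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: list[Transcript] = []
    seen: set[str] = set()
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        t = Transcript.from_raw(rec.id, str(rec.seq), label=label)
        t = validate(t, policy=policy)
        if t is None:
            continue
        if dedup:
            if t.seq in seen:
                logger.warning("dropping duplicate record %r", t.id)
                continue
            seen.add(t.seq)
        out.append(t)
    if n_records == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> int:
    """Write transcripts to FASTA; returns the number of records written."""
    records = [
        SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts
    ]
    return SeqIO.write(records, str(Path(path)), "fasta")


@dataclass
class DatasetSplit:
    """A stratified train/test partition of a labeled sample set."""

    train: list[Transcript]
    test: list[Transcript]
    fraction: float
    seed: int = field(default=0)


def split(samples: Sequence[Transcript], fraction: float, seed: int) -> DatasetSplit:
    """Stratified random train/test split.

    Per class, ``round(fraction * n_class)`` samples go to the training
    partition; the rest are held out.  Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        If ``fraction`` is outside (0, 1), any sample is unlabeled, or
        only one class is present.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    labels = [t.label for t in samples]
    if any(lab is None for lab in labels):
        raise ValueError("all samples must be labeled for a stratified split")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError(
            f"stratified split requires both classes, found only {classes}"
        )
    rng = np.random.default_rng(seed)
    train: list[Transcript] = []
    test: list[Transcript] = []
    for cls in classes:
        idx = np.flatnonzero(np.asarray(labels) == cls)
        perm = rng.permutation(idx)
        n_train = int(round(fraction * len(idx)))
        train.extend(samples[i] for i in perm[:n_train])
        test.extend(samples[i] for i in perm[n_train:])
    return DatasetSplit(train=train, test=test, fraction=fraction, seed=seed)
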