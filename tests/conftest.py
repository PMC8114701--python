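import numpy as np
import pytest

from lncfuse.io import LNCRNA, MRNA, Transcript
from lncfuse.synthetic import SynthConfig, gen_dataset


@pytest.fixture(scope="session")
def strong_dataset():
    """A small strong-effect dataset shared across tests (pos, neg)."""
    cfg = SynthConfig(n_pos=60, n_neg=60, len_range=(210, 300), seed=7)
    return gen_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, length, bases="ATCG"):
    return "".join(rng.choice(list(bases), size=length))


@pytest.fixture()
def toy_labeled():
    """Tiny labeled transcript list with both classes."""
    seqs = ["ATCG" * 60, "GGCC" * 55, "ATAT" * 58, "CGCG" * 52]
    labels = [LNCRNA, LNCRNA, MRNA, MRNA]
    return [
        Transcript(id=f"t{i}", seq=s, label=lab)
        for i, (s, lab) in enumerate(zip(seqs, labels))
    ]
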