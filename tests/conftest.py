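import numpy as np
import pytest

from tsakit.core import TranscriptRecord
from tsakit.simulate import SimConfig, generate_transcriptome


@pytest.fixture(scope="session")
def protein_bench():
    """Truth-labelled assembly with >= 400 planted proteins of all categories."""
    cfg = SimConfig(
        seed=11, n_components=520, n_secreted=130, n_tm=110, n_mito=80, n_cytosolic=200
    )
    return generate_transcriptome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_transcript(rng, n, tid="comp0_c0_seq1", alphabet="ACGT"):
    return TranscriptRecord(tid, "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n)))
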