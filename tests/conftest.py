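import numpy as np
import pytest

from crispramp.model import PipelineConfig, Read


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230615)


def make_read(seq: str, quals=None, mate: str = "R1", read_id: str = "r") -> Read:
    if quals is None:
        quals = np.full(len(seq), 35, dtype=np.int16)
    elif np.isscalar(quals):
        quals = np.full(len(seq), int(quals), dtype=np.int16)
    else:
        quals = np.asarray(quals, dtype=np.int16)
    return Read(read_id, seq, quals, mate)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
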