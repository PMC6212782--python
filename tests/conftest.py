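import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pamquant import AmpliconRef, make_amplicon


@pytest.fixture(scope="session")
def amplicon() -> AmpliconRef:
    """240 bp amplicon, protospacer [100, 123) on '+', PAM TTTA at [96, 100),
    cut site 118 at the default offset."""
    return make_amplicon(length=240, protospacer_start=100, spacer_len=23,
                         pam="TTTA", strand="+", seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
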