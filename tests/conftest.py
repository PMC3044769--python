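import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mirneq import load_parameters

BASES = np.array(list("ACGU"))


@pytest.fixture(scope="session")
def params():
    return load_parameters("default")


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))
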