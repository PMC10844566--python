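import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240123)


def random_trace(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random trace biased toward ties/plateaus and boundary extremes."""
    kind = rng.integers(0, 3)
    if kind == 0:  # small integer alphabet: plateaus and tied cols
        v = rng.integers(0, 6, size=n).astype(float)
    elif kind == 1:  # continuous
        v = rng.normal(0, 1, size=n)
    else:  # smooth + discrete mix, frequent boundary maxima
        v = np.round(np.cumsum(rng.normal(0, 1, size=n)), 1)
    return v
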