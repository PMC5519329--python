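import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from prdm9kit.motif import PWM

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_finger(rng: np.random.Generator) -> str:
    """One random valid 28-aa C2H2 finger."""
    seq = [AA20[i] for i in rng.integers(len(AA20), size=28)]
    seq[2], seq[5], seq[18], seq[22] = "C", "C", "H", "H"
    return "".join(seq)


def random_protein(rng: np.random.Generator, n: int = 120) -> str:
    """Random protein sequence (may contain fingers by chance)."""
    return "".join(AA20[i] for i in rng.integers(len(AA20), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def sharp_pwm(rng):
    """A 12-column PWM with near-deterministic columns (high IC)."""
    L = 12
    mat = np.full((L, 4), 0.02)
    mat[np.arange(L), rng.integers(4, size=L)] = 0.94
    return PWM(mat, name="sharp")


def random_genome(rng: np.random.Generator, sizes: dict[str, int]) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {c: "".join(bases[rng.integers(4, size=n)]) for c, n in sizes.items()}
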