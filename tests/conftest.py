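from fractions import Fraction
from math import comb

import pytest

from phasfinder.sequence_io import Transcript


def hypergeom_tail_oracle(k: int, n: int, m: int, p: int) -> Fraction:
    """Exact-rational upper tail of the phasing hypergeometric.

    Independent enumeration of the tail terms with big-integer binomials;
    used as the oracle against the production (scipy-backed) implementation.
    """
    total = comb(p * m, n)
    return sum(
        (Fraction(comb(m, x) * comb((p - 1) * m, n - x), total)
         for x in range(k, min(m, n) + 1)),
        start=Fraction(0),
    )


@pytest.fixture
def toy_transcript() -> Transcript:
    """A 400-nt deterministic, non-repetitive transcript."""
    import random

    rng = random.Random(42)
    return Transcript(id="toy1", seq="".join(rng.choice("ACGT") for _ in range(400)))
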