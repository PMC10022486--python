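import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # test-local oracles

from myrtle.kaks import SENSE_CODONS, STOP_CODONS  # noqa: E402


def random_valid_pair(rng: np.random.Generator, max_codons: int = 5):
    """A random stop-free codon-aligned pair for oracle comparisons."""
    n = int(rng.integers(1, max_codons + 1))
    codons_a = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n)]
    codons_b = []
    for codon in codons_a:
        while True:
            cb = list(codon)
            for pos in range(3):
                if rng.random() < 0.35:
                    cb[pos] = "ACGT"[rng.integers(0, 4)]
            cand = "".join(cb)
            if cand not in STOP_CODONS:
                codons_b.append(cand)
                break
    return "".join(codons_a), "".join(codons_b)


@pytest.fixture(scope="session")
def expression_sim():
    from myrtle.simulate import ExpressionSimParams, simulate_expression

    return simulate_expression(ExpressionSimParams(seed=5))
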