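import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from rloopscape.intervals import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_intervals(rng, n, genome_size, max_len=300, chrom="chr1"):
    out = []
    for _ in range(n):
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, max(1, genome_size - length)))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across tests (seed fixed)."""
    from rloopscape.synthetic_data import SimulationConfig, simulate_all

    return simulate_all(SimulationConfig(seed=11))
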