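import numpy as np
import pytest

from karyoscan.core import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_intervals(rng, n, seq_ids=("s1", "s2", "s3"), max_pos=1000, max_len=60):
    """Random interval set for oracle comparisons."""
    out = []
    for _ in range(n):
        seq_id = seq_ids[int(rng.integers(len(seq_ids)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(seq_id, start, start + length))
    return out


def covered_positions(intervals):
    """Brute-force set of (seq_id, position) covered by an interval set."""
    pos = set()
    for iv in intervals:
        for p in range(iv.start, iv.end):
            pos.add((iv.seq_id, p))
    return pos
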