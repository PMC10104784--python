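import numpy as np
import pytest

from epientropy.io import ReadProfile


def make_read(read_id, pos_states, chrom="chr1", start=None, end=None):
    """Build a ReadProfile from a list of (pos, state) tuples."""
    pos_states = sorted(pos_states)
    positions = np.array([p for p, _ in pos_states], dtype=np.int64)
    states = np.array([s for _, s in pos_states], dtype=np.int8)
    if start is None:
        start = int(positions[0])
    if end is None:
        end = int(positions[-1]) + 1
    return ReadProfile(read_id, chrom, start, end, positions, states)


@pytest.fixture
def read_factory():
    return make_read
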