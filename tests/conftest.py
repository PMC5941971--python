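import numpy as np
import pytest

from ptrcat.model import GenomicInterval, TRCandidate


@pytest.fixture
def rng():
    return np.random.default_rng(20180502)


def make_candidate(start, end, motif="AC", seq_id="chr1", units=None,
                   sequence=None, tools=frozenset({"TRF"})):
    """Interval-level candidate helper; sequence defaults to a motif tiling."""
    length = end - start
    if sequence is None:
        sequence = (motif * (length // len(motif) + 1))[:length]
    if units is None:
        units = length / len(motif)
    return TRCandidate(
        interval=GenomicInterval(seq_id, start, end),
        motif=motif, unit_count_ref=float(units),
        sequence=sequence, source_tools=tools)


@pytest.fixture
def candidate_factory():
    return make_candidate
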