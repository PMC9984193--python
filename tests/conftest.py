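import numpy as np
import pytest

from chromaburst.datatypes import GeneActivityMatrix, LocusTraceSet


@pytest.fixture
def line_traces():
    """Two chromosome copies with 5 loci laid out on the x axis; copy 2 is
    copy 1 shifted, so pair distances are hand-computable."""
    base = np.zeros((5, 3))
    base[:, 0] = [0.0, 300.0, 600.0, 1000.0, 1500.0]
    coords = np.stack([base, base * 1.2])  # second copy stretched by 1.2
    return LocusTraceSet(
        coords=coords,
        genomic_start=np.arange(5, dtype=np.int64) * 50_000,
        chromosome_ids=np.array(["c0", "c1"]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_activity(states, promoters=None, gene_ids=None):
    states = np.asarray(states, dtype=float)
    if promoters is None:
        promoters = np.arange(states.shape[1])
    return GeneActivityMatrix(
        states=states,
        promoter_locus=np.asarray(promoters),
        gene_ids=gene_ids or [f"g{k}" for k in range(states.shape[1])],
    )
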