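import numpy as np
import pandas as pd
import pytest

from micronet.otu import OtuTable
from micronet.simulate import SyntheticTruth, make_precision, synth_graph


def make_table(counts, sample_ids=None, taxon_ids=None, meta_extra=None):
    """Small OtuTable from a taxa x samples array."""
    counts = np.asarray(counts)
    p, n = counts.shape
    taxon_ids = taxon_ids or [f"OTU{i:03d}" for i in range(p)]
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"subject_id": sample_ids, "group": "control",
         "experiment": "test", "time_point": 0},
        index=sample_ids,
    )
    if meta_extra:
        for k, v in meta_extra.items():
            meta[k] = v
    return OtuTable(
        counts=pd.DataFrame(counts, index=taxon_ids, columns=sample_ids),
        sample_meta=meta,
    )


@pytest.fixture
def small_table():
    return make_table([[5, 0, 12, 3], [1, 9, 0, 2], [4, 4, 4, 4]])


@pytest.fixture
def band_truth():
    adj = synth_graph(10, "band", n_edges=9, rng_seed=0)
    return SyntheticTruth(graph=adj, precision=make_precision(adj, rng_seed=0))
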