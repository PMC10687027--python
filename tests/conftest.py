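import networkx as nx
import numpy as np
import pandas as pd
import pytest

from orcnet.net_io import OmicsMatrix
from orcnet.sample_graph import build_weighted_graph


@pytest.fixture
def k3_uniform():
    """Triangle with uniform node values."""
    net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
    return net, build_weighted_graph(net, {n: 1.0 for n in net})


@pytest.fixture
def p3_uniform():
    """Path a-b-c with uniform node values."""
    net = nx.Graph([("a", "b"), ("b", "c")])
    return net, build_weighted_graph(net, {n: 1.0 for n in net})


@pytest.fixture
def toy_cohort_tables():
    """Tiny 5-gene, 6-sample cohort with all three omics layers."""
    rng = np.random.default_rng(42)
    net = nx.Graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("A", "C"), ("D", "E")])
    genes = sorted(net.nodes())
    samples = [f"s{k}" for k in range(1, 7)]
    tpm = pd.DataFrame(rng.uniform(1, 100, size=(5, 6)), index=genes, columns=samples)
    counts = pd.DataFrame(rng.integers(5, 500, size=(5, 6)), index=genes, columns=samples)
    cna = pd.DataFrame(2.0, index=genes, columns=samples)
    clinical = pd.DataFrame({
        "sample": samples,
        "pfs_time": [1.0, 2.0, 0.5, 3.0, 1.5, 2.5],
        "event": [1, 0, 1, 0, 1, 1],
        "iss": ["I", "II", "III", "I", "II", "III"],
    }).set_index("sample", drop=False)
    matrices = {
        "tpm": OmicsMatrix(tpm, "tpm"),
        "counts": OmicsMatrix(counts, "counts"),
        "cna": OmicsMatrix(cna, "cna"),
    }
    return net, matrices, clinical
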