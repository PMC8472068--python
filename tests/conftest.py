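import numpy as np
import pytest

import pathwalk as pw


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-signal dataset shared by pipeline-level tests."""
    cfg = pw.SimConfig(
        n_genes=400,
        n_samples_per_class=[20] * 3,
        n_pathways=40,
        pathway_size=(5, 12),
        n_informative_pathways=6,
        effect_size=2.0,
        seed=11,
    )
    return pw.generate(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The package's reference study conditions (used by heavier checks)."""
    return pw.generate(pw.SimConfig(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_graph(rng, n=50, p=0.08):
    """Random directed graph over n string-labelled nodes."""
    nodes = [f"g{i}" for i in range(n)]
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    edges = [(nodes[i], nodes[j]) for i, j in zip(*np.nonzero(mask))]
    return pw.DirectedGeneGraph(set(nodes), edges)


def random_restart(rng, node_ids):
    w = rng.random(len(node_ids))
    return pw.WeightVector(list(node_ids), w / w.sum(), "initial")
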