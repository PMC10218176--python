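import networkx as nx
import numpy as np
import pandas as pd
import pytest

from persig import SimConfig, simulate_perturbagen_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """200-protein dose-series experiment with planted effects."""
    cfg = SimConfig(n_proteins=200, doses=(1.0, 10.0),
                    compartments=("cytoplasm", "membrane"),
                    dep_fraction=0.1, effect_size_log2=2.0,
                    noise_sd_log2=0.3, missing_rate=0.05, seed=42)
    matrix, truth = simulate_perturbagen_experiment(cfg)
    return cfg, matrix, truth


@pytest.fixture
def weighted_graph():
    """Builder for small undirected graphs from (u, v, confidence) triples."""
    def build(edges, nodes=()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, c in edges:
            g.add_edge(u, v, confidence=c)
        return g
    return build


def toy_ratio_table(ratios, ids=None):
    """Minimal log-ratio table in the shape compute_log_ratios emits."""
    ids = ids or [f"P{i:05d}" for i in range(1, len(ratios) + 1)]
    out = pd.DataFrame({"log2_ratio": np.asarray(ratios, dtype=float),
                        "n_case": 3, "n_mock": 3, "n_used": 6},
                       index=pd.Index(ids, name="protein_id"))
    return out
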