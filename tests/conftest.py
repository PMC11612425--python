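import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spatialhet.graph import SpatialGraph


def make_graph(edges, labels, type_universe=None):
    """Small labeled graph from an edge list and a cell_id -> label map."""
    ids = sorted(labels)
    index = {c: i for i, c in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        adj[index[a], index[b]] = adj[index[b], index[a]] = True
    return SpatialGraph(
        cell_ids=np.array(ids, dtype=object),
        adjacency=sp.csr_matrix(adj),
        labels=np.array([labels[c] for c in ids], dtype=object),
        type_universe=type_universe or sorted(set(labels.values())),
    )


@pytest.fixture
def star_graph():
    """Hub of type A with three B leaves, |T| = 2."""
    return make_graph(
        edges=[("hub", "l1"), ("hub", "l2"), ("hub", "l3")],
        labels={"hub": "A", "l1": "B", "l2": "B", "l3": "B"},
    )


@pytest.fixture
def path_aabb():
    """Path a-b-c-d labeled A-A-B-B."""
    return make_graph(
        edges=[("a", "b"), ("b", "c"), ("c", "d")],
        labels={"a": "A", "b": "A", "c": "B", "d": "B"},
    )


def cell_frame(points, sample_id="S1", condition="X", cell_types=None):
    ids = [f"c{i}" for i in range(len(points))]
    return pd.DataFrame(
        {
            "cell_id": ids,
            "x": [p[0] for p in points],
            "y": [p[1] for p in points],
            "sample_id": sample_id,
            "condition": condition,
            "cell_type": cell_types if cell_types is not None else ["A"] * len(points),
        }
    )
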