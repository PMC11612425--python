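"""Spatial neighborhood graphs on segmented cells.

A spatial cell graph connects the centroids of segmented cells of one tissue
sample by the edges of their Delaunay triangulation.  The triangulation is
parameter-free (unlike k-nearest-neighbor or distance-threshold graphs) and
always connected for >= 3 non-collinear points, which makes hop distance a
well-defined notion of tissue-scale vicinity.

The r-hop neighborhood of a cell c is the set of cells whose unweighted
shortest-path distance from c is at most r (c itself included).  Local
heterogeneity scores are computed on these neighborhoods, see
:mod:`spatialhet.scores`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError
from scipy.sparse.csgraph import dijkstra

UNKNOWN_LABEL = "unknown"


class GraphConstructionError(ValueError):
    """Raised when a point set does not admit a Delaunay spatial graph."""


@dataclass
class Neighborhood:
    """The r-hop neighborhood N_r(c) of a single cell."""

    center: object
    radius: int
    members: set
    induced_edges: set  # set of frozenset({u, v}) cell_id pairs


@dataclass
class SpatialGraph:
    """Undirected labeled graph on the cells of one sample.

    Attributes
    ----------
    cell_ids : ndarray of cell identifiers, in canonical (sorted) order.
    adjacency : boolean CSR adjacency matrix (symmetric, zero diagonal).
    labels : ndarray of cell-type labels aligned with ``cell_ids``.
    type_universe : ordered list of labels used for entropy normalization;
        fixed cohort-wide so that scores are comparable across samples.
    """

    cell_ids: np.ndarray
    adjacency: sp.csr_matrix
    labels: np.ndarray
    type_universe: list = field(default_factory=list)

    def __post_init__(self):
        self._index = {cid: i for i, cid in enumerate(self.cell_ids)}
        if not self.type_universe:
            self.type_universe = sorted({str(l) for l in self.labels})
        extra = {str(l) for l in self.labels} - set(self.type_universe)
        if extra:
            raise GraphConstructionError(f"labels outside the type universe: {sorted(extra)}")

    @property
    def n_vertices(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def index_of(self, cell_id) -> int:
        try:
            return self._index[cell_id]
        except KeyError:
            raise KeyError(f"cell {cell_id!r} is not a vertex of this graph") from None

    def edge_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Each undirected edge once, as (u, v) index arrays with u < v."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return coo.row, coo.col

    def edge_list(self) -> list:
        u, v = self.edge_indices()
        return [frozenset((self.cell_ids[a], self.cell_ids[b])) for a, b in zip(u, v)]

    def label_codes(self) -> np.ndarray:
        """Labels as integer codes into ``type_universe``."""
        lut = {t: i for i, t in enumerate(self.type_universe)}
        return np.array([lut[str(l)] for l in self.labels], dtype=np.int64)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(edge list, node attributes) as DataFrames for CSV export."""
        u, v = self.edge_indices()
        edges = pd.DataFrame({"source": self.cell_ids[u], "target": self.cell_ids[v]})
        nodes = pd.DataFrame({"cell_id": self.cell_ids, "cell_type": self.labels})
        return edges, nodes


def build_delaunay_graph(cells: pd.DataFrame, type_universe: list | None = None) -> SpatialGraph:
    """Build the Delaunay spatial graph of one sample's cell centroids.

    *cells* is a cell-table slice for a single sample (columns cell_id, x, y
    and optionally cell_type).  Edges are exactly the edges of the Delaunay
    triangulation of the centroids, deduplicated and undirected.

    Raises
    ------
    GraphConstructionError
        For fewer than 3 cells, duplicate coordinates, or an all-collinear
        point set; the message names the offending cells.
    """
    if "sample_id" in cells.columns and cells["sample_id"].nunique() > 1:
        raise GraphConstructionError("build_delaunay_graph expects cells of a single sample")
    cells = cells.sort_values("cell_id", kind="stable").reset_index(drop=True)
    if len(cells) < 3:
        raise GraphConstructionError(
            f"need at least 3 cells for a Delaunay graph, got {len(cells)} "
            f"({cells['cell_id'].tolist()})"
        )
    pts = cells[["x", "y"]].to_numpy(dtype=float)
    dup_mask = pd.DataFrame(pts).duplicated(keep=False).to_numpy()
    if dup_mask.any():
        raise GraphConstructionError(
            "duplicate centroid coordinates (possible segmentation failure) for cells: "
            f"{cells.loc[dup_mask, 'cell_id'].tolist()[:10]}"
        )
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise GraphConstructionError(
            f"Delaunay triangulation failed (all-collinear points?): first cells "
            f"{cells['cell_id'].tolist()[:10]}"
        ) from exc
    n = len(cells)
    s = tri.simplices
    u = np.concatenate([s[:, 0], s[:, 1], s[:, 2]])
    v = np.concatenate([s[:, 1], s[:, 2], s[:, 0]])
    adj = sp.coo_matrix((np.ones(len(u), dtype=bool), (u, v)), shape=(n, n)).tocsr()
    adj = ((adj + adj.T) > 0).tocsr()
    adj.setdiag(False)
    adj.eliminate_zeros()
    if "cell_type" in cells.columns:
        labels = cells["cell_type"].fillna(UNKNOWN_LABEL).astype(str).to_numpy()
    else:
        labels = np.full(n, UNKNOWN_LABEL, dtype=object)
    return SpatialGraph(
        cell_ids=cells["cell_id"].to_numpy(),
        adjacency=adj,
        labels=labels,
        type_universe=type_universe or sorted(set(map(str, labels))),
    )


def _binarize(m: sp.spmatrix) -> sp.csr_matrix:
    m = m.tocsr()
    m.eliminate_zeros()
    out = m.copy()
    out.data = np.ones_like(out.data, dtype=np.int32)
    return out


def hop_reachability(adjacency: sp.spmatrix, radii) -> dict:
    """Reachability-within-r matrices for each radius in *radii*.

    Returns a dict radius -> CSR matrix R with R[i, j] = 1 iff the hop
    distance d(i, j) <= radius (the diagonal is always set: d(i, i) = 0).
    Computed by incremental boolean sparse matrix products; expansion stops
    early once the reachable sets converge (r beyond the graph diameter),
    after which all remaining radii share the converged matrix.
    """
    radii = sorted(set(int(r) for r in radii))
    if any(r < 0 for r in radii):
        raise ValueError("radii must be non-negative")
    n = adjacency.shape[0]
    a = _binarize(adjacency)
    reach = _binarize(sp.identity(n, dtype=np.int32, format="csr"))
    out = {}
    converged = False
    step = 0
    for r in radii:
        while step < r and not converged:
            nxt = _binarize(reach + reach @ a)
            if nxt.nnz == reach.nnz:
                converged = True
            reach = nxt
            step += 1
        out[r] = reach
    return out


def khop_neighborhood(graph: SpatialGraph, center, r: int) -> Neighborhood:
    """N_r(center): all cells within hop distance r, plus the induced edges.

    r = 0 yields the singleton {center} with no induced edges.  On a
    disconnected graph, vertices unreachable from *center* are outside every
    finite-radius neighborhood.
    """
    if r < 0:
        raise ValueError("radius must be non-negative")
    i = graph.index_of(center)
    dist = dijkstra(graph.adjacency, unweighted=True, indices=i, limit=r)
    member_idx = np.flatnonzero(dist <= r)
    members = {graph.cell_ids[j] for j in member_idx}
    in_hood = np.zeros(graph.n_vertices, dtype=bool)
    in_hood[member_idx] = True
    u, v = graph.edge_indices()
    keep = in_hood[u] & in_hood[v]
    induced = {
        frozenset((graph.cell_ids[a], graph.cell_ids[b]))
        for a, b in zip(u[keep], v[keep])
    }
    return Neighborhood(center=center, radius=int(r), members=members, induced_edges=induced)


def all_khop_neighborhoods(graph: SpatialGraph, r: int) -> dict:
    """Batch form of :func:`khop_neighborhood` for every vertex.

    Uses one bounded all-pairs reachability computation; pointwise identical
    to calling :func:`khop_neighborhood` per vertex.
    """
    reach = hop_reachability(graph.adjacency, [r])[r].tocsr()
    u, v = graph.edge_indices()
    edge_ids = [frozenset((graph.cell_ids[a], graph.cell_ids[b])) for a, b in zip(u, v)]
    out = {}
    for i, cid in enumerate(graph.cell_ids):
        row = reach.indices[reach.indptr[i]: reach.indptr[i + 1]]
        member_mask = np.zeros(graph.n_vertices, dtype=bool)
        member_mask[row] = True
        keep = member_mask[u] & member_mask[v]
        out[cid] = Neighborhood(
            center=cid,
            radius=int(r),
            members={graph.cell_ids[j] for j in row},
            induced_edges={edge_ids[e] for e in np.flatnonzero(keep)},
        )
    return out
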