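"""Graph-based heterogeneity scores for spatial cell graphs.

Two sample-level scores and three cell-level scores quantify how mixed the
cell types in a tissue sample are:

* ``global_entropy``   -- normalized Shannon entropy of the cell-type
  fractions over the whole graph; 1 = perfectly balanced types, 0 = a single
  type.
* ``global_homophily`` -- fraction of edges joining two cells of the same
  type; 1 = fully segregated tissue.
* ``local_entropy``    -- the entropy score restricted to the r-hop
  neighborhood N_r(c) of each cell c.
* ``local_homophily``  -- monochromatic fraction of the edges induced by
  N_r(c); undefined (missing) when N_r(c) induces no edge.
* ``egophily``         -- fraction of cells in N_r(c) sharing c's own type;
  always positive since c is a member of its own neighborhood.

Entropies are normalized by log |T| where T is the cohort-wide type universe
(fixed before scoring), so values are comparable across samples.  The
logarithm base cancels in the normalization; natural log is used.  The
conventions 0*log(0) = 0 and H = 0 for |T| = 1 apply.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cells import validate_cell_table
from .graph import GraphConstructionError, SpatialGraph, build_delaunay_graph, hop_reachability
from .graph import UNKNOWN_LABEL

logger = logging.getLogger(__name__)

GLOBAL_SENTINEL = "global"
SCORE_COLUMNS = ["sample_id", "condition", "cell_id", "cell_type", "score", "radius", "value"]
DEFAULT_RADII = (1, 2, 3, 4, 5, 10, 20, 50, 100, 500)

LOCAL_SCORES = ("local_entropy", "local_homophily", "egophily")
GLOBAL_SCORES = ("global_entropy", "global_homophily")


def _entropy_from_counts(counts: np.ndarray, n_types: int) -> np.ndarray:
    """Normalized Shannon entropy per row of a counts matrix."""
    totals = counts.sum(axis=1, keepdims=True)
    if n_types <= 1:
        return np.zeros(counts.shape[0])
    p = counts / totals
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return -plogp.sum(axis=1) / np.log(n_types)


def global_entropy(graph: SpatialGraph) -> float:
    """H(G): normalized entropy of the cell-type fractions of the graph."""
    if graph.n_vertices == 0:
        raise ValueError("cannot score an empty graph")
    counts = np.bincount(graph.label_codes(), minlength=len(graph.type_universe))
    return float(_entropy_from_counts(counts[None, :].astype(float), len(graph.type_universe))[0])


def global_homophily(graph: SpatialGraph) -> float:
    """h(G): fraction of edges whose endpoints share a cell type."""
    u, v = graph.edge_indices()
    if len(u) == 0:
        raise ValueError("global homophily is undefined on an edgeless graph")
    codes = graph.label_codes()
    return float(np.mean(codes[u] == codes[v]))


def _local_score_arrays(graph: SpatialGraph, radii) -> dict:
    """All three local scores for every vertex at each radius.

    Returns {radius: dict(local_entropy=..., local_homophily=..., egophily=...)}
    with arrays aligned to ``graph.cell_ids``.  local_homophily is NaN where
    the neighborhood induces no edges.
    """
    codes = graph.label_codes()
    n, t = graph.n_vertices, len(graph.type_universe)
    onehot = sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, t), dtype=np.float64
    )
    u, v = graph.edge_indices()
    same = (codes[u] == codes[v]).astype(np.float64)
    ones = np.ones(len(u), dtype=np.float64)
    out = {}
    for r, reach in hop_reachability(graph.adjacency, radii).items():
        reach = reach.tocsr().astype(np.float64)
        sizes = np.asarray(reach.sum(axis=1)).ravel()
        counts = np.asarray((reach @ onehot).todense())
        ent = _entropy_from_counts(counts, t)
        ego = counts[np.arange(n), codes] / sizes
        if len(u):
            reach_csc = reach.tocsc()
            both = reach_csc[:, u].multiply(reach_csc[:, v]).tocsr()
            denom = np.asarray(both.sum(axis=1)).ravel()
            num = both @ same
            hom = np.divide(num, denom, out=np.full(n, np.nan), where=denom > 0)
        else:
            hom = np.full(n, np.nan)
        out[r] = {"local_entropy": ent, "local_homophily": hom, "egophily": ego}
    return out


def local_entropy(graph: SpatialGraph, r: int) -> dict:
    """H_r(c) for every cell c, as a cell_id -> value map."""
    arr = _local_score_arrays(graph, [r])[int(r)]["local_entropy"]
    return dict(zip(graph.cell_ids, arr))


def local_homophily(graph: SpatialGraph, r: int) -> dict:
    """h_r(c) per cell; NaN where N_r(c) induces no edge (missing, not error)."""
    arr = _local_score_arrays(graph, [r])[int(r)]["local_homophily"]
    return dict(zip(graph.cell_ids, arr))


def egophily(graph: SpatialGraph, r: int) -> dict:
    """e_r(c): fraction of N_r(c) sharing c's own type, per cell."""
    arr = _local_score_arrays(graph, [r])[int(r)]["egophily"]
    return dict(zip(graph.cell_ids, arr))


def cohort_type_universe(cells: pd.DataFrame) -> list:
    """Cell-type universe observed across a whole cohort (incl. 'unknown')."""
    labels = cells["cell_type"].fillna(UNKNOWN_LABEL).astype(str)
    return sorted(labels.unique())


def compute_all(
    cells: pd.DataFrame,
    radii=DEFAULT_RADII,
    type_universe: list | None = None,
    include_unknown: bool = True,
    timings: dict | None = None,
) -> pd.DataFrame:
    """Score every sample of a cohort at every requested radius.

    Produces a tidy score table with one row per (sample, global score) and
    one row per (cell, local score, radius).  The type universe defaults to
    all labels observed across the cohort and is recorded in
    ``result.attrs['type_universe']`` so downstream analyses can verify the
    normalization.  Samples that violate graph preconditions (fewer than 3
    cells, duplicate or collinear centroids) are skipped with a warning and
    listed in ``result.attrs['skipped_samples']``.

    Cells labeled "unknown" are labeled vertices and count toward the
    type fractions by default; ``include_unknown=False`` drops them from the
    cell table (and hence the graphs) before scoring.

    If *timings* is a dict, per-sample wall-clock seconds (graph construction
    plus all scores) are stored into it keyed by sample_id.
    """
    cells = validate_cell_table(cells)
    if cells["cell_type"].isna().any():
        raise ValueError("compute_all requires a cell_type for every cell (may be 'unknown')")
    if not include_unknown:
        dropped = int((cells["cell_type"].astype(str) == UNKNOWN_LABEL).sum())
        if dropped:
            logger.info("excluding %d 'unknown' cells before scoring", dropped)
        cells = cells[cells["cell_type"].astype(str) != UNKNOWN_LABEL]
    radii = sorted({int(r) for r in radii})
    if any(r < 1 for r in radii):
        raise ValueError("local score radii must be >= 1")
    universe = list(type_universe) if type_universe is not None else cohort_type_universe(cells)
    rows = []
    skipped = []
    for sample_id, sub in cells.groupby("sample_id", sort=True):
        sub = sub.sort_values("cell_id", kind="stable")
        condition = sub["condition"].iloc[0]
        tic = time.perf_counter()
        try:
            graph = build_delaunay_graph(sub, type_universe=universe)
        except GraphConstructionError as exc:
            logger.warning("skipping sample %s: %s", sample_id, exc)
            skipped.append((sample_id, str(exc)))
            continue
        ge, gh = global_entropy(graph), global_homophily(graph)
        local = _local_score_arrays(graph, radii)
        if timings is not None:
            timings[sample_id] = time.perf_counter() - tic
        for name, value in (("global_entropy", ge), ("global_homophily", gh)):
            rows.append((sample_id, condition, np.nan, np.nan, name, GLOBAL_SENTINEL, value))
        n = graph.n_vertices
        for r in radii:
            for name in LOCAL_SCORES:
                vals = local[r][name]
                rows.extend(
                    zip(
                        [sample_id] * n,
                        [condition] * n,
                        graph.cell_ids,
                        graph.labels,
                        [name] * n,
                        [r] * n,
                        vals,
                    )
                )
    if not rows and skipped:
        raise GraphConstructionError(f"all samples failed graph construction: {skipped}")
    table = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    table = table.sort_values(
        ["sample_id", "score", "radius", "cell_id"], kind="stable"
    ).reset_index(drop=True)
    table.attrs["type_universe"] = universe
    table.attrs["skipped_samples"] = skipped
    n_missing = int(table["value"].isna().sum())
    if n_missing:
        logger.info("%d local homophily values are missing (empty induced edge sets)", n_missing)
    return table


def write_score_table(table: pd.DataFrame, path) -> None:
    table[SCORE_COLUMNS].to_csv(path, index=False)


def read_score_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table {path} is missing columns: {missing}")
    return table
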