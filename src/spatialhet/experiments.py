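"""Validation experiments: oracle comparisons, recovery and calibration runs.

These drivers re-derive the package's headline properties from scratch on
synthetic cohorts: agreement of the vectorized scores with a naive per-cell
reference, detection of planted type-mixing differences with a calibrated
null, robustness of pooled tests to label permutation and subsampling,
cell-type recovery through the imaging pipeline, and quasi-linear runtime
scaling.  They are used by the test suite and by ``scripts/acceptance.py``.

Statistical design note: local scores of cells within one sample are
correlated (overlapping r-hop neighborhoods), so pooling cells across samples
pseudo-replicates and the pooled MWU's theoretical null is anti-conservative.
Calibration experiments therefore use the per-sample-median aggregation of
:func:`spatialhet.stats.test_scores`; the pooled variant is validated against
its own sample-level permutation reference instead (see
:func:`robustness_experiment`).
"""

from __future__ import annotations

import math
import time
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .graph import SpatialGraph, build_delaunay_graph
from .scores import compute_all, _local_score_arrays
from .simulate import TissueSimConfig, simulate_channels, simulate_reference, simulate_tissue
from .stats import bonferroni_cutoff, mwu_two_sided, permutation_test, subsampling_test
from .quantify import abundance_matrix, adaptive_binarize
from .celltypes import assign_cell_types


# ---------------------------------------------------------------------------
# naive per-cell reference scores (independent of the vectorized path)

def naive_scores(graph: SpatialGraph, r: int) -> dict:
    """Per-cell local scores by explicit BFS and Python counting.

    Deliberately naive: one breadth-first search per cell, dictionaries and
    loops, no shared reachability structures.  Serves as the oracle for the
    vectorized implementation.
    """
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_vertices))
    u, v = graph.edge_indices()
    g.add_edges_from(zip(u.tolist(), v.tolist()))
    codes = graph.label_codes()
    n_types = len(graph.type_universe)
    ent, hom, ego = {}, {}, {}
    for i in range(graph.n_vertices):
        dist = nx.single_source_shortest_path_length(g, i, cutoff=r)
        members = set(dist)
        counts = {}
        for m in members:
            counts[codes[m]] = counts.get(codes[m], 0) + 1
        total = len(members)
        if n_types > 1:
            h = 0.0
            for c in counts.values():
                p = c / total
                h -= p * math.log(p)
            ent[i] = h / math.log(n_types)
        else:
            ent[i] = 0.0
        induced = [(a, b) for a, b in zip(u, v) if a in members and b in members]
        hom[i] = (
            sum(codes[a] == codes[b] for a, b in induced) / len(induced) if induced else np.nan
        )
        ego[i] = counts.get(codes[i], 0) / total
    return {"local_entropy": ent, "local_homophily": hom, "egophily": ego}


def naive_global_scores(graph: SpatialGraph) -> tuple[float, float]:
    codes = graph.label_codes()
    n_types = len(graph.type_universe)
    total = len(codes)
    h = 0.0
    if n_types > 1:
        for c in np.bincount(codes, minlength=n_types):
            if c:
                p = c / total
                h -= p * math.log(p)
        h /= math.log(n_types)
    u, v = graph.edge_indices()
    mono = sum(codes[a] == codes[b] for a, b in zip(u, v)) / len(u)
    return h, float(mono)


def random_labeled_graph(rng: np.random.Generator, max_vertices=60, max_types=5) -> SpatialGraph:
    """Random connected labeled graph for oracle comparisons."""
    n = int(rng.integers(5, max_vertices + 1))
    t = int(rng.integers(2, max_types + 1))
    g = nx.gnp_random_graph(n, p=min(1.0, 3.0 / n), seed=int(rng.integers(2**31)))
    # connect components so hop distances are finite
    comps = [sorted(c) for c in nx.connected_components(g)]
    for a, b in zip(comps, comps[1:]):
        g.add_edge(a[0], b[0])
    import scipy.sparse as sp

    adj = nx.to_scipy_sparse_array(g, nodelist=range(n), format="csr").astype(bool)
    universe = [f"t{k}" for k in range(t)]
    labels = np.array(universe, dtype=object)[rng.integers(0, t, size=n)]
    return SpatialGraph(
        cell_ids=np.arange(n), adjacency=sp.csr_matrix(adj), labels=labels, type_universe=universe
    )


def score_oracle_deviation(n_graphs: int = 100, seed: int = 0) -> float:
    """Max |vectorized - naive| over random labeled graphs and radii 1..3."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        graph = random_labeled_graph(rng)
        radii = [1, 2, 3]
        fast = _local_score_arrays(graph, radii)
        for r in radii:
            ref = naive_scores(graph, r)
            for name in ("local_entropy", "local_homophily", "egophily"):
                a = fast[r][name]
                b = np.array([ref[name][i] for i in range(graph.n_vertices)], dtype=float)
                mask = ~(np.isnan(a) & np.isnan(b))
                if (np.isnan(a) != np.isnan(b)).any():
                    return np.inf
                diff = np.abs(a[mask] - b[mask])
                if diff.size:
                    worst = max(worst, float(diff.max()))
    return worst


# ---------------------------------------------------------------------------
# planted-effect detection and null calibration

#: Study conditions for the detection/calibration experiment: a two-condition
#: cohort (lesion-bearing vs control), 12 samples of 500 cells each.  The
#: local-score family for this analysis is 1 condition pair x 5 cell types x
#: 1 radius.
DETECTION_COHORT = dict(
    conditions=("CTCL", "AD"),
    samples_per_condition=12,
    cells_per_sample=500,
    beta=3.0,
)
DETECTION_RADIUS = 5
DETECTION_FAMILY = (1, 5, 1)  # condition pairs, cell types, radii


def _median_focal_p(cells: pd.DataFrame, score_name: str, focal: str, radius: int) -> float:
    scores = compute_all(cells, radii=[radius])
    sub = scores[
        (scores["radius"].astype(str) == str(radius))
        & (scores["cell_type"] == focal)
        & (scores["score"] == score_name)
    ]
    conds = sorted(sub["condition"].unique())
    med = sub.groupby(["condition", "sample_id"])["value"].median()
    return mwu_two_sided(med[conds[0]].to_numpy(), med[conds[1]].to_numpy())[1]


def planted_mixing_experiment(n_seeds: int = 100, seed: int = 0, effect: bool = True) -> pd.DataFrame:
    """Detection (or null calibration) of planted focal-type mixing.

    For each of *n_seeds* cohorts, compares focal-type local entropy and
    egophily at r=5 between the two conditions using per-sample medians.
    With ``effect=True`` the first condition carries focal lesions; with
    ``effect=False`` both conditions come from the identical lesion-free
    generator (exchangeable null).  Returns one row per (seed, score) with
    the raw p value.
    """
    base = np.random.SeedSequence(seed).generate_state(n_seeds, dtype=np.uint32) % (2**31)
    lesions = {"CTCL": 3, "AD": 0} if effect else {"CTCL": 0, "AD": 0}
    rows = []
    for s in base:
        cfg = TissueSimConfig(seed=int(s), lesion_count=lesions, **DETECTION_COHORT)
        cells = simulate_tissue(cfg)
        scores = compute_all(cells, radii=[DETECTION_RADIUS])
        sub = scores[
            (scores["radius"].astype(str) == str(DETECTION_RADIUS))
            & (scores["cell_type"] == cfg.focal_type)
        ]
        med = sub.groupby(["score", "condition", "sample_id"])["value"].median()
        for score_name in ("local_entropy", "egophily"):
            m = med[score_name]
            conds = sorted(m.index.get_level_values(0).unique())
            p = mwu_two_sided(m[conds[0]].to_numpy(), m[conds[1]].to_numpy())[1]
            rows.append({"seed": int(s), "score": score_name, "p": p})
    return pd.DataFrame(rows)


def detection_cutoff(alpha: float = 0.05) -> float:
    return bonferroni_cutoff(alpha, *DETECTION_FAMILY)


# ---------------------------------------------------------------------------
# permutation / subsampling robustness on one planted cohort

ROBUSTNESS_COHORT = dict(
    conditions=("CTCL", "AD", "PSO"),
    samples_per_condition=18,
    cells_per_sample=500,
    beta=3.0,
    lesion_count={"CTCL": 3, "AD": 0, "PSO": 0},
)
ROBUSTNESS_FAMILY = (3, 5, 1)


def robustness_experiment(seed: int = 0, iterations: int = 100, k: int = 15) -> dict:
    """Permutation and subsampling robustness of the pooled focal-type tests.

    Builds one three-condition planted-effect cohort, scores it at r=5 and
    runs the sample-level permutation test and the k-per-condition
    subsampling test on the focal strata (local entropy and egophily of the
    focal type, lesion condition vs each control).  Returns the fraction of
    permutation p values above the original p (1.0 = original smaller than
    all) and the fraction of subsampling p values below the local-family
    Bonferroni cutoff, minimized over the effect-condition strata.
    """
    cfg = TissueSimConfig(seed=seed, **ROBUSTNESS_COHORT)
    cells = simulate_tissue(cfg)
    scores = compute_all(cells, radii=[DETECTION_RADIUS])
    focal = cfg.focal_type
    kw = dict(
        radius=DETECTION_RADIUS,
        cell_types=[focal],
        score_names=("local_entropy", "egophily"),
        iterations=iterations,
        seed=seed,
    )
    perm = permutation_test(scores, **kw)
    subs = subsampling_test(scores, k=k, **kw)
    cutoff = bonferroni_cutoff(0.05, *ROBUSTNESS_FAMILY)
    lesioned = {c for c in cfg.conditions if cfg.lesions_of(c) > 0}

    def involves_effect(res):
        return bool(lesioned & set(res.conditions))

    perm_frac = min(
        float(np.mean(res.iteration_p > res.original_p)) for res in perm if involves_effect(res)
    )
    sub_frac = min(
        float(np.mean(res.iteration_p < cutoff)) for res in subs if involves_effect(res)
    )
    originals = {
        (res.score, res.conditions): res.original_p for res in perm if involves_effect(res)
    }
    return {
        "permutation_fraction_above_original": perm_frac,
        "subsampling_fraction_significant": sub_frac,
        "cutoff": cutoff,
        "original_p": originals,
    }


# ---------------------------------------------------------------------------
# end-to-end typing recovery through the imaging pipeline

def typing_recovery_experiment(seed: int = 0, cells_per_sample: int = 800) -> dict:
    """Clean-channel round trip: render -> binarize -> abundance -> typing.

    Returns the fraction of marker-bearing cells recovering their generating
    type and the fraction of planted markerless cells labeled 'unknown'.
    """
    cfg = TissueSimConfig(
        conditions=("CTCL",),
        samples_per_condition=1,
        cells_per_sample=cells_per_sample,
        markerless_fraction=0.05,
        background_rate=0.0,
        salt_pepper_rate=0.0,
        seed=seed,
    )
    cells = simulate_tissue(cfg)
    channels, _, detected, truth = simulate_channels(cells, cfg)
    binarized = {p: adaptive_binarize(img) for p, img in channels.items()}
    abundance = abundance_matrix(binarized, detected)
    reference = simulate_reference(cfg)
    labels, log = assign_cell_types(abundance, reference, seed=seed)
    true_labels = truth.set_index("segment").loc[abundance.index, "cell_type"]
    known = (true_labels != "unknown").to_numpy()
    recovery = float((labels[known].to_numpy() == true_labels[known].to_numpy()).mean())
    unknown_ok = float((labels[~known] == "unknown").mean()) if (~known).any() else 1.0
    return {
        "recovery": recovery,
        "markerless_unknown": unknown_ok,
        "iterations": len(log),
        "n_cells": int(len(abundance)),
    }


# ---------------------------------------------------------------------------
# runtime scaling

def scaling_experiment(seed: int = 0, sizes=(1000, 3000, 8000, 20000, 50000), reps: int = 3) -> dict:
    """Log-log slope of compute_all runtime vs cell count at r=5.

    Runtime is CPU (process) time, which measures the computation itself and
    is insensitive to other processes competing for the machine; each size is
    measured *reps* times and the minimum kept, the usual benchmarking guard
    against transient effects.
    """
    times = []
    for n in sizes:
        cfg = TissueSimConfig(
            conditions=("CTCL",), samples_per_condition=1, cells_per_sample=int(n), seed=seed
        )
        cells = simulate_tissue(cfg)
        best = np.inf
        for _ in range(reps):
            tic = time.process_time()
            compute_all(cells, radii=[DETECTION_RADIUS])
            best = min(best, time.process_time() - tic)
        times.append(best)
    slope = float(np.polyfit(np.log(sizes), np.log(times), 1)[0])
    return {"slope": slope, "sizes": list(sizes), "seconds": times}
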