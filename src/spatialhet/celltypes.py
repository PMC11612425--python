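"""Rule-based cell-type assignment from marker abundances and a reference.

Cell types are assigned iteratively against a single-cell RNA-seq reference
(cluster-level expression with cluster sizes and cluster -> cell-type
annotations, in the dialect of the Human Protein Atlas single-cell TSV
downloads):

1. Aggregate cluster-level expression X(C, g) to type level X(t, g) by a
   cluster-size weighted mean.
2. For every remaining type t and gene g compute the spread score
   s(t, g) = X(t, g) - max over other remaining types t' of X(t', g);
   a large spread marks g as a candidate marker gene for t.  Sort all
   (t, g) pairs by decreasing spread.
3. For every gene, fit a two-component Gaussian mixture to the abundances of
   the still-unassigned cells.  A gene is "good" (usably bimodal) iff
   mu0 + 1.96*sigma0 < mu1 - 1.96*sigma1, where component 0 has the lower
   mean.
4. Take the first pair (t*, g*) in the sorted list whose gene is good and
   assign t* to every unassigned cell with A(c, g*) > mu1(g*) - 1.96*sigma1(g*).
5. Remove t* from the remaining types and the assigned cells from the pool;
   repeat.  Stop when no cells or no types remain, when no gene is good, or
   when a single type remains (the spread score needs two types); surviving
   cells are labeled "unknown".

Every iteration is logged (type, gene, mixture fit, threshold, cells
assigned) so the resulting labels are fully auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .graph import UNKNOWN_LABEL

logger = logging.getLogger(__name__)

SEPARATION_MULTIPLIER = 1.96
SIGMA_COLLAPSE = 1e-6


class ReferenceError(ValueError):
    """Raised for malformed reference expression inputs."""


@dataclass
class ReferenceExpression:
    """Cluster-level reference expression plus its type-level aggregation."""

    clusters: pd.DataFrame  # columns: cluster, gene, expression
    annotations: pd.DataFrame  # columns: cluster, cell_type, size
    type_expression: pd.DataFrame = field(init=False)  # types x genes

    def __post_init__(self):
        self.type_expression = aggregate_reference(self.clusters, self.annotations)

    @property
    def types(self) -> list:
        return list(self.type_expression.index)

    @property
    def genes(self) -> list:
        return list(self.type_expression.columns)


# Column synonyms accepted in HPA-style TSV files.
_EXPR_COLS = {
    "cluster": ["cluster"],
    "gene": ["gene name", "gene"],
    "expression": ["ntpm", "ptpm", "read count", "expression"],
}
_DESC_COLS = {
    "cluster": ["cluster"],
    "cell_type": ["cell type", "cell_type"],
    "size": ["cell count", "cell_count", "size"],
}


def _pick_columns(df: pd.DataFrame, wanted: dict, path) -> pd.DataFrame:
    lower = {c.lower().strip(): c for c in df.columns}
    chosen = {}
    for target, candidates in wanted.items():
        for cand in candidates:
            if cand in lower:
                chosen[target] = lower[cand]
                break
        else:
            raise ReferenceError(f"{path}: no column matching {candidates} for {target!r}")
    out = df[[chosen[t] for t in wanted]].copy()
    out.columns = list(wanted)
    return out


def load_reference(expression_tsv, description_tsv, tissue: str | None = None) -> ReferenceExpression:
    """Load an HPA-dialect cluster expression table and its cluster annotations.

    *expression_tsv* holds cluster x gene expression (columns like
    Gene name / Cluster / nTPM); *description_tsv* holds Cluster / Cell type /
    Cell count.  If *tissue* is given and a Tissue column exists, rows are
    restricted to it.
    """
    expr = pd.read_csv(expression_tsv, sep="\t")
    desc = pd.read_csv(description_tsv, sep="\t")
    if tissue is not None:
        for df in (expr, desc):
            tissue_col = next((c for c in df.columns if c.lower().strip() == "tissue"), None)
            if tissue_col is not None:
                df.drop(df.index[df[tissue_col] != tissue], inplace=True)
    expr = _pick_columns(expr, _EXPR_COLS, expression_tsv)
    desc = _pick_columns(desc, _DESC_COLS, description_tsv)
    return ReferenceExpression(clusters=expr, annotations=desc)


def aggregate_reference(clusters: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Type-level expression X(t, g): cluster-size weighted mean of X(C, g)."""
    ann = annotations.set_index("cluster")
    if (ann["size"] <= 0).any():
        raise ReferenceError("cluster sizes must be positive")
    unknown = set(clusters["cluster"]) - set(ann.index)
    if unknown:
        raise ReferenceError(f"clusters without annotation: {sorted(unknown)[:5]}")
    merged = clusters.merge(
        ann[["cell_type", "size"]], left_on="cluster", right_index=True, how="left"
    )
    merged["weighted"] = merged["expression"] * merged["size"]
    grouped = merged.groupby(["cell_type", "gene"], sort=True).agg(
        weighted=("weighted", "sum"), size=("size", "sum")
    )
    if (grouped["size"] <= 0).any():
        raise ReferenceError("zero total cluster size for some (type, gene)")
    values = (grouped["weighted"] / grouped["size"]).unstack("gene")
    return values


def spread_scores(type_expression: pd.DataFrame, remaining: list) -> pd.DataFrame:
    """s(t, g) = X(t, g) - max_{t' != t, t' remaining} X(t', g).

    Recomputed each assignment iteration because the remaining-type set
    shrinks.  Requires at least two remaining types.
    """
    remaining = [t for t in remaining]
    if len(remaining) < 2:
        raise ValueError("spread scores need at least two remaining types")
    x = type_expression.loc[remaining]
    arr = x.to_numpy(dtype=float)
    order = np.sort(arr, axis=0)
    top, second = order[-1], order[-2]
    best_other = np.where(arr == top[None, :], second[None, :], top[None, :])
    # where a type ties the maximum, the "other" max equals the shared value
    ties = (arr == top[None, :]).sum(axis=0) > 1
    best_other[:, ties] = top[ties]
    return pd.DataFrame(arr - best_other, index=x.index, columns=x.columns)


def sorted_candidates(spreads: pd.DataFrame) -> list:
    """(type, gene) pairs by decreasing spread; ties broken lexicographically."""
    stacked = spreads.stack()
    frame = stacked.rename("s").reset_index()
    frame.columns = ["cell_type", "gene", "s"]
    frame = frame.sort_values(
        ["s", "cell_type", "gene"], ascending=[False, True, True], kind="stable"
    )
    return list(frame[["cell_type", "gene"]].itertuples(index=False, name=None))


@dataclass
class MixtureFit:
    mu0: float
    sigma0: float
    mu1: float
    sigma1: float
    good: bool

    @property
    def threshold(self) -> float:
        return self.mu1 - SEPARATION_MULTIPLIER * self.sigma1


def fit_bimodal(values: np.ndarray, seed: int = 0, n_init: int = 10) -> MixtureFit:
    """Fit a two-component 1-D Gaussian mixture and test usable bimodality.

    Components are ordered by mean; the gene is good iff
    mu0 + 1.96*sigma0 < mu1 - 1.96*sigma1.  Degenerate fits (a component
    standard deviation collapsing below 1e-6, or too few observations) are
    reported as not good.
    """
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(values) < 4 or np.ptp(values) == 0:
        return MixtureFit(float(values.mean()), 0.0, float(values.mean()), 0.0, False)
    gm = GaussianMixture(n_components=2, n_init=n_init, random_state=seed)
    gm.fit(values)
    means = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    mu0, mu1 = means[order]
    s0, s1 = sigmas[order]
    if min(s0, s1) < SIGMA_COLLAPSE:
        logger.debug("degenerate mixture fit (sigma collapse): mu=%s sigma=%s", means, sigmas)
        return MixtureFit(float(mu0), float(s0), float(mu1), float(s1), False)
    good = mu0 + SEPARATION_MULTIPLIER * s0 < mu1 - SEPARATION_MULTIPLIER * s1
    return MixtureFit(float(mu0), float(s0), float(mu1), float(s1), bool(good))


def check_separation(mu0, sigma0, mu1, sigma1, multiplier=SEPARATION_MULTIPLIER) -> bool:
    """The bimodality gate on explicit mixture parameters."""
    return mu0 + multiplier * sigma0 < mu1 - multiplier * sigma1


def match_genes(abundance: pd.DataFrame, genes, synonym_map: dict | None = None) -> dict:
    """Map abundance columns (protein names) to reference genes.

    Exact case-insensitive matching, optionally routed through a
    protein -> gene synonym map.  Unmatched proteins are dropped with a
    warning; an empty overlap is an error.
    """
    gene_by_lower = {str(g).lower(): g for g in genes}
    mapping = {}
    for protein in abundance.columns:
        name = protein
        if synonym_map:
            lowered = {str(k).lower(): v for k, v in synonym_map.items()}
            name = lowered.get(str(protein).lower(), protein)
        gene = gene_by_lower.get(str(name).lower())
        if gene is None:
            logger.warning("protein %r has no matching reference gene; dropped", protein)
        else:
            mapping[protein] = gene
    if not mapping:
        raise ReferenceError("no overlap between abundance proteins and reference genes")
    return mapping


def assign_cell_types(
    abundance: pd.DataFrame,
    reference: ReferenceExpression,
    synonym_map: dict | None = None,
    seed: int = 0,
    multiplier: float = SEPARATION_MULTIPLIER,
) -> tuple[pd.Series, list]:
    """Iterative marker-gated assignment of one cell type per iteration.

    Returns ``(labels, log)``: a cell_id -> type Series covering every input
    cell ("unknown" for survivors) and a per-iteration audit log of dicts
    with the chosen (type, gene), the mixture fit, the applied threshold and
    the number of cells assigned.  Deterministic given *seed*; cells are
    processed in canonical sorted order so input row order is irrelevant.
    """
    mapping = match_genes(abundance, reference.genes, synonym_map)
    data = abundance[list(mapping)].rename(columns=mapping)
    data = data.sort_index(kind="stable")
    x = reference.type_expression[list(data.columns)]

    unassigned = data.index.to_list()
    remaining = sorted(reference.types)
    labels = pd.Series(UNKNOWN_LABEL, index=abundance.index.copy(), dtype=object, name="cell_type")
    log = []
    iteration = 0
    while unassigned and remaining:
        if len(remaining) < 2:
            logger.info("single type %r left; spread undefined, stopping", remaining[0])
            break
        spreads = spread_scores(x, remaining)
        candidates = sorted_candidates(spreads)
        fits = {}

        def gene_fit(gene):
            if gene not in fits:
                fits[gene] = fit_bimodal(
                    data.loc[unassigned, gene].to_numpy(), seed=seed + iteration
                )
            return fits[gene]

        chosen = next(((t, g) for t, g in candidates if gene_fit(g).good), None)
        if chosen is None:
            logger.info("no good gene at iteration %d; stopping", iteration)
            break
        t_star, g_star = chosen
        fit = fits[g_star]
        threshold = fit.mu1 - multiplier * fit.sigma1
        values = data.loc[unassigned, g_star]
        hit = values.index[values.to_numpy() > threshold]
        labels.loc[hit] = t_star
        log.append(
            {
                "iteration": iteration,
                "cell_type": t_star,
                "gene": g_star,
                "spread": float(spreads.loc[t_star, g_star]),
                "mu0": fit.mu0,
                "sigma0": fit.sigma0,
                "mu1": fit.mu1,
                "sigma1": fit.sigma1,
                "threshold": float(threshold),
                "n_assigned": int(len(hit)),
            }
        )
        unassigned = [c for c in unassigned if c not in set(hit)]
        remaining = [t for t in remaining if t != t_star]
        iteration += 1
    return labels, log
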