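"""Differential analysis of heterogeneity score tables between conditions.

Every comparison uses the two-sided Mann-Whitney U test: exact null
distribution for small untied samples (n1*n2 <= 400 and no ties), the
tie-corrected normal approximation otherwise.  P values are Bonferroni
corrected within score families:

* global scores -- one sample-level test per condition pair; family size =
  number of condition pairs.
* local scores  -- cells pooled per (condition, cell type, radius) across
  samples; family size = condition pairs x cell types x radii.

Pooling cells across samples mirrors the original figure logic but ignores
patient/sample nesting (cells within a sample are spatially correlated, so
the pooled theoretical null is anti-conservative).  Two complements are
provided: ``aggregate='median'`` in :func:`test_scores` tests per-sample
medians instead (valid under sample exchangeability), and the
permutation/subsampling robustness tests shuffle or subsample at the sample
level, preserving within-sample correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scores import GLOBAL_SENTINEL, GLOBAL_SCORES, LOCAL_SCORES

logger = logging.getLogger(__name__)

EXACT_LIMIT = 400  # n1*n2 at or below which the exact MWU null is used


def bonferroni_cutoff(alpha: float, n_condition_pairs: int, n_cell_types: int, n_radii: int) -> float:
    """Local-family significance cutoff alpha / (pairs * cell types * radii)."""
    m = n_condition_pairs * n_cell_types * n_radii
    if m <= 0:
        raise ValueError("family size must be positive")
    return alpha / m


def mwu_two_sided(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Missing values (NaN) are dropped with a logged count; a group left with
    zero observations is an error.  The exact distribution is used for small
    untied inputs, the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_missing = int(np.isnan(x).sum() + np.isnan(y).sum())
    if n_missing:
        logger.debug("dropping %d missing values before MWU", n_missing)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("MWU requires at least one non-missing value per group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) * len(y) <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class TestResult:
    score: str
    radius: object  # int or "global"
    cell_type: str  # "sample" for global scores
    conditions: tuple
    p_raw: float
    p_adjusted: float
    family_size: int
    n_x: int
    n_y: int


def _global_values(scores: pd.DataFrame, score: str, condition) -> np.ndarray:
    sub = scores[
        (scores["score"] == score)
        & (scores["radius"].astype(str) == GLOBAL_SENTINEL)
        & (scores["condition"] == condition)
    ]
    return sub["value"].to_numpy(dtype=float)


def _local_values(
    scores: pd.DataFrame, score: str, radius, cell_type, condition, aggregate: str
) -> np.ndarray:
    sub = scores[
        (scores["score"] == score)
        & (scores["radius"].astype(str) == str(radius))
        & (scores["cell_type"] == cell_type)
        & (scores["condition"] == condition)
    ]
    vals = sub["value"]
    if aggregate == "pooled":
        return vals.to_numpy(dtype=float)
    if aggregate == "median":
        return sub.groupby("sample_id")["value"].median().to_numpy(dtype=float)
    raise ValueError(f"unknown aggregate mode {aggregate!r}")


def test_scores(
    scores: pd.DataFrame,
    alpha: float = 0.05,
    aggregate: str = "pooled",
) -> pd.DataFrame:
    """All between-condition MWU tests with family-wise Bonferroni correction.

    *aggregate* selects how local-score observations enter the test:
    ``'pooled'`` (default) pools cells across samples within a condition,
    as in the original cohort figures; ``'median'`` tests per-sample medians,
    which respects sample nesting and keeps the theoretical null calibrated.
    Strata in which one condition has no observations are skipped with a log
    entry.
    """
    conditions = sorted(scores["condition"].dropna().unique())
    if len(conditions) < 2:
        raise ValueError("need at least two conditions to test")
    pairs = list(combinations(conditions, 2))

    local = scores[scores["radius"].astype(str) != GLOBAL_SENTINEL]
    radii = sorted(local["radius"].astype(int).unique())
    cell_types = sorted(local["cell_type"].dropna().astype(str).unique())

    results: list[TestResult] = []
    m_global = len(pairs)
    for score in GLOBAL_SCORES:
        for a, b in pairs:
            x = _global_values(scores, score, a)
            y = _global_values(scores, score, b)
            if len(x) == 0 or len(y) == 0:
                logger.warning("skipping global %s for %s vs %s: empty group", score, a, b)
                continue
            _, p = mwu_two_sided(x, y)
            results.append(
                TestResult(score, GLOBAL_SENTINEL, "sample", (a, b),
                           p, min(1.0, m_global * p), m_global, len(x), len(y))
            )

    m_local = len(pairs) * len(cell_types) * len(radii)
    for score in LOCAL_SCORES:
        for r in radii:
            for ct in cell_types:
                for a, b in pairs:
                    x = _local_values(scores, score, r, ct, a, aggregate)
                    y = _local_values(scores, score, r, ct, b, aggregate)
                    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
                    if len(x) == 0 or len(y) == 0:
                        logger.info(
                            "skipping %s r=%s type=%s %s vs %s: empty group",
                            score, r, ct, a, b,
                        )
                        continue
                    _, p = mwu_two_sided(x, y)
                    results.append(
                        TestResult(score, r, ct, (a, b),
                                   p, min(1.0, m_local * p), m_local, len(x), len(y))
                    )
    frame = pd.DataFrame([vars(t) for t in results])
    frame.attrs["family_sizes"] = {"global": m_global, "local": m_local}
    return frame


def _sample_conditions(scores: pd.DataFrame) -> pd.Series:
    return scores.groupby("sample_id")["condition"].first()


@dataclass
class RobustnessResult:
    score: str
    radius: object
    cell_type: str
    conditions: tuple
    original_p: float
    iteration_p: np.ndarray
    mode: str
    seed: int


def _stratum_p(local: pd.DataFrame, sample_condition: pd.Series, a, b) -> float:
    cond = local["sample_id"].map(sample_condition)
    x = local.loc[cond == a, "value"].to_numpy(dtype=float)
    y = local.loc[cond == b, "value"].to_numpy(dtype=float)
    _, p = mwu_two_sided(x, y)
    return p


def _iter_strata(scores: pd.DataFrame, score_names, radius, cell_types):
    local = scores[
        (scores["radius"].astype(str) == str(radius))
        & (scores["cell_type"].astype(str).isin(cell_types))
    ]
    for score in score_names:
        for ct in cell_types:
            sub = local[(local["score"] == score) & (local["cell_type"] == ct)]
            sub = sub.dropna(subset=["value"])
            if len(sub):
                yield score, ct, sub


def permutation_test(
    scores: pd.DataFrame,
    radius: int = 5,
    cell_types=None,
    score_names=LOCAL_SCORES,
    iterations: int = 100,
    seed: int = 0,
) -> list[RobustnessResult]:
    """Sample-level label-permutation test of the pooled local-score MWU.

    Condition labels are shuffled across samples (group sizes preserved);
    each iteration recomputes the pooled MWU p per stratum.  The original,
    unpermuted p is carried alongside; no multiple-testing correction is
    applied to either (the comparison is between p values).
    """
    sample_condition = _sample_conditions(scores)
    conditions = sorted(sample_condition.unique())
    if len(sample_condition) < len(conditions):
        raise ValueError("fewer samples than conditions")
    if cell_types is None:
        cell_types = sorted(scores["cell_type"].dropna().astype(str).unique())
    rng = np.random.default_rng(seed)
    shuffles = [
        pd.Series(rng.permutation(sample_condition.to_numpy()), index=sample_condition.index)
        for _ in range(iterations)
    ]
    out = []
    for score, ct, sub in _iter_strata(scores, score_names, radius, cell_types):
        for a, b in combinations(conditions, 2):
            original = _stratum_p(sub, sample_condition, a, b)
            perm_p = np.array([_stratum_p(sub, s, a, b) for s in shuffles])
            out.append(
                RobustnessResult(score, radius, ct, (a, b), original, perm_p, "permutation", seed)
            )
    return out


def subsampling_test(
    scores: pd.DataFrame,
    radius: int = 5,
    cell_types=None,
    score_names=LOCAL_SCORES,
    k: int = 15,
    iterations: int = 100,
    seed: int = 0,
) -> list[RobustnessResult]:
    """Robustness of pooled local-score MWU p to cohort composition.

    Each iteration retains k samples per condition (drawn without
    replacement) and recomputes the pooled MWU p per stratum.  If a condition
    has fewer than k samples, k is lowered to the minimum group size with a
    warning.
    """
    sample_condition = _sample_conditions(scores)
    conditions = sorted(sample_condition.unique())
    group_sizes = sample_condition.value_counts()
    k_eff = int(min(k, group_sizes.min()))
    if k_eff < k:
        logger.warning("k lowered from %d to %d (smallest condition group)", k, k_eff)
    if cell_types is None:
        cell_types = sorted(scores["cell_type"].dropna().astype(str).unique())
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(iterations):
        kept = []
        for c in conditions:
            ids = sample_condition.index[sample_condition == c].to_numpy()
            kept.extend(rng.choice(ids, size=k_eff, replace=False))
        draws.append(set(kept))
    out = []
    for score, ct, sub in _iter_strata(scores, score_names, radius, cell_types):
        for a, b in combinations(conditions, 2):
            original = _stratum_p(sub, sample_condition, a, b)
            sub_p = np.array(
                [
                    _stratum_p(sub[sub["sample_id"].isin(kept)], sample_condition, a, b)
                    for kept in draws
                ]
            )
            out.append(
                RobustnessResult(score, radius, ct, (a, b), original, sub_p, "subsampling", seed)
            )
    return out


def robustness_frame(results: list[RobustnessResult]) -> pd.DataFrame:
    """Long-format (stratum x iteration -> p) table for CSV export."""
    rows = []
    for res in results:
        for i, p in enumerate(res.iteration_p):
            rows.append(
                (res.score, res.radius, res.cell_type, "|".join(map(str, res.conditions)),
                 res.mode, res.original_p, i, p)
            )
    return pd.DataFrame(
        rows,
        columns=["score", "radius", "cell_type", "conditions", "mode",
                 "original_p", "iteration", "p"],
    )
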