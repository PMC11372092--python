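"""Permutation gene-set overlap tests and PPI weighted-degree comparison.

The permutation test asks whether a target gene set (e.g. the 18 merged
damaging genes of the case group, drawn from a 60-gene cohort pool)
overlaps a reference gene list more than random subsets of the pool do:
the null distribution is the overlap of ``n_perm`` draws of k genes from
the pool, sampled without replacement.  Significance is reported both as
an add-one empirical p-value and as the null distribution's 95th
percentile cutoff, and p-values across reference lists are BH-adjusted.

The PPI score of a gene is its weighted degree: the sum of the
reliability scores of all interactions incident to it.  Groups of genes
are compared with a two-sided Wilcoxon rank-sum test on their scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "permutation_overlap_test",
    "bh_adjust",
    "ppi_weighted_degree",
    "compare_ppi",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    observed_overlap: int
    p_value: float
    cutoff_95: int
    null_overlaps: np.ndarray
    n_perm: int
    draw_size: int


def permutation_overlap_test(
    pool,
    target_set,
    reference_list,
    draw_size: int | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of gene-set overlap against a reference list.

    Draws ``n_perm`` subsets of ``draw_size`` genes (default: the size of
    the target set) from ``pool`` without replacement and counts their
    overlap with ``reference_list``.  The empirical p-value uses the
    add-one estimator ``(1 + #{null >= observed}) / (n_perm + 1)`` so it is
    never exactly zero; the 5% cutoff is the smallest null overlap count at
    or above the 95th percentile.
    """
    pool = list(dict.fromkeys(pool))
    target = set(target_set)
    reference = set(reference_list)
    if not target <= set(pool):
        raise ValueError("target set must be a subset of the pool")
    draw_size = len(target) if draw_size is None else draw_size
    if not 0 < draw_size <= len(pool):
        raise ValueError("draw size must lie in [1, |pool|]")
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    in_ref = np.array([g in reference for g in pool])
    observed = len(target & reference)
    # vectorised draws without replacement: argsort of uniform noise gives
    # a uniform random permutation per row; the first draw_size columns are
    # the drawn subset
    perm = np.argsort(rng.random((n_perm, len(pool))), axis=1)[:, :draw_size]
    null = in_ref[perm].sum(axis=1)
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    cutoff = int(np.quantile(null, 0.95, method="higher"))
    return PermutationResult(observed, float(p), cutoff, null, n_perm, draw_size)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def ppi_weighted_degree(edges: pd.DataFrame, genes=None) -> pd.Series:
    """Weighted degree (summed interaction reliability) per gene.

    ``edges`` holds one undirected interaction per row with columns
    ``gene_a``, ``gene_b`` and ``reliability`` in (0, 1].  Each edge adds
    its reliability to both endpoints; a self-loop counts once toward its
    gene and is logged.  When ``genes`` is given, the result is reindexed
    over it so isolated genes score 0.
    """
    rel = edges["reliability"].to_numpy(float)
    if ((rel <= 0) | (rel > 1)).any():
        raise ValueError("reliability scores must lie in (0, 1]")
    loops = edges["gene_a"] == edges["gene_b"]
    if loops.any():
        logger.info("%d self-loops counted once toward their gene", loops.sum())
    a_part = edges.groupby("gene_a")["reliability"].sum()
    b_part = edges.loc[~loops].groupby("gene_b")["reliability"].sum()
    score = a_part.add(b_part, fill_value=0.0)
    if genes is not None:
        score = score.reindex(list(genes), fill_value=0.0)
    score.index.name = "gene"
    return score.rename("weighted_degree")


def compare_ppi(scores_a, scores_b) -> dict:
    """Compare weighted-degree distributions of two gene groups.

    Reports group medians and the two-sided Wilcoxon rank-sum
    (Mann-Whitney U) p-value.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    if np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "statistic": float(stat),
        "p_value": float(min(p, 1.0)),
    }
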