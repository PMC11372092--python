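"""Damaging gene-set construction and case-control risk assessment.

Per-subject damaging gene sets come from two sources: validated damaging
brain somatic SNVs, and rare damaging germline SNVs in curated
autism-risk genes (SFARI class 1-3).  The union of both sources across a
diagnostic group is the group's merged gene set.  Subjects carrying at
least one gene under a chosen mode (somatic only, germline only, or
merged) populate a 2x2 carrier table; risk is assessed with a two-sided
Fisher exact test, reporting the conditional maximum-likelihood odds
ratio with its exact confidence interval (the estimator conventionally
paired with Fisher's exact test) alongside the sample cross-product odds
ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .filtering import classify_consequence

__all__ = [
    "GermlineFilter",
    "ContingencyResult",
    "select_damaging_germline",
    "select_damaging_somatic",
    "merge_genesets",
    "carrier_table",
    "fisher_risk",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GermlineFilter:
    """Thresholds for rare damaging germline SNVs in risk genes.

    ``allele_fraction_min`` is the within-sample alternate-read fraction
    (a heterozygous-call heuristic), not a population frequency;
    ``population_af_max`` is the ExAC-style population allele frequency
    ceiling; CADD must be strictly above ``cadd_min``.
    """

    depth_min: int = 100
    allele_fraction_min: float = 0.30
    population_af_max: float = 0.0002
    cadd_min: float = 20.0
    risk_classes: tuple = (1, 2, 3)


def select_damaging_germline(
    calls: pd.DataFrame,
    sfari: dict[str, int | str],
    cfg: GermlineFilter | None = None,
) -> dict[str, set[str]]:
    """Per-subject sets of risk genes with rare damaging germline SNVs.

    A (subject, gene) is selected iff depth >= 100, allele fraction >= 30%,
    population AF < 0.02% (missing treated as 0: a variant absent from the
    population database cannot be common), CADD > 20, the gene's curated
    risk class is 1-3, and the consequence is LOF_MIS.  ``calls`` needs
    columns ``subject, gene, depth, allele_fraction, cadd, exac_af,
    consequence``.
    """
    cfg = cfg or GermlineFilter()
    sets: dict[str, set[str]] = {}
    risk_classes = set(cfg.risk_classes)
    for row in calls.itertuples():
        sfari_class = sfari.get(row.gene, "other")
        if sfari_class not in risk_classes:
            if row.gene not in sfari:
                logger.debug("gene %s absent from risk-class table", row.gene)
            continue
        exac = 0.0 if pd.isna(row.exac_af) else float(row.exac_af)
        cadd = float("nan") if pd.isna(row.cadd) else float(row.cadd)
        if (
            row.depth >= cfg.depth_min
            and row.allele_fraction >= cfg.allele_fraction_min
            and exac < cfg.population_af_max
            and cadd > cfg.cadd_min
            and classify_consequence(row.consequence) == "LOF_MIS"
        ):
            sets.setdefault(row.subject, set()).add(row.gene)
    return sets


def select_damaging_somatic(calls: pd.DataFrame) -> dict[str, set[str]]:
    """Per-subject sets of genes with validated damaging somatic SNVs.

    ``calls`` needs boolean ``damaging`` and ``validated`` columns (see
    :func:`brainmosaic.filtering.annotate_calls` and
    :func:`brainmosaic.validation.validate_table`); a (subject, gene) is
    selected iff both are true.
    """
    sets: dict[str, set[str]] = {}
    hit = calls[calls["damaging"].astype(bool) & calls["validated"].astype(bool)]
    for subject, grp in hit.groupby("subject"):
        sets[subject] = set(grp["gene"])
    return sets


def merge_genesets(
    somatic_sets: dict[str, set[str]],
    germline_sets: dict[str, set[str]],
    subjects: list[str] | None = None,
) -> pd.DataFrame:
    """Union of distinct genes across subjects and both mutation sources.

    Restricting to ``subjects`` (e.g. one diagnostic group) when given.
    Returns one row per gene with its source annotation
    (``somatic``, ``germline`` or ``both``).
    """
    def _collect(sets: dict[str, set[str]]) -> set[str]:
        out: set[str] = set()
        for subj, genes in sets.items():
            if subjects is None or subj in subjects:
                out |= genes
        return out

    somatic = _collect(somatic_sets)
    germline = _collect(germline_sets)
    genes = sorted(somatic | germline)
    source = [
        "both" if g in somatic and g in germline
        else "somatic" if g in somatic else "germline"
        for g in genes
    ]
    return pd.DataFrame({"gene": genes, "source": source})


def carrier_table(
    somatic_sets: dict[str, set[str]],
    germline_sets: dict[str, set[str]],
    cohort: pd.DataFrame,
    mode: str = "merged",
) -> np.ndarray:
    """2x2 carrier counts (rows: case/control; columns: carrier/non-carrier).

    A subject is a carrier when it holds at least one gene under the mode:
    ``somatic_only`` / ``germline_only`` count one source, ``merged``
    counts either.  Cells sum to the cohort size.
    """
    if mode not in ("somatic_only", "germline_only", "merged"):
        raise ValueError(f"unknown mode {mode!r}")
    if cohort["diagnosis"].isna().any():
        missing = cohort.loc[cohort["diagnosis"].isna(), "subject"].tolist()
        raise ValueError(f"subjects without diagnosis: {missing}")
    table = np.zeros((2, 2), dtype=int)
    for row in cohort.itertuples():
        som = bool(somatic_sets.get(row.subject))
        germ = bool(germline_sets.get(row.subject))
        carrier = {
            "somatic_only": som,
            "germline_only": germ,
            "merged": som or germ,
        }[mode]
        i = 0 if row.diagnosis == "ASD" else 1
        table[i, 0 if carrier else 1] += 1
    return table


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float            # conditional MLE
    sample_odds_ratio: float     # cross-product ad/bc
    ci_low: float
    ci_high: float
    p_two_sided: float


def _cmle_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Conditional MLE of the odds ratio given all four table margins."""
    M, n, N = a + b + c + d, a + c, a + b
    lo, hi = max(0, N + n - M), min(n, N)
    if a <= lo:
        return 0.0
    if a >= hi:
        return float("inf")

    def mean_gap(log_psi: float) -> float:
        return stats.nchypergeom_fisher.mean(M, n, N, np.exp(log_psi)) - a

    return float(np.exp(optimize.brentq(mean_gap, -50.0, 50.0)))


def _exact_ci(a: int, b: int, c: int, d: int, alpha: float = 0.05):
    """Exact CI by inverting the noncentral hypergeometric tail probabilities."""
    M, n, N = a + b + c + d, a + c, a + b
    lo_sup, hi_sup = max(0, N + n - M), min(n, N)

    def upper_tail(log_psi: float) -> float:
        return stats.nchypergeom_fisher.sf(a - 1, M, n, N, np.exp(log_psi))

    def lower_tail(log_psi: float) -> float:
        return stats.nchypergeom_fisher.cdf(a, M, n, N, np.exp(log_psi))

    if a <= lo_sup:
        ci_low = 0.0
    else:
        ci_low = float(np.exp(optimize.brentq(
            lambda lp: upper_tail(lp) - alpha / 2, -50.0, 50.0)))
    if a >= hi_sup:
        ci_high = float("inf")
    else:
        ci_high = float(np.exp(optimize.brentq(
            lambda lp: lower_tail(lp) - alpha / 2, -50.0, 50.0)))
    return ci_low, ci_high


def fisher_risk(table) -> ContingencyResult:
    """Two-sided Fisher exact test with conditional-MLE OR and exact 95% CI.

    The two-sided p sums the point masses of all tables (with the observed
    margins) no more probable than the observed one.  A zero margin leaves
    the odds ratio undefined (NaN) with p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integer counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    tupled = ((a, b), (c, d))
    if min(a + b, c + d, a + c, b + d) == 0:
        return ContingencyResult(
            tupled, float("nan"), float("nan"), float("nan"), float("nan"), 1.0
        )
    sample_or = (a * d) / (b * c) if b * c > 0 else float("inf")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    ci_low, ci_high = _exact_ci(a, b, c, d)
    return ContingencyResult(
        tupled, _cmle_odds_ratio(a, b, c, d), sample_or, ci_low, ci_high, float(p)
    )
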