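"""Mutational burden summaries and group comparisons.

Burden is counted per subject-region pair (each sampled brain region of
each subject contributes one observation), matching a per-single-region
presentation of somatic SNV counts.  Exome-level per-region counts can be
linearly extrapolated to genome scale, and per-gene burden can be
normalized by transcript length for the LOF_MIS vs SYN comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "summarize_burden",
    "compare_groups",
    "extrapolate_genome",
    "length_normalized_burden",
]


def summarize_burden(calls: pd.DataFrame, cohort: pd.DataFrame) -> dict:
    """Per-subject-region SNV burden plus group means with standard errors.

    Every (subject, region) pair of the cohort gets a row, including zero
    rows for regions with no surviving calls.  Group means and standard
    errors are computed over subject-region rows.  ``calls`` may be empty
    but must not name a (subject, region) absent from the cohort.
    """
    pairs = cohort.explode("regions").rename(columns={"regions": "region"})[
        ["subject", "diagnosis", "region"]
    ]
    known = set(zip(pairs["subject"], pairs["region"]))
    if not calls.empty:
        seen = set(zip(calls["subject"], calls["tissue"]))
        unknown = seen - known
        if unknown:
            raise ValueError(f"calls in regions absent from cohort: {sorted(unknown)}")
        per = calls.groupby(["subject", "tissue"]).agg(
            snv_count=("vaf", "size"), mean_vaf=("vaf", "mean")
        )
        if "category" in calls.columns:
            cats = calls.pivot_table(
                index=["subject", "tissue"], columns="category",
                values="vaf", aggfunc="size", fill_value=0,
            )
            for cat in ("LOF_MIS", "SYN"):
                per[f"n_{cat}"] = cats.get(cat, 0)
        per = per.reset_index().rename(columns={"tissue": "region"})
    else:
        per = pd.DataFrame(columns=["subject", "region", "snv_count", "mean_vaf"])
    table = pairs.merge(per, on=["subject", "region"], how="left")
    count_cols = ["snv_count"] + [c for c in table.columns if c.startswith("n_")]
    for col in count_cols:
        table[col] = (
            pd.to_numeric(table[col], errors="coerce").fillna(0).astype(int)
        )
    group = table.groupby("diagnosis")["snv_count"].agg(
        mean="mean", sem=lambda x: x.sem() if len(x) > 1 else np.nan, n="size"
    )
    return {"table": table, "group_summary": group.reset_index()}


def compare_groups(values_a, values_b, test: str = "students_t") -> dict:
    """Two-sided comparison of two groups of burden values.

    ``test`` is ``"students_t"`` (equal-variance t test) or ``"wilcoxon"``
    (Wilcoxon rank-sum / Mann-Whitney U).  Two groups with zero variance
    and equal means compare as p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "students_t":
        if min(a.size, b.size) < 2:
            raise ValueError("t test needs n >= 2 per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return {"statistic": 0.0, "p_value": 1.0, "test": test}
            raise ValueError("degenerate t test: zero variance, unequal means")
        stat, p = stats.ttest_ind(a, b, equal_var=True)
    elif test == "wilcoxon":
        if min(a.size, b.size) < 1:
            raise ValueError("rank-sum test needs n >= 1 per group")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"statistic": float(stat), "p_value": float(min(p, 1.0)), "test": test}


def extrapolate_genome(
    count_per_exome_region: float,
    exome_bp: float = 75e6,
    genome_bp: float = 3e9,
) -> float:
    """Linearly extrapolate a per-exome count to genome scale.

    With the ~75 Mb exome and ~3 Gb genome defaults, 2.4 somatic SNVs per
    exome per region extrapolates to 96 per genome.
    """
    if exome_bp <= 0 or genome_bp <= 0:
        raise ValueError("genome and exome sizes must be positive")
    if count_per_exome_region < 0:
        raise ValueError("count must be non-negative")
    return count_per_exome_region * genome_bp / exome_bp


def length_normalized_burden(
    calls: pd.DataFrame, transcript_lengths: dict[str, float]
) -> dict:
    """Per-gene mutations per kilobase of transcript, by consequence category.

    ``calls`` needs ``gene`` and ``category`` columns (see
    :func:`brainmosaic.filtering.annotate_calls`).  Returns the per-gene
    rate table and a two-sided Wilcoxon rank-sum comparison of LOF_MIS vs
    SYN gene rates; the comparison is skipped with a warning when either
    category has no genes.
    """
    coding = calls[calls["category"].isin(["LOF_MIS", "SYN"])]
    missing = sorted(set(coding["gene"]) - set(transcript_lengths))
    if missing:
        raise ValueError(f"genes without transcript length: {missing}")
    counts = (
        coding.groupby(["gene", "category"]).size().rename("n").reset_index()
    )
    counts["transcript_bp"] = counts["gene"].map(transcript_lengths)
    counts["per_kb"] = counts["n"] * 1000.0 / counts["transcript_bp"]
    lof = counts.loc[counts["category"] == "LOF_MIS", "per_kb"].to_numpy()
    syn = counts.loc[counts["category"] == "SYN", "per_kb"].to_numpy()
    if lof.size == 0 or syn.size == 0:
        warnings.warn("a consequence category has no genes; comparison skipped")
        comparison = None
    else:
        comparison = compare_groups(lof, syn, test="wilcoxon")
    return {"per_gene": counts, "comparison": comparison}
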