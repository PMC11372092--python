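"""Post-call filtering of candidate somatic SNVs.

Raw candidate calls (from a single-region caller plus a replicate-aware
caller run on region pairs) pass through a cascade of filters before any
downstream analysis:

* paired subjects (matched peripheral tissue): drop candidates with
  VAF >= 20%, EB score <= 5, all supporting reads at read ends, unclean
  supporting reads, or a high second-best BLAT alignment score;
* unpaired subjects (brain tissue only): the same criteria plus the
  stricter depth >= 300 and VAF < 10% thresholds;
* multi-region pseudoreplicate rescue: a low-VAF candidate recurring in at
  least two distinct region pairs (i.e. three brain regions) of one
  subject, and absent from the peripheral tissue, is rescued;
* barcode-sequencing (BCDseq) concordance: a rescued candidate must show
  >4 supporting barcodes and WES/BCDseq VAF concordance (within a 10-fold
  change and a 5-percentage-point difference) in every contributing region.

Variant identity throughout is the exact tuple
(subject, chromosome, position, ref, alt); positions are 1-based.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LOF_MIS_TERMS",
    "FilterConfig",
    "filter_paired_calls",
    "filter_unpaired_calls",
    "find_replicate_calls",
    "filter_bcd_calls",
    "classify_consequence",
    "flag_damaging",
    "annotate_calls",
]

logger = logging.getLogger(__name__)

#: Consequence terms that define the LOF_MIS (loss-of-function or missense)
#: category; matching is case-insensitive on the term root.
LOF_MIS_TERMS = (
    "missense", "stop_gained", "start_lost",
    "stop_lost", "splice_donor", "splice_acceptor",
)

VARIANT_KEY = ["subject", "chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the post-call filter cascade.

    All exclusion rules are as strict as written: ``eb_min`` and
    ``cadd_damaging`` are exclusive bounds (a score exactly at the bound
    fails), ``vaf_max_*`` are exclusive upper bounds on surviving VAF, and
    ``bcd_min_barcodes`` is exclusive (>4 barcodes required).
    """

    vaf_max_paired: float = 0.20
    eb_min: float = 5.0
    blat_second_max: float = 900.0
    depth_min_unpaired: int = 300
    vaf_max_unpaired: float = 0.10
    bcd_min_barcodes: int = 4
    bcd_fold_max: float = 10.0
    bcd_absdiff_max: float = 0.05
    cadd_damaging: float = 20.0

    def __post_init__(self) -> None:
        if min(self.vaf_max_paired, self.vaf_max_unpaired) <= 0:
            raise ValueError("VAF ceilings must be positive")
        if self.bcd_fold_max <= 1:
            raise ValueError("fold-change ceiling must exceed 1")
        if self.depth_min_unpaired <= 0 or self.bcd_min_barcodes <= 0:
            raise ValueError("count thresholds must be positive")


def _check_required(calls: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in calls.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    for col in ("vaf", "eb_score"):
        if col in columns and calls[col].isna().any():
            bad = calls.index[calls[col].isna()].tolist()
            raise ValueError(f"calls with missing {col}: rows {bad}")


def _paired_criteria(calls: pd.DataFrame, cfg: FilterConfig) -> dict[str, pd.Series]:
    """Per-criterion pass masks shared by the paired and unpaired filters."""
    blat = calls.get("blat_second_avg", pd.Series(np.nan, index=calls.index))
    return {
        "vaf_below_20pct": calls["vaf"] < cfg.vaf_max_paired,
        "eb_score_above_5": calls["eb_score"] > cfg.eb_min,
        "not_end_read_only": ~calls["end_read_only"].astype(bool),
        "clean_support": calls["clean_support"].astype(bool),
        "blat_second_below_900": blat.isna() | (blat < cfg.blat_second_max),
    }


def _apply_criteria(
    calls: pd.DataFrame, criteria: dict[str, pd.Series]
) -> tuple[pd.DataFrame, dict[str, int]]:
    # Each rejected call is attributed to the first criterion it fails, in
    # the cascade's fixed order, so the rejection counts sum to in - out.
    rejected_by: dict[str, int] = {}
    alive = pd.Series(True, index=calls.index)
    for name, passed in criteria.items():
        newly_rejected = alive & ~passed
        rejected_by[name] = int(newly_rejected.sum())
        alive &= passed
    return calls[alive].copy(), rejected_by


def filter_paired_calls(
    calls: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter candidates from subjects with a matched peripheral sample.

    A call survives iff VAF < 20%, EB score > 5, not all supporting reads
    at read ends, clean supporting reads, and (when measured) a second-best
    BLAT score below 900.  Returns the surviving table and per-criterion
    rejection counts (first failing criterion wins).
    """
    cfg = cfg or FilterConfig()
    if calls.empty:
        names = (
            "vaf_below_20pct", "eb_score_above_5", "not_end_read_only",
            "clean_support", "blat_second_below_900",
        )
        return calls.copy(), {name: 0 for name in names}
    _check_required(calls, ["vaf", "eb_score", "end_read_only", "clean_support"])
    return _apply_criteria(calls, _paired_criteria(calls, cfg))


def filter_unpaired_calls(
    calls: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter candidates from brain-only subjects (no peripheral tissue).

    On top of every paired-case criterion, unpaired calls must satisfy the
    stricter depth >= 300 and VAF < 10% thresholds.
    """
    cfg = cfg or FilterConfig()
    if calls.empty:
        out, counts = filter_paired_calls(calls, cfg)
        counts.update({"depth_at_least_300": 0, "vaf_below_10pct": 0})
        return out, counts
    _check_required(
        calls, ["vaf", "eb_score", "end_read_only", "clean_support", "depth"]
    )
    criteria = {
        "depth_at_least_300": calls["depth"] >= cfg.depth_min_unpaired,
        "vaf_below_10pct": calls["vaf"] < cfg.vaf_max_unpaired,
    }
    criteria.update(_paired_criteria(calls, cfg))
    return _apply_criteria(calls, criteria)


def find_replicate_calls(
    calls: pd.DataFrame,
    peripheral_tissues: tuple[str, ...] = ("peripheral", "heart", "liver", "spleen"),
) -> pd.DataFrame:
    """Rescue low-VAF candidates recurring across brain regions.

    A variant (subject, chrom, pos, ref, alt) is rescued iff it was called
    in at least two distinct unordered region pairs — equivalently, in at
    least three distinct brain regions — of one subject, and never in that
    subject's peripheral tissue.  Returns one row per rescued variant with
    its supporting brain regions and region-pair count.
    """
    if calls.empty:
        return pd.DataFrame(
            columns=VARIANT_KEY + ["regions", "n_regions", "n_region_pairs"]
        )
    peripheral = set(t.lower() for t in peripheral_tissues)
    is_periph = calls["tissue"].str.lower().isin(peripheral)
    rows = []
    for key, grp in calls.groupby(VARIANT_KEY, sort=False):
        tissues = set(grp["tissue"])
        brain = sorted(t for t in tissues if t.lower() not in peripheral)
        in_periph = bool(is_periph.loc[grp.index].any())
        if len(brain) >= 3 and not in_periph:
            n_pairs = len(list(itertools.combinations(brain, 2)))
            rows.append(dict(zip(VARIANT_KEY, key)) | {
                "regions": brain,
                "n_regions": len(brain),
                "n_region_pairs": n_pairs,
            })
        elif len(brain) < 3:
            logger.debug("variant %s in <3 brain regions; cannot rescue", key)
    return pd.DataFrame(
        rows, columns=VARIANT_KEY + ["regions", "n_regions", "n_region_pairs"]
    )


def filter_bcd_calls(
    bcd: pd.DataFrame, cfg: FilterConfig | None = None
) -> pd.DataFrame:
    """Apply barcode-sequencing concordance filters to rescued variants.

    ``bcd`` holds one row per (variant, region) with columns
    ``barcode_count``, ``wes_vaf`` and ``bcd_vaf`` plus the variant key.
    A variant passes iff in EVERY contributing region: barcode_count > 4,
    the WES/BCDseq VAF ratio is within 10-fold, and the absolute VAF
    difference is within 5 percentage points.  A zero VAF on one platform
    with a nonzero VAF on the other leaves the fold change undefined and
    fails concordance.
    """
    cfg = cfg or FilterConfig()
    if bcd.empty:
        return pd.DataFrame(columns=VARIANT_KEY + ["n_regions"])
    wes = bcd["wes_vaf"].to_numpy(float)
    bvaf = bcd["bcd_vaf"].to_numpy(float)
    hi = np.maximum(wes, bvaf)
    lo = np.minimum(wes, bvaf)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))
    ok = (
        (bcd["barcode_count"].to_numpy() > cfg.bcd_min_barcodes)
        & (fold <= cfg.bcd_fold_max)
        & (np.abs(wes - bvaf) <= cfg.bcd_absdiff_max)
    )
    n_undef = int(np.isinf(fold).sum())
    if n_undef:
        logger.info("%d region observations with undefined fold change", n_undef)
    per_region = bcd.assign(_ok=ok)
    agg = per_region.groupby(VARIANT_KEY, sort=False).agg(
        n_regions=("_ok", "size"), all_ok=("_ok", "all")
    )
    passed = agg[(agg["all_ok"]) & (agg["n_regions"] >= 2)]
    return passed.reset_index()[VARIANT_KEY + ["n_regions"]]


def classify_consequence(consequence: str) -> str:
    """Classify a (possibly multi-term) consequence string.

    Returns ``"LOF_MIS"`` if any term is missense, stop gained, start lost,
    stop lost, splice donor or splice acceptor; else ``"SYN"`` for
    synonymous; else ``"OTHER"``.  Case-insensitive; terms may be separated
    by commas or ampersands.
    """
    if not consequence or not consequence.strip():
        raise ValueError("empty consequence string")
    terms = [
        t.strip().lower()
        for t in consequence.replace("&", ",").split(",")
        if t.strip()
    ]
    for term in terms:
        if any(term.startswith(root) for root in LOF_MIS_TERMS):
            return "LOF_MIS"
    if any(t.startswith("synonymous") for t in terms):
        return "SYN"
    return "OTHER"


def flag_damaging(
    consequence: str, cadd: float | None, cfg: FilterConfig | None = None
) -> bool:
    """True iff the call is LOF_MIS with a CADD score strictly above 20."""
    cfg = cfg or FilterConfig()
    if classify_consequence(consequence) != "LOF_MIS":
        return False
    if cadd is None or (isinstance(cadd, float) and np.isnan(cadd)):
        warnings.warn("LOF_MIS call without CADD score treated as non-damaging")
        return False
    return float(cadd) > cfg.cadd_damaging


def annotate_calls(
    calls: pd.DataFrame, cfg: FilterConfig | None = None
) -> pd.DataFrame:
    """Add ``category`` and ``damaging`` columns to a call table."""
    cfg = cfg or FilterConfig()
    out = calls.copy()
    out["category"] = out["consequence"].map(classify_consequence)
    cadd = out.get("cadd", pd.Series(np.nan, index=out.index))
    out["damaging"] = (out["category"] == "LOF_MIS") & (
        cadd.fillna(-np.inf) > cfg.cadd_damaging
    )
    return out
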