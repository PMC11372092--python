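"""Amplicon-based validation of candidate somatic SNVs.

Ultradeep targeted amplicon sequencing (TASeq) re-sequences each candidate
site to very high depth.  A candidate is accepted as a true mutation when
its alternate-allele count is larger than platform background error alone
would plausibly produce: a one-sided exact binomial test of the observed
alt count against the substitution-class-specific background error rate.

Background error rates are strand-collapsed to the six canonical
pyrimidine-context substitution classes (T>A, T>C, T>G, C>T, C>G, C>A);
an observation reported on the purine strand (e.g. G>A) is mapped to its
pyrimidine complement (C>T) before lookup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SUBSTITUTION_CLASSES",
    "DEFAULT_ERROR_RATES",
    "ErrorModel",
    "ValidationResult",
    "collapse_substitution",
    "validate_call",
    "validate_table",
    "compute_precision",
    "vaf_concordance",
]

SUBSTITUTION_CLASSES = ("T>A", "T>C", "T>G", "C>T", "C>G", "C>A")

#: Background alternate-allele fractions of the amplicon platform, measured
#: from replicate sequencing of spike-in control samples, per substitution
#: class.
DEFAULT_ERROR_RATES = {
    "T>A": 0.00312,
    "T>C": 0.00797,
    "T>G": 0.000758,
    "C>T": 0.00407,
    "C>G": 0.000765,
    "C>A": 0.00185,
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def collapse_substitution(sub: str) -> str:
    """Map a substitution such as ``"G>A"`` to its pyrimidine-context class.

    Substitutions whose reference base is a purine are complemented on both
    alleles so that every SNV falls into one of the six canonical classes.
    """
    sub = sub.strip().replace(" ", "").upper()
    try:
        ref, alt = sub.split(">")
    except ValueError:
        raise ValueError(f"malformed substitution {sub!r}; expected 'R>A'")
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise ValueError(f"unknown substitution {sub!r}")
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class ErrorModel:
    """Per-substitution-class background error rates of a platform."""

    rate_by_substitution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_RATES)
    )

    def __post_init__(self) -> None:
        missing = set(SUBSTITUTION_CLASSES) - set(self.rate_by_substitution)
        if missing:
            raise ValueError(f"error model missing classes: {sorted(missing)}")
        for cls, rate in self.rate_by_substitution.items():
            if not 0.0 < rate < 1.0:
                raise ValueError(f"rate for {cls} must lie in (0, 1), got {rate}")

    def rate(self, substitution: str) -> float:
        cls = collapse_substitution(substitution)
        return self.rate_by_substitution[cls]


@dataclass(frozen=True)
class ValidationResult:
    variant_key: str
    p_value: float
    validated: bool
    observed_vaf: float
    background_rate: float


def validate_call(
    depth: int,
    alt_count: int,
    substitution: str,
    error_model: ErrorModel | None = None,
    alpha: float = 0.05,
    variant_key: str = "",
) -> ValidationResult:
    """Test one amplicon observation against the platform background.

    The p-value is the one-sided upper binomial tail
    ``P(X >= alt_count | depth, background rate)``; the call is validated
    when ``p < alpha``.  Zero depth yields ``p = 1`` with a warning.
    """
    error_model = error_model or ErrorModel()
    rate = error_model.rate(substitution)
    if depth < 0 or alt_count < 0 or alt_count > depth:
        raise ValueError(f"invalid counts: depth={depth}, alt_count={alt_count}")
    if depth == 0:
        warnings.warn(f"zero depth for {variant_key or substitution}; not validated")
        return ValidationResult(variant_key, 1.0, False, float("nan"), rate)
    # sf(k-1) = P(X >= k); alt_count == 0 gives exactly 1.
    p = float(stats.binom.sf(alt_count - 1, depth, rate))
    return ValidationResult(
        variant_key, p, p < alpha, alt_count / depth, rate
    )


def validate_table(
    observations: pd.DataFrame,
    error_model: ErrorModel | None = None,
    alpha: float = 0.05,
    combine_replicates: bool = True,
) -> pd.DataFrame:
    """Validate a table of amplicon observations.

    ``observations`` needs columns ``variant_key``, ``substitution``,
    ``depth`` and ``alt_count``.  Replicate observations of one candidate
    are pooled by summing depths and alt counts before testing.
    """
    required = {"variant_key", "substitution", "depth", "alt_count"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    obs = observations.copy()
    obs["substitution"] = obs["substitution"].map(collapse_substitution)
    if combine_replicates:
        obs = (
            obs.groupby(["variant_key", "substitution"], as_index=False)[
                ["depth", "alt_count"]
            ].sum()
        )
    rows = [
        validate_call(
            int(r.depth), int(r.alt_count), r.substitution,
            error_model, alpha, variant_key=str(r.variant_key),
        )
        for r in obs.itertuples()
    ]
    return pd.DataFrame(
        {
            "variant_key": [r.variant_key for r in rows],
            "substitution": obs["substitution"].to_numpy(),
            "depth": obs["depth"].to_numpy(),
            "alt_count": obs["alt_count"].to_numpy(),
            "observed_vaf": [r.observed_vaf for r in rows],
            "background_rate": [r.background_rate for r in rows],
            "p_value": [r.p_value for r in rows],
            "validated": [r.validated for r in rows],
        }
    )


def compute_precision(validated: "pd.Series | np.ndarray | list") -> dict:
    """Fraction of candidates that validated, with Clopper-Pearson 95% CI."""
    flags = np.asarray(validated, dtype=bool)
    if flags.size == 0:
        raise ValueError("cannot compute precision of an empty result table")
    k, n = int(flags.sum()), int(flags.size)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return {
        "n_validated": k,
        "n_total": n,
        "precision": k / n,
        "ci_low": float(lo),
        "ci_high": float(hi),
    }


def vaf_concordance(vaf_a, vaf_b) -> dict:
    """Cross-platform VAF concordance.

    Returns the Pearson correlation of the two VAF vectors together with a
    per-pair table of fold changes and absolute differences.  Zero-variance
    input leaves the correlation undefined (NaN) with a warning.
    """
    a = np.asarray(vaf_a, dtype=float)
    b = np.asarray(vaf_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("VAF vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.maximum(a, b) / np.minimum(a, b)
    pairs = pd.DataFrame(
        {"vaf_a": a, "vaf_b": b, "fold_change": fold, "abs_diff": np.abs(a - b)}
    )
    if np.isclose(a.std(), 0.0) or np.isclose(b.std(), 0.0):
        warnings.warn("zero-variance VAF vector; correlation undefined")
        return {"pearson_r": float("nan"), "p_value": float("nan"), "pairs": pairs}
    r, p = stats.pearsonr(a, b)
    return {"pearson_r": float(r), "p_value": float(p), "pairs": pairs}
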