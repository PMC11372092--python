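"""Spatiotemporal expression signatures and window enrichment.

A developmental expression atlas gives, for each gene i, an RPKM value
e_i^sr at every combination of developmental stage s and brain region r
(10 stages x 15 regions = 150 windows by default).  Specificity of a gene
for a window is measured with two robust z-scores:

    z_i^s = (e_i^sr - m_i^s) / (1.4826 * MAD_i^s)    across regions at s
    z_i^r = (e_i^sr - m_i^r) / (1.4826 * MAD_i^r)    across stages at r

where m is the median and MAD the median absolute deviation (1.4826*MAD
is a robust standard-deviation estimate under normality).  The two scores
combine into a meta-z, z_i^sr = (z_i^s + z_i^r) / sqrt(2), and the genes
with meta-z >= 1.5 form the window's expression signature.  A gene set is
tested for enrichment in each window with a one-sided Fisher exact test
over the tensor's gene universe, with Benjamini-Hochberg correction
across the windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["SignatureModel", "robust_z", "build_signatures", "enrich_windows"]

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826
META_Z_THRESHOLD = 1.5


def robust_z(e: float, center: float, mad: float) -> float:
    """Robust z-score (e - center) / (1.4826 * MAD); NaN when MAD is 0."""
    if mad < 0:
        raise ValueError("MAD must be non-negative")
    if mad == 0:
        return float("nan")
    return (e - center) / (MAD_SCALE * mad)


@dataclass(frozen=True)
class SignatureModel:
    """Robust z-scores and signature membership over a stage x region grid.

    ``z_stage``, ``z_region`` and ``meta_z`` are (gene, stage, region)
    arrays; entries are NaN where the corresponding MAD is zero.  A gene
    belongs to the signature of window (s, r) iff both components are
    defined and the meta-z is at least the threshold.
    """

    genes: tuple[str, ...]
    stages: tuple[str, ...]
    regions: tuple[str, ...]
    z_stage: np.ndarray
    z_region: np.ndarray
    meta_z: np.ndarray
    threshold: float = META_Z_THRESHOLD

    @property
    def n_windows(self) -> int:
        return len(self.stages) * len(self.regions)

    def signature(self, stage: str, region: str) -> set[str]:
        s = self.stages.index(stage)
        r = self.regions.index(region)
        col = self.meta_z[:, s, r]
        member = ~np.isnan(col) & (col >= self.threshold)
        return {self.genes[i] for i in np.nonzero(member)[0]}

    def signatures(self) -> dict[tuple[str, str], set[str]]:
        return {
            (s, r): self.signature(s, r)
            for s in self.stages for r in self.regions
        }


def _to_tensor(expression: pd.DataFrame):
    required = {"gene", "stage", "region", "rpkm"}
    missing = required - set(expression.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    genes = tuple(pd.unique(expression["gene"]))
    stages = tuple(pd.unique(expression["stage"]))
    regions = tuple(pd.unique(expression["region"]))
    wide = expression.pivot_table(
        index="gene", columns=["stage", "region"], values="rpkm", aggfunc="first"
    ).reindex(index=genes)
    cols = pd.MultiIndex.from_product([stages, regions])
    wide = wide.reindex(columns=cols)
    if wide.isna().any().any():
        holes = [
            (g, s, r)
            for (s, r) in wide.columns[wide.isna().any()]
            for g in wide.index[wide[(s, r)].isna()]
        ]
        raise ValueError(
            f"incomplete expression grid; {len(holes)} missing cells, "
            f"first few: {holes[:10]}"
        )
    values = wide[cols].to_numpy(float).reshape(len(genes), len(stages), len(regions))
    return genes, stages, regions, values


def build_signatures(expression: pd.DataFrame) -> SignatureModel:
    """Build the stage x region signature model from a long-format tensor.

    ``expression`` holds one row per (gene, stage, region) with an ``rpkm``
    column; the grid must be complete.  For each gene and cell, the
    stage-wise z compares the cell to the gene's distribution across all
    regions at that stage, the region-wise z across all stages at that
    region; the meta-z is their sum over sqrt(2).  Cells whose MAD is zero
    yield undefined (NaN) components and are excluded from signatures.
    """
    genes, stages, regions, values = _to_tensor(expression)
    # stage-wise: distribution across regions (axis 2) at fixed stage
    m_s = np.median(values, axis=2, keepdims=True)
    mad_s = np.median(np.abs(values - m_s), axis=2, keepdims=True)
    # region-wise: distribution across stages (axis 1) at fixed region
    m_r = np.median(values, axis=1, keepdims=True)
    mad_r = np.median(np.abs(values - m_r), axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_s = np.where(mad_s > 0, (values - m_s) / (MAD_SCALE * mad_s), np.nan)
        z_r = np.where(mad_r > 0, (values - m_r) / (MAD_SCALE * mad_r), np.nan)
    meta = (z_s + z_r) / math.sqrt(2.0)
    return SignatureModel(genes, stages, regions, z_s, z_r, meta)


def enrich_windows(
    gene_set,
    model: SignatureModel,
    universe=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of a gene set in every window signature.

    One-sided (over-representation) Fisher exact p per window on the 2x2 of
    set membership x signature membership over the universe (all tensor
    genes by default), BH-adjusted across the windows.  Gene-set members
    absent from the universe are dropped with a logged count.  Returns a
    window table with overlap counts, p, q and a significance flag.
    """
    universe = set(model.genes) if universe is None else set(universe)
    gene_set = set(gene_set)
    dropped = len(gene_set - universe)
    if dropped:
        logger.info("%d gene-set members outside the universe dropped", dropped)
    gene_set &= universe
    rows = []
    for s in model.stages:
        for r in model.regions:
            sig = model.signature(s, r) & universe
            overlap = len(gene_set & sig)
            if not gene_set:
                p = 1.0
            else:
                # upper tail of the hypergeometric: P(X >= overlap)
                p = float(stats.hypergeom.sf(
                    overlap - 1, len(universe), len(sig), len(gene_set)
                ))
            rows.append({
                "stage": s, "region": r, "signature_size": len(sig),
                "overlap": overlap, "p_value": min(p, 1.0),
            })
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p_value"], method="fdr_bh")
    out["q_value"] = q
    out["significant"] = out["q_value"] < alpha
    return out
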