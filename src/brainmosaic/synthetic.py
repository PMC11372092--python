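"""Synthetic cohorts, call sets, amplicon counts, expression tensors and PPI graphs.

Every generator emulates one input of the somatic/germline analysis so the
whole pipeline can be exercised end-to-end without any external download:

* a postmortem cohort of ASD cases and neurotypical controls, each subject
  sampled in up to five brain regions, a subset with a matched peripheral
  tissue;
* per-region somatic variant call sets in which true mosaic mutations carry
  low variant allele fractions (VAFs), recur across brain regions when they
  arose early in development, and artifact candidates carry low
  empirical-Bayes (EB) scores or end-of-read support;
* ultradeep amplicon read counts on top of substitution-class-specific
  background error rates;
* a gene x region x stage expression tensor with planted stage- and
  region-specific elevation;
* an undirected protein-protein interaction (PPI) graph with reliability
  scores and planted high-degree genes;
* GMT-style reference gene lists with a planted overlap against a target set.

All generators are deterministic under their seed and keep truth labels so
recovery tests can score the pipeline against the planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .validation import SUBSTITUTION_CLASSES, ErrorModel, collapse_substitution

__all__ = [
    "BRAIN_REGIONS",
    "EXPRESSION_REGIONS",
    "EXPRESSION_STAGES",
    "CohortSpec",
    "MutationModel",
    "generate_cohort",
    "simulate_callsets",
    "simulate_amplicon",
    "simulate_expression",
    "simulate_ppi",
    "simulate_reference_genesets",
]

#: Brain regions sampled per subject (Brodmann areas and cerebellum).
BRAIN_REGIONS = ("BA9", "BA21", "BA22", "BA17", "CB")

PERIPHERAL_TISSUES = ("heart", "liver", "spleen")

#: 15 brain regions of the developmental expression atlas.
EXPRESSION_REGIONS = (
    "OFC", "DFC", "VFC", "MFC", "M1C", "S1C", "IPC", "A1C",
    "STC", "ITC", "V1C", "HIP", "AMY", "STR", "MD",
)

#: 10 developmental stages, early fetal through middle adulthood.
EXPRESSION_STAGES = (
    "early_fetal", "early_mid_fetal", "late_mid_fetal", "late_fetal",
    "infancy", "early_childhood", "late_childhood", "adolescence",
    "young_adulthood", "middle_adulthood",
)

_LOF_MIS_TERMS = (
    "missense_variant", "stop_gained", "start_lost",
    "stop_lost", "splice_donor_variant", "splice_acceptor_variant",
)


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a case-control postmortem cohort.

    ``paired_fraction_cases`` / ``paired_fraction_controls`` give the
    fraction of each group with a matched peripheral tissue; the default
    reproduces the study design of 24 cases (13 paired) and 31 controls
    (all paired).
    """

    n_cases: int = 24
    n_controls: int = 31
    regions_per_subject: tuple[str, ...] = BRAIN_REGIONS
    paired_fraction_cases: float = 13 / 24
    paired_fraction_controls: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("subject counts must be non-negative")
        for frac in (self.paired_fraction_cases, self.paired_fraction_controls):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("paired fractions must lie in [0, 1]")
        if len(self.regions_per_subject) == 0:
            raise ValueError("need at least one brain region")


@dataclass(frozen=True)
class MutationModel:
    """Generative model of true mosaic SNVs and artifact candidates.

    True VAFs follow a Beta(a, b) distribution rescaled to
    ``(vaf_min, vaf_max)``; the defaults give a mean VAF near 5.3% with a
    lower bound of 0.3%, the range of low-level brain mosaicism.  A fraction
    ``shared_region_fraction`` of true mutations arose early enough in
    development to be present in at least three brain regions of the
    subject.  ``artifact_rate`` is the expected number of false candidates
    per region; artifacts carry EB scores <= 5 and/or end-of-read support,
    the marks the post-call filter is designed to catch.
    """

    vaf_beta_a: float = 1.2
    vaf_beta_b: float = 3.53
    vaf_min: float = 0.003
    vaf_max: float = 0.2
    mutations_per_region_mean: float = 2.4
    shared_region_fraction: float = 0.2
    artifact_rate: float = 1.0
    damaging_fraction: float = 0.38
    mean_depth: float = 560.0

    def __post_init__(self) -> None:
        if self.mutations_per_region_mean < 0 or self.artifact_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.shared_region_fraction <= 1.0:
            raise ValueError("shared_region_fraction must lie in [0, 1]")
        if not 0.0 <= self.damaging_fraction <= 1.0:
            raise ValueError("damaging_fraction must lie in [0, 1]")
        if not 0.0 < self.vaf_min < self.vaf_max <= 1.0:
            raise ValueError("need 0 < vaf_min < vaf_max <= 1")

    def draw_true_vafs(self, rng: np.random.Generator, n: int) -> np.ndarray:
        raw = rng.beta(self.vaf_beta_a, self.vaf_beta_b, size=n)
        return self.vaf_min + (self.vaf_max - self.vaf_min) * raw

    @property
    def true_vaf_mean(self) -> float:
        m = self.vaf_beta_a / (self.vaf_beta_a + self.vaf_beta_b)
        return self.vaf_min + (self.vaf_max - self.vaf_min) * m


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the subject table of a synthetic cohort.

    Returns one row per subject with diagnosis, brain-region list, a
    paired-peripheral flag (with the peripheral tissue type) and sex.  The
    number of paired subjects per group is the rounded target fraction, so
    the cohort shape is exact rather than binomial.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, n, frac in (
        ("ASD", spec.n_cases, spec.paired_fraction_cases),
        ("control", spec.n_controls, spec.paired_fraction_controls),
    ):
        n_paired = int(round(frac * n))
        paired_idx = set(rng.choice(n, size=n_paired, replace=False)) if n else set()
        for i in range(n):
            paired = i in paired_idx
            rows.append(
                {
                    "subject": f"{group}_{i:03d}",
                    "diagnosis": group,
                    "regions": list(spec.regions_per_subject),
                    "paired": paired,
                    "peripheral_tissue": (
                        str(rng.choice(PERIPHERAL_TISSUES)) if paired else None
                    ),
                    "sex": "M" if rng.random() < 0.5 else "F",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "diagnosis", "regions", "paired",
                 "peripheral_tissue", "sex"],
    )


def _region_span(rng, model: MutationModel, n_regions: int) -> int:
    # Early ("shared") mutations span >=3 regions, late ones 1-2; a subject
    # with fewer than 3 regions cannot host a shared mutation.
    if rng.random() < model.shared_region_fraction and n_regions >= 3:
        return int(rng.integers(3, n_regions + 1))
    return int(rng.integers(1, min(2, n_regions) + 1))


def _expected_span(model: MutationModel, n_regions: int) -> float:
    if n_regions >= 3:
        shared = (3 + n_regions) / 2.0
        unshared = 1.5
        return (
            model.shared_region_fraction * shared
            + (1 - model.shared_region_fraction) * unshared
        )
    return (1 + min(2, n_regions)) / 2.0


def _draw_site(rng, used: set) -> tuple[str, int, str, str, str]:
    while True:
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(1, 50_000_000))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            break
    sub = SUBSTITUTION_CLASSES[int(rng.integers(len(SUBSTITUTION_CLASSES)))]
    ref, alt = sub.split(">")
    return chrom, pos, ref, alt, sub


def _consequence(rng, model: MutationModel) -> tuple[str, float]:
    # Roughly one third of exome SNVs land in annotated coding consequence
    # classes; among coding calls missense dominates over synonymous.
    u = rng.random()
    if u < 0.45:
        csq = "intron_variant" if rng.random() < 0.7 else "3_prime_UTR_variant"
        return csq, float(rng.uniform(0, 15))
    if u < 0.65:
        return "synonymous_variant", float(rng.uniform(0, 15))
    csq = str(rng.choice(_LOF_MIS_TERMS, p=[0.85, 0.05, 0.02, 0.02, 0.03, 0.03]))
    if rng.random() < model.damaging_fraction:
        cadd = float(rng.uniform(20.5, 45.0))
    else:
        cadd = float(rng.uniform(0.0, 19.5))
    return csq, cadd


def simulate_callsets(
    cohort: pd.DataFrame,
    model: MutationModel | None = None,
    error_model: ErrorModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-region somatic variant call sets for a cohort.

    Each true mutation has one subject-level ("cellular") VAF drawn from the
    model's Beta distribution and appears in each of its regions with a
    binomially resampled observed VAF at the region's sequencing depth.
    The number of mutation events per subject is Poisson with a rate chosen
    so that the expected number of true calls per region equals
    ``mutations_per_region_mean``.  Artifact candidates are Poisson per
    region and carry EB score <= 5 and/or end-of-read-only support.

    Truth labels (``is_true``, ``true_vaf``) are retained for recovery tests.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    model = model or MutationModel()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for subj in cohort.itertuples():
        regions = list(subj.regions)
        n_regions = len(regions)
        used_sites: set = set()
        lam = model.mutations_per_region_mean * n_regions / _expected_span(
            model, n_regions
        )
        n_events = rng.poisson(lam)
        for _ in range(n_events):
            chrom, pos, ref, alt, sub = _draw_site(rng, used_sites)
            vaf_true = float(model.draw_true_vafs(rng, 1)[0])
            span = _region_span(rng, model, n_regions)
            mut_regions = [regions[j] for j in rng.choice(n_regions, span, False)]
            csq, cadd = _consequence(rng, model)
            gene = f"GENE{int(rng.integers(0, 20_000)):05d}"
            for region in mut_regions:
                depth = max(50, int(rng.gamma(20.0, model.mean_depth / 20.0)))
                alt_count = int(rng.binomial(depth, vaf_true))
                rows.append(
                    {
                        "subject": subj.subject, "tissue": region,
                        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                        "substitution": sub, "gene": gene,
                        "vaf": alt_count / depth, "depth": depth,
                        "alt_count": alt_count,
                        "eb_score": float(rng.uniform(6.0, 40.0)),
                        "caller": "replicate" if span >= 3 else "single",
                        "end_read_only": False,
                        "blat_second_avg": float(rng.uniform(0, 850))
                        if rng.random() < 0.3 else np.nan,
                        "clean_support": True,
                        "consequence": csq, "cadd": cadd,
                        "population_af": 0.0,
                        "is_true": True, "true_vaf": vaf_true,
                    }
                )
        # artifact candidates, independently per region
        for region in regions:
            for _ in range(rng.poisson(model.artifact_rate)):
                chrom, pos, ref, alt, sub = _draw_site(rng, used_sites)
                vaf_art = float(rng.uniform(0.005, 0.15))
                depth = max(50, int(rng.gamma(20.0, model.mean_depth / 20.0)))
                alt_count = max(1, int(rng.binomial(depth, vaf_art)))
                end_read = bool(rng.random() < 0.5)
                csq, cadd = _consequence(rng, model)
                rows.append(
                    {
                        "subject": subj.subject, "tissue": region,
                        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                        "substitution": sub,
                        "gene": f"GENE{int(rng.integers(0, 20_000)):05d}",
                        "vaf": alt_count / depth, "depth": depth,
                        "alt_count": alt_count,
                        "eb_score": float(rng.uniform(0.0, 5.0)),
                        "caller": "single",
                        "end_read_only": end_read,
                        "blat_second_avg": float(rng.uniform(900, 1000))
                        if rng.random() < 0.2 else np.nan,
                        "clean_support": bool(rng.random() < 0.8),
                        "consequence": csq, "cadd": cadd,
                        "population_af": 0.0,
                        "is_true": False, "true_vaf": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def simulate_amplicon(
    variants: pd.DataFrame,
    error_model: ErrorModel | None = None,
    depth: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ultradeep amplicon read counts for candidate variants.

    True variants (``is_true``) draw alt counts from
    ``Binomial(depth, true_vaf + class error rate)``; false candidates from
    ``Binomial(depth, class error rate)`` alone.  ``variants`` needs columns
    ``substitution``, ``is_true`` and ``true_vaf``; a ``variant_key`` column
    is used if present, otherwise one is built from coordinates.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    error_model = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    if "variant_key" in variants.columns:
        keys = variants["variant_key"].astype(str)
    else:
        keys = (
            variants["subject"].astype(str) + ":" + variants["chrom"].astype(str)
            + ":" + variants["pos"].astype(str) + variants["ref"] + ">"
            + variants["alt"]
        )
    subs = variants["substitution"].map(collapse_substitution)
    rates = subs.map(error_model.rate_by_substitution).to_numpy(float)
    true_vaf = variants["true_vaf"].fillna(0.0).to_numpy(float)
    p = np.where(variants["is_true"].to_numpy(bool), true_vaf + rates, rates)
    p = np.clip(p, 0.0, 1.0)
    alt = rng.binomial(depth, p) if depth > 0 else np.zeros(len(p), dtype=int)
    return pd.DataFrame(
        {
            "variant_key": keys.to_numpy(),
            "substitution": subs.to_numpy(),
            "depth": depth,
            "alt_count": alt,
            "platform": "TASeq",
            "is_true": variants["is_true"].to_numpy(bool),
        }
    )


def simulate_expression(
    genes: list[str] | int = 500,
    regions: tuple[str, ...] = EXPRESSION_REGIONS,
    stages: tuple[str, ...] = EXPRESSION_STAGES,
    planted_windows: list[tuple[str, str, list[str], float]] | None = None,
    noise: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a gene x region x stage expression tensor (long format).

    Background expression is log-normal around a per-gene baseline:
    ``rpkm = base_g * exp(noise * eps)``.  Each planted window
    ``(region, stage, gene_subset, effect)`` elevates its genes in that one
    cell additively by ``effect`` units of the gene's robust scale
    (``base_g * noise`` approximates ``1.4826 * MAD`` of the lognormal
    background), so each robust z component sits near ``effect`` above its
    background value and the meta-z exceeds the target in expectation.
    Returns a complete long-format frame with columns
    ``gene, region, stage, rpkm``.
    """
    if isinstance(genes, int):
        genes = [f"G{i:05d}" for i in range(genes)]
    planted_windows = planted_windows or []
    for region, stage, subset, _ in planted_windows:
        if region not in regions or stage not in stages:
            raise ValueError(f"planted window ({region}, {stage}) outside grid")
        unknown = set(subset) - set(genes)
        if unknown:
            raise ValueError(f"planted genes not in gene list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n_g, n_s, n_r = len(genes), len(stages), len(regions)
    base = rng.lognormal(mean=np.log(10.0), sigma=1.0, size=n_g)
    eps = rng.standard_normal((n_g, n_s, n_r))
    values = base[:, None, None] * np.exp(noise * eps)
    gene_idx = {g: i for i, g in enumerate(genes)}
    s_idx = {s: i for i, s in enumerate(stages)}
    r_idx = {r: i for i, r in enumerate(regions)}
    for region, stage, subset, effect in planted_windows:
        gi = [gene_idx[g] for g in subset]
        values[gi, s_idx[stage], r_idx[region]] += base[gi] * effect * noise
    long = pd.DataFrame(
        {
            "gene": np.repeat(genes, n_s * n_r),
            "stage": np.tile(np.repeat(stages, n_r), n_g),
            "region": np.tile(regions, n_g * n_s),
            "rpkm": values.ravel(),
        }
    )
    return long


def simulate_ppi(
    genes: list[str],
    mean_degree: float = 4.0,
    reliability_range: tuple[float, float] = (0.1, 0.9),
    planted_hub_genes: tuple[str, ...] = (),
    hub_degree_factor: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an undirected PPI edge table with reliability scores.

    Background edges follow an Erdos-Renyi graph with the requested mean
    degree; planted hub genes receive extra random partners until their
    degree reaches ``hub_degree_factor * mean_degree``.  Each unordered gene
    pair appears at most once.
    """
    lo, hi = reliability_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("reliability range must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(genes)
    edges: set[tuple[int, int]] = set()
    if n >= 2 and mean_degree > 0:
        p = min(1.0, mean_degree / (n - 1))
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < p
        edges.update(zip(iu[mask].tolist(), ju[mask].tolist()))
        gene_idx = {g: i for i, g in enumerate(genes)}
        degree = np.zeros(n, dtype=int)
        for i, j in edges:
            degree[i] += 1
            degree[j] += 1
        target = int(round(hub_degree_factor * mean_degree))
        for hub in planted_hub_genes:
            h = gene_idx[hub]
            others = [k for k in range(n) if k != h]
            rng.shuffle(others)
            for k in others:
                if degree[h] >= target:
                    break
                e = (min(h, k), max(h, k))
                if e not in edges:
                    edges.add(e)
                    degree[h] += 1
                    degree[k] += 1
    edge_list = sorted(edges)
    rel = rng.uniform(lo, hi, size=len(edge_list))
    return pd.DataFrame(
        {
            "gene_a": [genes[i] for i, _ in edge_list],
            "gene_b": [genes[j] for _, j in edge_list],
            "reliability": rel,
        }
    )


def simulate_reference_genesets(
    universe: list[str],
    n_lists: int = 8,
    list_size_range: tuple[int, int] = (20, 200),
    planted_overlap: tuple[list[str], int, int] | None = None,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Simulate GMT-style reference gene lists over a gene universe.

    ``planted_overlap = (target_set, list_index, k)`` forces the list at
    ``list_index`` to share exactly ``k`` genes with the target set; every
    other list is a uniform draw from the universe.
    """
    rng = np.random.default_rng(seed)
    lo, hi = list_size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError("invalid list size range for this universe")
    lists: dict[str, list[str]] = {}
    target: set[str] = set()
    idx_planted, k = -1, 0
    if planted_overlap is not None:
        target_list, idx_planted, k = planted_overlap
        target = set(target_list)
        if not target <= set(universe):
            raise ValueError("target set must be a subset of the universe")
    non_target = [g for g in universe if g not in target]
    for i in range(n_lists):
        size = int(rng.integers(lo, hi + 1))
        if i == idx_planted:
            if k > min(size, len(target)) or size - k > len(non_target):
                raise ValueError(
                    f"planted overlap k={k} infeasible for list size {size}"
                )
            inside = rng.choice(sorted(target), size=k, replace=False)
            outside = rng.choice(non_target, size=size - k, replace=False)
            members = sorted(inside.tolist() + outside.tolist())
        else:
            members = sorted(rng.choice(universe, size=size, replace=False))
        lists[f"REF_{i:02d}"] = members
    return lists
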