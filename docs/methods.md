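# Methods

This note records the models, parameter choices and numerical conventions
behind `brainmosaic`, and what the synthetic-data generators do and do not
emulate.

## Variant filtering model

Candidate somatic SNVs arrive as annotated tables (or VCFs) carrying the
caller's outputs as columns: VAF, depth, alt count, an empirical-Bayes
artifact score (EB), consequence string, CADD score, population allele
frequency, and two alignment-review surrogates (`end_read_only`,
`clean_support`, `blat_second_avg`). The filters never recompute
alignment-level evidence; they consume these columns.

Filter directions are strict as documented: EB ≤ 5 is exclusionary
(a score of exactly 5 fails), VAF must be strictly below the 20% (paired)
or 10% (unpaired) ceiling, unpaired depth must be at least 300, CADD must
be strictly above 20 to flag a damaging call, and barcode support must
strictly exceed 4. The unpaired rule is read as an *exclusion* of
depth < 300 and VAF ≥ 10% — i.e. stricter than the paired VAF < 20% rule.
A second-best BLAT average below 900 is treated as acceptance (missing
values pass). Each rejected call is attributed to the first criterion it
fails in the cascade's fixed order, so per-criterion rejection counts sum
to input minus output; because the cascade is a pure conjunction, the
surviving set is independent of criterion order.

Pseudoreplicate rescue treats the brain regions of one subject as
replicates: a variant identified by the exact tuple
(subject, chrom, pos, ref, alt) is rescued when called in at least two
distinct unordered region pairs — equivalently three distinct brain
regions — and never in the subject's peripheral tissue. Barcode
concordance requires, in *every* contributing region, > 4 barcodes, a
WES/BCDseq VAF ratio ≤ 10 and an absolute difference ≤ 0.05; a zero VAF
on one platform with a nonzero VAF on the other leaves the ratio
undefined and conservatively fails concordance.

## Amplicon validation statistic

A candidate with alt count *k* at filtered depth *n* is tested against
its substitution class's background error rate *r* with the one-sided
upper binomial tail `P(X ≥ k | n, r)`; `p < 0.05` validates. The six
background rates (T>A 0.00312, T>C 0.00797, T>G 0.000758, C>T 0.00407,
C>G 0.000765, C>A 0.00185) are platform constants measured from spike-in
replicate sequencing; purine-reference substitutions are strand-collapsed
to these classes before lookup. The exact binomial was chosen over a
Poisson approximation to stay exact at low depth; one-sidedness reflects
the question asked (more alt reads than error alone would produce).
Replicate observations of one candidate are pooled by summing depths and
alt counts before testing. Because the statistic is discrete, the
realized type-I error sits at or below the nominal 5%.

## Burden conventions

Burden denominators are subject-region pairs: each sampled brain region
of each subject contributes one observation, including explicit zero rows.
Genome extrapolation is exactly linear (count × 3 Gb / 75 Mb by default;
both sizes configurable). Transcript-length normalization divides a
gene's per-category count by its supplied canonical transcript length
(mutations per kb); the LOF_MIS vs SYN comparison and all other two-group
comparisons use scipy's t and Mann-Whitney U implementations, with the
degenerate equal-constant case pinned to p = 1.

## Risk assessment

The carrier 2×2 (case/control × carrier/non-carrier) is tested with the
two-sided Fisher exact test under the standard point-mass-summation
convention. The reported odds ratio is the conditional maximum-likelihood
estimate — the root of `E_ψ[X] = a` under Fisher's noncentral
hypergeometric distribution given all margins — with the exact 95% CI
obtained by inverting the noncentral tail probabilities at α/2 per side;
this is the estimator conventionally paired with the exact test and it
shrinks toward 1 relative to the sample cross-product ratio, which is
reported alongside. A zero margin leaves the OR undefined (NaN) with
p = 1. Missing population AF in the germline filter is treated as 0: a
variant absent from the population database cannot be common. The
germline ≥ 30% allele-fraction rule is a within-sample heterozygous-call
heuristic, not a population frequency. Merged gene sets use union
(deduplicating) semantics across subjects and mutation sources.

## Spatiotemporal signatures

For gene *i* at stage *s* and region *r*, the stage-wise z compares
`e_i^sr` with the gene's distribution across all regions at *s*, and the
region-wise z across all stages at *r*, each as
`(e − median) / (1.4826·MAD)`; the meta-z is `(z_s + z_r)/√2` and genes
with meta-z ≥ 1.5 form the window's signature. When a MAD is zero the
affected component is undefined and the gene is excluded from that
window's signature (the robust scale is uninformative there). The
construction is invariant to global rescaling of the tensor and to
per-gene additive shifts. Enrichment of a gene set in a window is the
one-sided hypergeometric upper tail over the tensor's gene universe
(set members absent from the tensor are dropped with a logged count);
the 150 windows of one gene set form a single Benjamini-Hochberg family
and windows are flagged at q < 0.05.

## Permutation and PPI tests

The overlap null draws subsets of the cohort gene pool without
replacement (a draw is a gene subset, matching how a merged gene set
arises). The empirical p uses the add-one estimator
`(1 + #{null ≥ obs})/(n_perm + 1)`, which cannot be zero and differs from
the raw fraction by at most 1/(n_perm+1); the "5% cutoff" reported
alongside is the null distribution's 95th percentile (smallest overlap
count at or above it). As n_perm grows the empirical p converges to the
exact hypergeometric tail, which the tests verify by full enumeration on
small pools. Weighted PPI degree sums the reliability scores of a gene's
interactions (each edge contributes to both endpoints; self-loops count
once); groups are compared two-sided by Mann-Whitney U.

## Synthetic-data generators

The generators' defaults are the study conditions: 24 cases (13 with a
matched peripheral tissue) and 31 controls (all matched), five brain
regions per subject, ~2.4 true somatic SNVs per exome per region, VAFs in
(0.3%, 20%) with mean ≈ 5.3%, and sequencing depth around 560×. Choices
the data do not pin down were made once and documented here:

- **True-VAF family** — Beta(1.2, 3.53) rescaled to (0.003, 0.2); the
  shape reproduces the observed low-VAF-dominated range and the ≈ 5.3%
  mean. The family itself is a modeling choice, not an observed fact.
- **Region sharing** — a two-epoch model: with probability
  `shared_region_fraction` a mutation is "early" and spans a uniform
  3–5 regions, otherwise "late" spanning 1–2. The per-subject event rate
  is scaled by the expected span so the per-region mean is exact in
  expectation.
- **Artifacts** — Poisson per region (default 1 per region), carrying
  EB ≤ 5 and/or end-of-read support. This makes artifact/true separation
  by the EB criterion clean by construction; real artifact scores
  overlap the threshold, so pipeline precision on real data is an
  empirical question the synthetic recall/precision tests do not answer.
- **Substitution classes** — uniform over the six pyrimidine-context
  classes; no trinucleotide-context spectrum is simulated.
- **Expression** — per-gene log-normal baselines with multiplicative
  log-normal noise (σ = 0.5 by default). A planted window elevates its
  genes additively by `effect` units of the gene's robust scale
  (`base·noise ≈ 1.4826·MAD` of the background), so each z component
  rises by ≈ `effect` over its background value. Real atlases have
  region-region correlation and developmental trends that this
  independence model lacks.
- **PPI** — Erdős–Rényi background at the requested mean degree with hub
  genes topped up to 10× mean degree; reliabilities uniform in (0.1, 0.9).
- **Sex** — Bernoulli(0.5), used only by the burden comparison.

Every generator is deterministic under its seed and keeps truth labels
(`is_true`, `true_vaf`, planted gene lists), which is what the recovery
tests score against.

## Problem sizes and tolerances

Monte-Carlo tests use 3-standard-error bands around oracle values;
exactness tests compare against rational-arithmetic summation oracles at
1e-12. The planted-window recovery suite uses 400-gene tensors over 100
seeds (20 in the acceptance script); permutation-vs-enumeration checks
use 10,000 permutations on pools up to size 12; type-I calibrations use
10,000 null amplicon sites and 500–1,000 reanalysis seeds. These sizes
make the checks statistically decisive while keeping the default suite
fast.

## Known limitations

- Upstream callers (MuTect2/RePlow-style), EB scoring, VEP annotation and
  CADD scoring are consumed as input columns, never recomputed; the
  ambiguous manual-review criterion concerning the fraction of supporting
  reads is not implemented (its inputs are exposed as pre-computed flags).
- The biological headline findings that depend on real reference gene
  lists, the real expression atlas and the real PPI database (specific GO
  term p-values, the 4.03 vs 1.93 PPI medians) are not reproducible from
  synthetic inputs; the package reproduces the *methods* and verifies
  them by calibration and planted-signal recovery instead.
- The published germline per-subject gene lists are not public; bundled
  stand-ins (labelled synthetic) match the published summary counts only.
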