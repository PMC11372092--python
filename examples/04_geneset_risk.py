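"""Merged damaging gene sets and case-control risk assessment.

Builds the ASD merged gene set from the bundled validated damaging
somatic calls (7 genes across 6 subjects) plus an 11-gene germline risk
set, then tests the published merged carrier table (14 of 24 cases vs
8 of 31 controls) with a two-sided Fisher exact test.
"""

from brainmosaic import datasets, risk

somatic = risk.select_damaging_somatic(datasets.example_validated_somatic_calls())
print(f"somatic damaging genes: {sorted(set().union(*somatic.values()))}")

germline = datasets.synthetic_germline_genesets()["ASD"]
merged = risk.merge_genesets(somatic, germline)
print(f"merged ASD gene set: {len(merged)} genes "
      f"({(merged.source == 'somatic').sum()} somatic, "
      f"{(merged.source == 'germline').sum()} germline)")

counts = datasets.example_carrier_counts()["merged"]
res = risk.fisher_risk(counts)
print(f"\ncarrier table {res.table}")
print(f"odds ratio (conditional MLE) = {res.odds_ratio:.2f} "
      f"(sample OR {res.sample_odds_ratio:.3f})")
print(f"95% CI {res.ci_low:.3f}-{res.ci_high:.3f}, "
      f"two-sided Fisher p = {res.p_two_sided:.4f}")
# Carrying a damaging somatic or germline variant in the merged gene set
# is ~3.9x more likely in cases; the CI excluding 1 marks significance.
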