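"""Permutation gene-set overlap test and PPI weighted-degree comparison.

Draws random 18-gene subsets from a 60-gene cohort pool (10,000
permutations) to test whether a target set's overlap with a reference
list exceeds chance, then compares weighted PPI degrees of planted hub
genes against background genes.
"""

import numpy as np

from brainmosaic import enrichment as enr, synthetic as syn

rng = np.random.default_rng(0)
pool = [f"g{i}" for i in range(60)]
target = list(rng.choice(pool, size=18, replace=False))
lists = syn.simulate_reference_genesets(
    pool, n_lists=1, list_size_range=(25, 25),
    planted_overlap=(target, 0, 12), seed=1,
)
res = enr.permutation_overlap_test(pool, target, lists["REF_00"], seed=2)
print(f"observed overlap {res.observed_overlap}, "
      f"null 95th-percentile cutoff {res.cutoff_95}, "
      f"empirical p = {res.p_value:.4f}")
# overlap above the cutoff (equivalently p < 0.05) marks enrichment

genes = [f"g{i}" for i in range(500)]
hubs = genes[:50]
edges = syn.simulate_ppi(genes, mean_degree=3.0,
                         planted_hub_genes=tuple(hubs), seed=4)
score = enr.ppi_weighted_degree(edges, genes=genes)
background = rng.choice(genes[50:], size=50, replace=False)
ppi = enr.compare_ppi(score[hubs], score[background])
print(f"hub median weighted degree {ppi['median_a']:.2f} vs background "
      f"{ppi['median_b']:.2f}; two-sided rank-sum p = {ppi['p_value']:.2e}")
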