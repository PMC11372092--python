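"""Generators: determinism, planted structure, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainmosaic import synthetic as syn
from brainmosaic.expression import build_signatures
from brainmosaic.validation import ErrorModel


class TestGenerateCohort:
    def test_empty_cohort(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_cases=0, n_controls=0))
        assert cohort.empty

    def test_study_shape(self):
        """24 cases (13 paired) + 31 controls (all paired) = 55 / 44."""
        cohort = syn.generate_cohort(syn.CohortSpec(seed=3))
        assert len(cohort) == 55
        assert cohort["paired"].sum() == 44
        assert (cohort["diagnosis"] == "ASD").sum() == 24
        paired_cases = cohort[(cohort.diagnosis == "ASD") & cohort.paired]
        assert len(paired_cases) == 13

    def test_deterministic_under_seed(self):
        a = syn.generate_cohort(syn.CohortSpec(seed=42))
        b = syn.generate_cohort(syn.CohortSpec(seed=42))
        pd.testing.assert_frame_equal(a, b)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            syn.CohortSpec(n_cases=-1)


class TestSimulateCallsets:
    def test_deterministic_under_seed(self, default_cohort):
        a = syn.simulate_callsets(default_cohort, seed=5)
        b = syn.simulate_callsets(default_cohort, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_forced_sharing(self, default_cohort):
        model = syn.MutationModel(artifact_rate=0.0, shared_region_fraction=1.0)
        calls = syn.simulate_callsets(default_cohort, model, seed=6)
        spans = calls.groupby(["subject", "chrom", "pos"])["tissue"].nunique()
        assert (spans >= 3).all()

    def test_true_vaf_mean_recovered(self):
        """Monte-Carlo mean of true VAFs within 3 SE of the model mean."""
        cohort = syn.generate_cohort(syn.CohortSpec(n_cases=250, n_controls=0))
        model = syn.MutationModel(mutations_per_region_mean=20, artifact_rate=0)
        calls = syn.simulate_callsets(cohort, model, seed=7)
        events = calls.drop_duplicates(["subject", "chrom", "pos"])
        vafs = events["true_vaf"].to_numpy()
        assert len(vafs) >= 10_000
        se = vafs.std() / np.sqrt(len(vafs))
        assert abs(vafs.mean() - model.true_vaf_mean) < 3 * se

    def test_per_region_rate_recovered(self):
        """mutations_per_region_mean=2.4 recovered over 1,000 region-samples."""
        cohort = syn.generate_cohort(syn.CohortSpec(n_cases=200, n_controls=0))
        calls = syn.simulate_callsets(
            cohort, syn.MutationModel(artifact_rate=0.0), seed=8
        )
        per_region = calls.groupby(["subject", "tissue"]).size()
        n_region_samples = 200 * 5
        mean = per_region.sum() / n_region_samples
        assert 2.25 <= mean <= 2.55

    def test_artifacts_carry_filterable_marks(self, default_calls):
        artifacts = default_calls[~default_calls["is_true"]]
        assert (artifacts["eb_score"] <= 5).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_callsets(pd.DataFrame(), seed=0)


class TestSimulateAmplicon:
    def test_zero_depth_gives_zero_counts(self, default_calls):
        amp = syn.simulate_amplicon(default_calls.head(20), depth=0, seed=0)
        assert (amp["alt_count"] == 0).all()

    def test_background_rate_recovered(self):
        """False T>G candidates at depth 10,000 recover the printed rate."""
        n = 2000
        variants = pd.DataFrame(
            {
                "variant_key": [f"v{i}" for i in range(n)],
                "substitution": "T>G",
                "is_true": False,
                "true_vaf": np.nan,
            }
        )
        amp = syn.simulate_amplicon(variants, depth=10_000, seed=9)
        mean_frac = (amp["alt_count"] / amp["depth"]).mean()
        assert 0.0005 <= mean_frac <= 0.0011

    def test_true_variant_in_binomial_interval(self):
        """VAF 5% at depth 10,000: alt count inside the 99.9% interval."""
        rate = ErrorModel().rate("C>T")
        variants = pd.DataFrame(
            {
                "variant_key": ["v0"], "substitution": ["C>T"],
                "is_true": [True], "true_vaf": [0.05],
            }
        )
        amp = syn.simulate_amplicon(variants, depth=10_000, seed=10)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 10_000, 0.05 + rate)
        assert lo <= amp["alt_count"].iloc[0] <= hi

    def test_unknown_class_rejected(self):
        variants = pd.DataFrame(
            {"variant_key": ["v"], "substitution": ["C>X"],
             "is_true": [False], "true_vaf": [np.nan]}
        )
        with pytest.raises(ValueError, match="C>X"):
            syn.simulate_amplicon(variants, seed=0)


class TestSimulateExpression:
    def test_grid_dimensions(self):
        tensor = syn.simulate_expression(genes=30, seed=1)
        assert len(tensor) == 30 * 15 * 10
        assert tensor["region"].nunique() == 15
        assert tensor["stage"].nunique() == 10

    def test_constant_tensor_yields_empty_signatures(self):
        tensor = syn.simulate_expression(genes=20, noise=0.0, seed=2)
        model = build_signatures(tensor)
        assert model.n_windows == 150
        assert all(len(s) == 0 for s in model.signatures().values())

    def test_planted_genes_recovered(self):
        planted = [f"G{i:05d}" for i in range(20)]
        tensor = syn.simulate_expression(
            genes=400,
            planted_windows=[("STR", "early_fetal", planted, 5.0)],
            seed=3,
        )
        sig = build_signatures(tensor).signature("early_fetal", "STR")
        assert len(sig & set(planted)) >= 18

    def test_window_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_expression(
                genes=10, planted_windows=[("NOPE", "early_fetal", [], 1.0)]
            )


class TestSimulatePPI:
    def test_zero_degree_empty(self):
        edges = syn.simulate_ppi([f"g{i}" for i in range(50)], mean_degree=0.0)
        assert edges.empty

    def test_unordered_pairs_unique(self):
        genes = [f"g{i}" for i in range(100)]
        edges = syn.simulate_ppi(genes, mean_degree=6.0, seed=4)
        pairs = {frozenset((a, b)) for a, b in zip(edges.gene_a, edges.gene_b)}
        assert len(pairs) == len(edges)

    def test_planted_hubs_have_higher_degree(self):
        from brainmosaic.enrichment import compare_ppi, ppi_weighted_degree

        genes = [f"g{i}" for i in range(500)]
        hubs = tuple(genes[:50])
        edges = syn.simulate_ppi(
            genes, mean_degree=3.0, planted_hub_genes=hubs, seed=5
        )
        score = ppi_weighted_degree(edges, genes=genes)
        background = score.drop(list(hubs)).sample(50, random_state=0)
        result = compare_ppi(score[list(hubs)], background)
        assert result["median_a"] > result["median_b"]
        assert result["p_value"] < 0.01


class TestSimulateReferenceGenesets:
    @pytest.mark.parametrize("k", [0, 5, 18])
    def test_planted_overlap_exact(self, k):
        universe = [f"g{i}" for i in range(200)]
        target = universe[:18]
        lists = syn.simulate_reference_genesets(
            universe, n_lists=4, list_size_range=(30, 60),
            planted_overlap=(target, 2, k), seed=6,
        )
        assert len(set(lists["REF_02"]) & set(target)) == k

    def test_infeasible_overlap_rejected(self):
        universe = [f"g{i}" for i in range(50)]
        with pytest.raises(ValueError):
            syn.simulate_reference_genesets(
                universe, n_lists=1, list_size_range=(5, 5),
                planted_overlap=(universe[:3], 0, 4), seed=0,
            )
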