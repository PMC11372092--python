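"""Post-call filter cascade: criteria, rescue logic and recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from brainmosaic import filtering as flt
from brainmosaic import synthetic as syn
from conftest import calls_frame, make_call


class TestFilterPairedCalls:
    @pytest.mark.parametrize(
        "override, kept",
        [
            ({}, True),
            ({"vaf": 0.25}, False),            # VAF >= 20% excluded
            ({"vaf": 0.1999}, True),
            ({"eb_score": 5.0}, False),        # EB <= 5 is exclusionary
            ({"eb_score": 5.0001}, True),
            ({"end_read_only": True}, False),
            ({"clean_support": False}, False),
            ({"blat_second_avg": 950.0}, False),
            ({"blat_second_avg": 899.0}, True),
            ({"blat_second_avg": np.nan}, True),
        ],
    )
    def test_single_criterion(self, override, kept):
        out, _ = flt.filter_paired_calls(calls_frame(override))
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        out, rejected = flt.filter_paired_calls(pd.DataFrame())
        assert out.empty
        assert all(v == 0 for v in rejected.values())

    def test_rejection_counts_conserve(self, default_calls):
        out, rejected = flt.filter_paired_calls(default_calls)
        assert sum(rejected.values()) == len(default_calls) - len(out)

    def test_subset_and_idempotent(self, default_calls):
        out, _ = flt.filter_paired_calls(default_calls)
        assert out.index.isin(default_calls.index).all()
        again, rejected = flt.filter_paired_calls(out)
        pd.testing.assert_frame_equal(again, out)
        assert sum(rejected.values()) == 0

    def test_survivors_match_row_wise_conjunction(self, default_calls):
        """Surviving set equals an independently evaluated conjunction,
        so criterion ordering cannot matter."""
        out, _ = flt.filter_paired_calls(default_calls)
        expect = [
            i for i, r in default_calls.iterrows()
            if r.vaf < 0.20 and r.eb_score > 5 and not r.end_read_only
            and r.clean_support
            and (pd.isna(r.blat_second_avg) or r.blat_second_avg < 900)
        ]
        assert list(out.index) == expect

    def test_missing_vaf_raises(self):
        with pytest.raises(ValueError, match="missing vaf"):
            flt.filter_paired_calls(calls_frame({"vaf": np.nan}))


class TestFilterUnpairedCalls:
    @pytest.mark.parametrize(
        "override, kept",
        [
            ({"depth": 299, "vaf": 0.05}, False),   # depth < 300 excluded
            ({"depth": 500, "vaf": 0.10}, False),   # VAF >= 10% excluded
            ({"depth": 500, "vaf": 0.05}, True),
            ({"depth": 300, "vaf": 0.0999}, True),
        ],
    )
    def test_strict_thresholds(self, override, kept):
        out, _ = flt.filter_unpaired_calls(calls_frame(override))
        assert (len(out) == 1) is kept

    def test_paired_criteria_still_apply(self):
        out, _ = flt.filter_unpaired_calls(
            calls_frame({"depth": 500, "vaf": 0.05, "eb_score": 2.0})
        )
        assert out.empty


class TestFindReplicateCalls:
    def _calls(self, tissues, subject="S1"):
        return calls_frame(*[{"tissue": t, "subject": subject} for t in tissues])

    def test_three_regions_rescued(self):
        out = flt.find_replicate_calls(self._calls(["BA9", "BA21", "BA17"]))
        assert len(out) == 1
        assert out.iloc[0]["n_region_pairs"] == 3

    def test_two_regions_not_rescued(self):
        assert flt.find_replicate_calls(self._calls(["BA9", "BA21"])).empty

    def test_peripheral_presence_blocks_rescue(self):
        out = flt.find_replicate_calls(
            self._calls(["BA9", "BA21", "BA17", "heart"])
        )
        assert out.empty

    def test_agrees_with_pairwise_enumeration(self):
        """Brute-force oracle: count distinct unordered region pairs and
        require >= 2, on random instances with <= 5 regions."""
        rng = np.random.default_rng(17)
        regions = list(syn.BRAIN_REGIONS)
        rows = []
        for v in range(60):
            subject = f"S{v % 7}"
            pos = 1000 + v
            n = int(rng.integers(1, 6))
            tissues = list(rng.choice(regions + ["heart"], size=n, replace=False))
            rows += [
                make_call(subject=subject, pos=pos, tissue=t) for t in tissues
            ]
        calls = pd.DataFrame(rows)
        rescued = flt.find_replicate_calls(calls)
        got = set(zip(rescued["subject"], rescued["pos"]))
        want = set()
        for (subject, pos), grp in calls.groupby(["subject", "pos"]):
            brain = {t for t in grp["tissue"] if t != "heart"}
            pairs = list(itertools.combinations(sorted(brain), 2))
            if len(pairs) >= 2 and "heart" not in set(grp["tissue"]):
                want.add((subject, pos))
        assert got == want


class TestFilterBcdCalls:
    def _bcd(self, rows):
        base = {
            "subject": "S1", "chrom": "chr1", "pos": 100, "ref": "C", "alt": "T",
        }
        return pd.DataFrame([base | r for r in rows])

    def test_barcode_threshold_strict(self):
        bcd = self._bcd([
            {"region": "BA9", "barcode_count": 4, "wes_vaf": 0.02, "bcd_vaf": 0.02},
            {"region": "BA21", "barcode_count": 10, "wes_vaf": 0.02, "bcd_vaf": 0.02},
        ])
        assert flt.filter_bcd_calls(bcd).empty

    def test_fold_change_limit(self):
        bcd = self._bcd([
            {"region": "BA9", "barcode_count": 10, "wes_vaf": 0.010,
             "bcd_vaf": 0.0009},  # ratio 11.1
            {"region": "BA21", "barcode_count": 10, "wes_vaf": 0.02,
             "bcd_vaf": 0.02},
        ])
        assert flt.filter_bcd_calls(bcd).empty

    def test_concordant_pair_passes(self):
        bcd = self._bcd([
            {"region": "BA9", "barcode_count": 10, "wes_vaf": 0.02, "bcd_vaf": 0.03},
            {"region": "BA21", "barcode_count": 10, "wes_vaf": 0.02, "bcd_vaf": 0.03},
        ])
        assert len(flt.filter_bcd_calls(bcd)) == 1

    def test_zero_vaf_fails_concordance(self):
        bcd = self._bcd([
            {"region": "BA9", "barcode_count": 10, "wes_vaf": 0.0, "bcd_vaf": 0.02},
            {"region": "BA21", "barcode_count": 10, "wes_vaf": 0.02, "bcd_vaf": 0.02},
        ])
        assert flt.filter_bcd_calls(bcd).empty


class TestConsequenceClassification:
    @pytest.mark.parametrize(
        "csq, category",
        [
            ("missense_variant", "LOF_MIS"),
            ("stop_gained", "LOF_MIS"),
            ("start_lost", "LOF_MIS"),
            ("stop_lost", "LOF_MIS"),
            ("splice_donor_variant", "LOF_MIS"),
            ("splice_acceptor_variant", "LOF_MIS"),
            ("synonymous_variant", "SYN"),
            ("intron_variant", "OTHER"),
            ("MISSENSE_VARIANT", "LOF_MIS"),
            ("synonymous_variant,missense_variant", "LOF_MIS"),
            ("intron_variant&synonymous_variant", "SYN"),
        ],
    )
    def test_classify(self, csq, category):
        assert flt.classify_consequence(csq) == category

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            flt.classify_consequence("  ")

    @pytest.mark.parametrize(
        "csq, cadd, damaging",
        [
            ("missense_variant", 20.0, False),  # strict >20
            ("missense_variant", 25.1, True),
            ("synonymous_variant", 35.0, False),
        ],
    )
    def test_flag_damaging(self, csq, cadd, damaging):
        assert flt.flag_damaging(csq, cadd) is damaging

    def test_missing_cadd_warns_false(self):
        with pytest.warns(UserWarning):
            assert flt.flag_damaging("missense_variant", float("nan")) is False


class TestPipelineRecovery:
    def test_shared_true_variants_fully_recalled(self, default_cohort):
        """With artifact EB <= 5 and true EB > 5 the cascade keeps every
        shared (>=3-region) true variant and every artifact is rejected."""
        calls = syn.simulate_callsets(
            default_cohort, syn.MutationModel(artifact_rate=2.0), seed=21
        )
        kept, _ = flt.filter_paired_calls(calls)
        assert not kept.empty
        precision = kept["is_true"].mean()
        assert precision == 1.0  # artifacts are all EB <= 5 by construction
        shared = (
            calls[calls["is_true"]]
            .groupby(["subject", "chrom", "pos"])["tissue"]
            .nunique()
        )
        shared_keys = set(shared[shared >= 3].index)
        kept_keys = set(
            kept.groupby(["subject", "chrom", "pos"]).groups
        )
        assert shared_keys <= kept_keys
        rescued = flt.find_replicate_calls(kept)
        rescued_keys = set(
            zip(rescued["subject"], rescued["chrom"], rescued["pos"])
        )
        assert shared_keys <= rescued_keys
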