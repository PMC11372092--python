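import numpy as np
import pandas as pd
import pytest

from brainmosaic import synthetic as syn


@pytest.fixture(scope="session")
def default_cohort():
    return syn.generate_cohort(syn.CohortSpec(seed=11))


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    return syn.simulate_callsets(default_cohort, seed=12)


def make_call(**overrides) -> dict:
    """A candidate call that passes every post-call filter by default."""
    base = {
        "subject": "S1", "tissue": "BA9", "chrom": "chr1", "pos": 1000,
        "ref": "C", "alt": "T", "vaf": 0.05, "depth": 500, "alt_count": 25,
        "eb_score": 12.0, "caller": "single", "end_read_only": False,
        "blat_second_avg": np.nan, "clean_support": True,
        "consequence": "missense_variant", "cadd": 25.0, "population_af": 0.0,
    }
    base.update(overrides)
    return base


def calls_frame(*rows) -> pd.DataFrame:
    return pd.DataFrame([make_call(**r) for r in rows])
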