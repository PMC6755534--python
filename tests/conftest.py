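import numpy as np
import pytest

from bwmr.simulate import (
    forty_three_snp_config,
    seven_snp_config,
    simulate_cohort,
    simulate_two_sample_summary,
)
from bwmr.summary_io import InstrumentVariant


def make_variant(
    rsid="rs1",
    ea="A",
    oa="G",
    eaf=0.3,
    bx=0.02,
    sx=0.004,
    by=0.05,
    sy=0.02,
    outcome_type="binary",
):
    return InstrumentVariant(
        rsid=rsid, effect_allele=ea, other_allele=oa, eaf=eaf,
        beta_exposure=bx, se_exposure=sx, beta_outcome=by, se_outcome=sy,
        outcome_type=outcome_type,
    )


@pytest.fixture(scope="session")
def cohort_7snp():
    """Moderate cohort from the 7-SNP configuration (shared, read-only)."""
    return simulate_cohort(seven_snp_config(seed=42), 20_000)


@pytest.fixture(scope="session")
def two_sample_43snp():
    """One two-sample summary draw at reduced sizes (shared, read-only)."""
    cfg = forty_three_snp_config(
        seed=7, n_exposure_sample=20_000, n_outcome_cases=4_000, n_outcome_controls=4_000
    )
    return simulate_two_sample_summary(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
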