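import numpy as np
import pytest

from karyocov import (
    AUTOSOMES,
    SimulationConfig,
    rank_autosome_normalizations,
    simulate_cohort,
    split_groups,
)
from karyocov.coverage_io import CANONICAL_CHROMS, SampleCoverage


def make_sample(
    sample_id="s1",
    capture="CES",
    index_mode="single",
    base=100.0,
    overrides=None,
    target_bases=None,
):
    """A flat-coverage sample with optional per-chromosome overrides."""
    mean_cov = {c: float(base) for c in CANONICAL_CHROMS}
    if overrides:
        mean_cov.update(overrides)
    return SampleCoverage(
        sample_id=sample_id, capture=capture, index_mode=index_mode,
        mean_cov=mean_cov, target_bases=target_bases,
    )


@pytest.fixture(scope="session")
def ces_cohort():
    """300-sample CES-like control cohort, sigma_c = 0.02 everywhere, seed 1."""
    cfg = SimulationConfig.from_preset(
        "CES-like", n_samples=300, seed=1,
        noise_sd={c: 0.02 for c in CANONICAL_CHROMS},
    )
    table, truth = simulate_cohort(cfg)
    cohort = split_groups(table)[0]
    assert cohort.usable
    return cohort


@pytest.fixture(scope="session")
def ces_rankings(ces_cohort):
    return {c: rank_autosome_normalizations(ces_cohort, c) for c in AUTOSOMES}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
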