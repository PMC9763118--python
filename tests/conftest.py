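"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pytest

from pathprs import SimConfig, simulate_case_control_study
from pathprs.scoring import ClumpConfig, clump, harmonize_alleles


@pytest.fixture(scope="session")
def small_cfg():
    # moderate prevalence keeps the ascertainment pool small and fast
    return SimConfig(
        n_samples=400,
        n_variants=800,
        n_genes=16,
        prevalence=0.05,
        case_fraction=0.5,
        discovery_n=20_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_case_control_study(small_cfg)


@pytest.fixture(scope="session")
def harmonized(small_study):
    stats, _ = harmonize_alleles(
        small_study.summary_stats, small_study.dosages.variants
    )
    return stats


@pytest.fixture(scope="session")
def clumped_ids(small_study, harmonized):
    return clump(harmonized, small_study.dosages, ClumpConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
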