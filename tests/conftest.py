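"""Shared fixtures: simulated cohorts at two scales.

The full-scale cohort (39 tumors, 22 x 3 Mb chromosomes) drives the
end-to-end recovery tests; the tiny cohort (3 tumors, 12 x 0.3 Mb
chromosomes) keeps structural/IO/pipeline tests fast.
"""

from __future__ import annotations

import warnings

import pytest

from pnetloh.pipeline import StageParams, analyze_cohort
from pnetloh.simulate import SimConfig, simulate_cohort


def tiny_config(**overrides) -> SimConfig:
    base = dict(
        n_group1=1, n_group2=1, n_group3=1,
        n_chromosomes=12, chrom_length=300_000,
        snps_per_chrom=60, genes_per_chrom=30,
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(tiny_config())


@pytest.fixture(scope="session")
def full_cohort():
    """The default 39-tumor study cohort (10/16/13 tumors in groups 1/2/3)."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def full_report(full_cohort):
    """Full pipeline run on the 39-tumor cohort (shared across tests)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_cohort(full_cohort, params=StageParams(seed=11))
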