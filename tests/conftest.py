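"""Shared fixtures: scaled-down cohorts for unit tests.

Unit tests run on miniature chromosomes (12 kb) with proportionally
shrunk SDR sections so a full cohort simulates in ~1 s; the acceptance
suite uses the full-size defaults.
"""

import numpy as np
import pytest

from sdrpipe.simdata import Cohort, SimConfig


def small_config(**over) -> SimConfig:
    base = dict(
        chrom_length=12_000,
        section_sizes={
            "retro_insert": 300,
            "cassette_total": 2_000,
            "flanking_total": 1_200,
            "outer_total": 600,
        },
        gmew_codons=80,
        stop_codon_at=45,
        n_females=3,
        n_males=3,
        seed=11,
    )
    base.update(over)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_gamma_cohort() -> Cohort:
    return Cohort(small_config(clade_of_female=("gamma",) * 3))


@pytest.fixture(scope="session")
def small_beta_cohort() -> Cohort:
    return Cohort(small_config(clade_of_female=("beta",) * 3))


@pytest.fixture(scope="session")
def small_alpha_cohort() -> Cohort:
    return Cohort(small_config(clade_of_female=("alpha",) * 3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))
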