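import random

import pytest

from asmcompare.core import Thresholds
from asmcompare.pipeline import run_synthetic_replicate
from asmcompare.simulate import (
    derive_assemblies,
    generate_bes_library,
    generate_true_genome,
    standard_event_suite,
)

#: seeds of the full-pipeline replicates shared by the end-to-end checks
REPLICATE_SEEDS = tuple(range(1, 21))


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture()
def rng():
    return random.Random(20_240_101)


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def small_true():
    """A cheap 2-chromosome true genome for unit tests (no low-copy family)."""
    return generate_true_genome(
        2, [400_000, 400_000], repeat_family_count=1, repeat_copies=6,
        seed=11, segdup_families=0,
    )


@pytest.fixture(scope="session")
def replicates():
    """Twenty seeded full-pipeline replicates under the standard study
    conditions (8 chromosomes x 2 Mbp, 12 planted events, 300 BES clones).

    Computed once per session; both the planted-event recovery checks and
    the FISH/PCR verdict checks read from these.
    """
    out = []
    for seed in REPLICATE_SEEDS:
        true, truth, result = run_synthetic_replicate(seed)
        out.append((seed, truth, result))
    return out
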