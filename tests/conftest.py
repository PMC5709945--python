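import numpy as np
import pytest

from mapsv import (
    DigestionParams,
    ErrorModelParams,
    HaplotypeMap,
    VariantPlan,
    digest,
    inject_variants,
    simulate_molecules,
)
from mapsv.simulator import random_genome


@pytest.fixture(scope="session")
def small_genome() -> str:
    """A 2 Mbp random reference chromosome shared by unit tests."""
    return random_genome(2_000_000, seed=101)


@pytest.fixture(scope="session")
def small_refmap(small_genome):
    return digest({"chr1": small_genome}, DigestionParams())


@pytest.fixture(scope="session")
def mutated_small(small_genome):
    """Small genome with 12 large indels plus the truth list."""
    plan = VariantPlan(n_insertions=6, n_deletions=6)
    mutated, truth = inject_variants(small_genome, plan, seed=202)
    return mutated, truth


@pytest.fixture(scope="session")
def noisy_molecules(mutated_small):
    mutated, _ = mutated_small
    hap = HaplotypeMap.from_sequences(1, {"chr1": mutated})
    return simulate_molecules([hap], ErrorModelParams(coverage=60), seed=303)
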