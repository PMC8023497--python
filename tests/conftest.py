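import pytest

from mitoarch import fixtures
from mitoarch.synthetic import SynthSpec, synth_genome


@pytest.fixture(scope="session")
def reference():
    """The packaged 36-gene reference annotation (17,064 bp, no sequence)."""
    return fixtures.reference_annotation()


@pytest.fixture(scope="session")
def region_table():
    return fixtures.reference_region_table()


@pytest.fixture(scope="session")
def codon_counts():
    return fixtures.reference_codon_counts()


@pytest.fixture(scope="session")
def codon_table_df():
    return fixtures.reference_codon_table()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One default synthetic genome, shared across tests that only read it."""
    return synth_genome(SynthSpec(seed=11))


def small_spec(seed: int, **overrides) -> SynthSpec:
    """A compact genome (8 genes, ~3 kb) for fast round-trip tests."""
    defaults = dict(
        seed=seed,
        genome_length=3600,
        gene_set=("cox1", "trnL2", "nad3", "trnK", "rrnS", "nad4l", "trnF", "cox3"),
        gene_lengths={"cox1": 900, "nad3": 354, "rrnS": 500, "nad4l": 288, "cox3": 789},
        cr_length=300,
        hairpin=(7, 8),
        cr_after="nad3",
    )
    defaults.update(overrides)
    return SynthSpec(**defaults)
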