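import pytest

from mitocomp.synthetic_data import SyntheticSpec, simulate_genome


@pytest.fixture(scope="session")
def base_genome():
    """One default synthetic genome (Pancrustacea order, seed 0)."""
    return simulate_genome(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def base_fixture_dir(tmp_path_factory, base_genome):
    """GenBank/FASTA/TSV files for the default genome."""
    from mitocomp.synthetic_data import write_fixture

    d = tmp_path_factory.mktemp("fixtures")
    write_fixture(base_genome, d)
    return d
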