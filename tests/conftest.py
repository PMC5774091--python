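import pytest

from familyscan import synthetic_data as sd


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic genome shared across the suite (seed 1)."""
    return sd.generate_genome(sd.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def family_rows():
    from familyscan import genome_io

    return genome_io.load_family_table()
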