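import pytest

import seqppi as sp


@pytest.fixture(scope="session")
def small_proteome():
    """300 uniform-composition proteins, enough for stable bin statistics."""
    return sp.random_proteome(300, (100, 300), seed=11)


@pytest.fixture(scope="session")
def freq_binning(small_proteome):
    return sp.fit_bins([sp.aa_frequency(r) for r in small_proteome])


@pytest.fixture(scope="session")
def freq_profiles(small_proteome, freq_binning):
    return {
        r.id: sp.bin_profile(sp.aa_frequency(r), freq_binning) for r in small_proteome
    }


@pytest.fixture(scope="session")
def fp_schema():
    return sp.build_schema("Fp", sp.AMINO_ACIDS)


@pytest.fixture(scope="session")
def grouping_table():
    return sp.load_grouping_table()


@pytest.fixture(scope="session")
def planted_table(small_proteome, freq_binning):
    """400 + 400 pairs labeled by the default Asn-Asn rule, noise-free."""
    return sp.planted_interactome(
        small_proteome, sp.PlantedRule(), freq_binning, n_pos=400, n_neg=400, seed=7
    )


@pytest.fixture(scope="session")
def planted_encoded(planted_table, freq_profiles, fp_schema):
    return sp.encode_table(planted_table.data, freq_profiles, fp_schema)
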