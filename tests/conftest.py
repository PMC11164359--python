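import pytest

from mitocomp import SyntheticConfig, generate_genome, get_code

MINIMAL_GENBANK = """\
LOCUS       TEST1                     12 bp    DNA     circular INV 01-JAN-2024
DEFINITION  minimal hand-written record.
ACCESSION   TEST1
VERSION     TEST1.1
KEYWORDS    .
SOURCE      test organism
  ORGANISM  test organism
            Eukaryota.
FEATURES             Location/Qualifiers
     source          1..12
                     /organism="test organism"
     CDS             1..6
                     /gene="cox1"
     tRNA            complement(8..10)
                     /gene="tRNA-Met"
ORIGIN
        1 atgtaaacgt tt
//
"""


@pytest.fixture(scope="session")
def code():
    return get_code()


@pytest.fixture(scope="session")
def genome():
    """One seeded Formica-like synthetic genome shared across tests."""
    return generate_genome(SyntheticConfig(seed=1))


@pytest.fixture()
def minimal_gb(tmp_path):
    path = tmp_path / "minimal.gb"
    path.write_text(MINIMAL_GENBANK)
    return path
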