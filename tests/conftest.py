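from pathlib import Path

import pytest

from mirstar import read_fasta, read_vienna

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def ath_precursor():
    """The Arabidopsis MIR156a precursor (123 nt)."""
    return read_fasta(DATA_DIR / "ath_mir156a_precursor.fa")[0]


@pytest.fixture(scope="session")
def ath_mature():
    """The annotated ath-miR156a mature (22 nt)."""
    return read_fasta(DATA_DIR / "ath_mir156a_mature.fa")[0]


@pytest.fixture(scope="session")
def ath_vienna():
    """RNAfold structure of the MIR156a precursor (frozen output)."""
    return read_vienna(DATA_DIR / "ath_mir156a.vienna")[0]


@pytest.fixture
def data_dir():
    return DATA_DIR
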