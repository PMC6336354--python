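import numpy as np
import pytest

from idrkit.ssp import load_reference_library


@pytest.fixture(scope="session")
def library():
    return load_reference_library()


@pytest.fixture(scope="session")
def idr_sequence():
    # 60-residue disordered-tail-like sequence with no prolines in the
    # "helical" window so every residue there carries a full shift set
    return "GSDKTAEQLSRFAEKQLNDVTSMKAEDFFKQLLRSEGKTVADNQESLRKMTGEYAKQDSV"


@pytest.fixture(scope="session")
def helix_window():
    # residues (1-based positions) forming the transient helix in fixtures
    return slice(24, 35)
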