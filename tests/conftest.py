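import pytest

from etpath import BridgeDesign, make_bridge_structure, read_structure


@pytest.fixture(scope="session")
def bridge_default(tmp_path_factory):
    """Default valine-bridge fixture: (structure, truth), via the PDB reader."""
    pdb_text, truth = make_bridge_structure(BridgeDesign())
    path = tmp_path_factory.mktemp("bridge") / "bridge.pdb"
    path.write_text(pdb_text)
    return read_structure(str(path)), truth


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.770  -1.200  1.00  0.00           C
END
"""


@pytest.fixture()
def minimal_ala(tmp_path):
    path = tmp_path / "ala.pdb"
    path.write_text(MINIMAL_PDB)
    return read_structure(str(path))
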