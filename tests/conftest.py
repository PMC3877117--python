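import numpy as np
import pytest

from bcmoments import build_template_bank, compute_distance_matrix, make_helix, make_sheet


@pytest.fixture(scope="session")
def bank():
    return build_template_bank()


@pytest.fixture(scope="session")
def helix_dm():
    return compute_distance_matrix(make_helix(25))


@pytest.fixture(scope="session")
def hairpin_trace():
    return make_sheet(8, "antiparallel", loop_len=3)


@pytest.fixture(scope="session")
def parallel_trace():
    return make_sheet(8, "parallel", loop_len=20)


TOY_PDB = """\
ATOM      1  N   ALA A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture()
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


def separation_matrix(n: int) -> np.ndarray:
    idx = np.arange(n)
    return np.abs(np.subtract.outer(idx, idx))
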