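import numpy as np
import pytest

from dynasite.structmodel import Atom, Structure
from dynasite.synthetic_data import gen_toy_active_site, tyrosinase_fixtures


@pytest.fixture(scope="session")
def toy_site():
    return gen_toy_active_site()


@pytest.fixture(scope="session")
def fixtures():
    return tyrosinase_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_structure(spec, hetero=False):
    """Build a Structure from (name, element, resname, resseq, chain, xyz)."""
    atoms = [
        Atom(serial=i + 1, name=n, element=e, residue_name=rn,
             residue_seq=rs, chain=ch, position=tuple(xyz), is_hetero=hetero)
        for i, (n, e, rn, rs, ch, xyz) in enumerate(spec)
    ]
    return Structure(atoms)


SINGLE_MODEL_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   GLY A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.558   0.000   0.000  1.00  0.00           C
ENDMDL
END
"""

RAGGED_MODEL_PDB = """\
MODEL        1
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   GLY A   1       0.100   0.000   0.000  1.00  0.00           N
ENDMDL
END
"""

BAD_COORD_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.4x8   0.000   0.000  1.00  0.00           C
END
"""
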