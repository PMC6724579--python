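import numpy as np
import pytest

from structimm.structmodel import Atom, Chain, Complex, Residue
from structimm.synthdata import GrooveFixtureConfig, make_groove_fixture


@pytest.fixture(scope="session")
def groove():
    """Default synthetic two-helix groove holding LLFGYPVYV."""
    return make_groove_fixture(GrooveFixtureConfig(seed=0))


@pytest.fixture(scope="session")
def small_groove():
    """Smaller groove for the expensive refinement tests."""
    return make_groove_fixture(GrooveFixtureConfig(seed=1, helix_length=14))


def _toy_residue(aa, chain_id, seq_pos, offset, names_elements):
    atoms = [Atom(n, e, np.asarray(p, dtype=float) + offset)
             for n, e, p in names_elements]
    return Residue(aa, chain_id, seq_pos, atoms)


@pytest.fixture
def toy_peptide_complex():
    """A 9-residue glycine 'peptide' chain alone (no groove): every residue
    has the four backbone atoms, spaced along x."""
    residues = []
    for i in range(9):
        off = np.array([3.8 * i, 0.0, 0.0])
        residues.append(_toy_residue("G", "C", i + 1, off, [
            ("N", "N", (0.0, 0.0, 0.0)),
            ("CA", "C", (1.46, 0.0, 0.0)),
            ("C", "C", (2.2, 1.3, 0.0)),
            ("O", "O", (2.2, 2.53, 0.0)),
        ]))
    return Complex([Chain("C", residues)], peptide_chain_id="C")
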