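import numpy as np
import pytest

from phscreen.conf_change import Atom, ResidueId, StructureSnapshot


@pytest.fixture
def one_atom_reference():
    """A single 1-atom residue, for direct RMSD arithmetic."""
    rid = ResidueId(chain="A", number=1, name="GLY")
    return StructureSnapshot(residues={rid: {"CA": Atom("CA", "C", (0.0, 0.0, 0.0))}})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
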