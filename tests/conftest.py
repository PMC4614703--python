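import numpy as np
import pytest

from flavoscore.fixtures import (
    LigandAtomSpec,
    ResidueSpec,
    StructureSpec,
    make_synthetic_structure,
)
from flavoscore.structure import load_structure


@pytest.fixture
def load_spec(tmp_path):
    """Write a StructureSpec to a PDB file and load it back."""

    def _load(spec, chain=None, altloc_residues=(), name="fixture.pdb"):
        path = tmp_path / name
        path.write_text(make_synthetic_structure(spec, altloc_residues))
        return load_structure(path, chain or spec.chain)

    return _load


@pytest.fixture
def three_residue_spec():
    """Three Cα atoms on the x axis, FMN at 5 Å from residue 1, SF4 further."""
    return StructureSpec(
        residues=(
            ResidueSpec(1, 0.0, 0.0, 0.0),
            ResidueSpec(2, 3.8, 0.0, 0.0),
            ResidueSpec(3, 7.6, 0.0, 0.0),
        ),
        ligand_atoms=(
            LigandAtomSpec("FMN", "C1", 5.0, 0.0, 0.0),
            LigandAtomSpec("SF4", "FE1", 0.0, 12.0, 0.0, element="FE",
                           res_num=902),
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
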