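import numpy as np
import pytest

from latticepocket.pocket_profiler import PocketDefinition
from latticepocket.structure_model import (
    Atom,
    CrystalStructure,
    Residue,
    UnitCell,
    space_group_symops,
)
from latticepocket.synthetic_data import make_toy_lattice


@pytest.fixture(scope="session")
def guest_fixture():
    """P212121 toy lattice with a planted symmetry-mate leucine guest."""
    return make_toy_lattice("P212121", plant_guest=True, seed=1)


@pytest.fixture(scope="session")
def empty_pocket_fixture():
    """P1 toy lattice with no guest and the gate in the closed rotamer."""
    return make_toy_lattice("P1", plant_guest=False, seed=3)


@pytest.fixture(scope="session")
def plk1_pocket():
    return PocketDefinition.plk1_default()


def single_atom_structure(cell: UnitCell, frac, space_group: str = "P 1"):
    """One carbon pseudo-residue at a fractional position."""
    orth = cell.orth_matrix @ np.asarray(frac, dtype=float)
    res = Residue("A", 1, "ALA", [Atom.from_orth("CB", "C", orth, cell)])
    return CrystalStructure("one", cell, space_group_symops(space_group),
                            {"A": [res]}, space_group=space_group)


def cloud_structure(n: int, cell: UnitCell, rng, space_group: str = "P 1"):
    """n single-carbon residues uniformly distributed over the cell."""
    residues = []
    for i in range(n):
        frac = rng.uniform(0.0, 1.0, size=3)
        orth = cell.orth_matrix @ frac
        residues.append(Residue("A", i + 1, "ALA",
                                [Atom.from_orth("CB", "C", orth, cell)]))
    return CrystalStructure("cloud", cell, space_group_symops(space_group),
                            {"A": residues}, space_group=space_group)
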