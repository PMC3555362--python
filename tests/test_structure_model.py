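import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latticepocket.structure_model import (
    SpaceGroupError,
    StructureError,
    SymOp,
    UnitCell,
    apply_symop,
    fractionalize,
    orthogonalize,
    read_structure,
    space_group_symops,
)


# ---------------------------------------------------------------------------
# Unit cell and coordinate transforms
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("params", [
    (0.0, 10, 10, 90, 90, 90),
    (10, 10, 10, 0.0, 90, 90),
    (10, 10, 10, 90, 180.0, 90),
    (10, 10, 10, 170, 170, 170),      # non-positive metric determinant
])
def test_invalid_cells_rejected(params):
    with pytest.raises(ValueError):
        UnitCell(*params)


def test_orthogonalization_convention():
    cell = UnitCell(10, 10, 10)
    assert np.allclose(orthogonalize([0, 0, 0], cell), [0, 0, 0])
    assert np.allclose(orthogonalize([1, 0, 0], cell), [10, 0, 0])
    # a along x: the b axis of an oblique cell acquires a y component
    mono = UnitCell(10, 12, 14, 90, 105, 90)
    b_axis = orthogonalize([0, 1, 0], mono)
    assert b_axis[0] == pytest.approx(0.0, abs=1e-12)
    assert b_axis[1] == pytest.approx(12.0)


@settings(derandomize=True, max_examples=60)
@given(
    edges=st.tuples(*[st.floats(5, 200) for _ in range(3)]),
    angles=st.tuples(*[st.floats(60, 120) for _ in range(3)]),
    data=st.data(),
)
def test_frac_orth_round_trip(edges, angles, data):
    """fractionalize(orthogonalize(p)) = p to 1e-9 for random valid cells."""
    try:
        cell = UnitCell(*edges, *angles)
    except ValueError:
        return  # degenerate angle combination
    pts = np.array(data.draw(
        st.lists(st.tuples(*[st.floats(-3, 3) for _ in range(3)]),
                 min_size=1, max_size=20)))
    back = fractionalize(orthogonalize(pts, cell), cell)
    assert np.max(np.abs(back - pts)) < 1e-9


def test_round_trip_bulk_random_cells():
    rng = np.random.default_rng(11)
    for _ in range(100):
        cell = UnitCell(*rng.uniform(10, 150, 3), *rng.uniform(70, 110, 3))
        pts = rng.uniform(-2, 2, size=(100, 3))
        back = fractionalize(orthogonalize(pts, cell), cell)
        assert np.max(np.abs(back - pts)) < 1e-9


# ---------------------------------------------------------------------------
# Symmetry operators
# ---------------------------------------------------------------------------


def test_apply_symop_examples():
    ident = SymOp.identity()
    assert np.allclose(apply_symop(ident, [0.1, 0.2, 0.3]), [0.1, 0.2, 0.3])
    op = SymOp.from_triplet("-x,y+1/2,-z+1/2")
    assert np.allclose(apply_symop(op, [0.1, 0.2, 0.3]), [-0.1, 0.7, 0.2])
    assert np.allclose(apply_symop(ident, [0.1, 0.2, 0.3], (1, 0, -1)),
                       [1.1, 0.2, -0.7])


def test_symop_inverse_round_trip():
    rng = np.random.default_rng(5)
    for op in space_group_symops("P 21 21 21"):
        inv = op.inverse()
        pts = rng.uniform(-1, 2, size=(100, 3))
        assert np.max(np.abs(inv.apply(op.apply(pts)) - pts)) < 1e-9


@pytest.mark.parametrize("symbol,n_ops", [
    ("P 1", 1), ("P1", 1), ("P 21", 2), ("P 21 21 21", 4),
    ("P212121", 4), ("P 43 21 2", 8), ("C 2", 4),
])
def test_space_group_operator_counts(symbol, n_ops):
    ops = space_group_symops(symbol)
    assert len(ops) == n_ops
    assert ops[0].is_identity()


def test_space_group_errors():
    with pytest.raises(SpaceGroupError, match="unknown space group"):
        space_group_symops("Q 9")
    with pytest.raises(SpaceGroupError, match="Sohncke"):
        space_group_symops("P -1")


@pytest.mark.parametrize("symbol", ["P 1", "P 21 21 21"])
def test_group_closure_mod_lattice(symbol):
    """g o h equals a stored operator modulo an integer lattice translation."""
    ops = space_group_symops(symbol)
    for g in ops:
        for h in ops:
            rot = g.rot @ h.rot
            trans = g.rot @ h.trans + g.trans
            matched = False
            for k in ops:
                if np.allclose(rot, k.rot):
                    diff = trans - k.trans
                    if np.allclose(diff, np.round(diff)):
                        matched = True
                        break
            assert matched, f"{g.triplet()} o {h.triplet()} not in group"


def test_triplet_formatting_round_trip():
    for op in space_group_symops("P 21 21 21"):
        assert SymOp.from_triplet(op.triplet()) == op


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

MINI_P1_PDB = """\
CRYST1   20.000   22.000   24.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.458   2.000   3.000  1.00  0.00           C
ATOM      3  N   GLY A   2       5.000   2.000   3.000  1.00  0.00           N
ATOM      4  CA  GLY A   2       6.458   2.000   3.000  1.00  0.00           C
ATOM      5  N   SER A   3       9.000   2.000   3.000  1.00  0.00           N
ATOM      6  CA  SER A   3      10.458   2.000   3.000  1.00  0.00           C
END
"""


def test_read_minimal_p1(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_P1_PDB)
    st = read_structure(path)
    assert len(st.symops) == 1
    assert [r.seq_num for r in st.chains["A"]] == [1, 2, 3]
    assert st.cell.parameters()[:3] == (20.0, 22.0, 24.0)


def test_read_p212121_resolves_four_ops(tmp_path):
    path = tmp_path / "ortho.pdb"
    path.write_text(MINI_P1_PDB.replace("P 1           1", "P 21 21 21    4"))
    st = read_structure(path)
    assert len(st.symops) == 4


def test_missing_cell_is_an_error(tmp_path):
    path = tmp_path / "nocryst.pdb"
    path.write_text("\n".join(MINI_P1_PDB.splitlines()[1:]) + "\n")
    with pytest.raises(StructureError, match="missing unit cell"):
        read_structure(path)


ALTLOC_PDB = """\
CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   TYR A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  TYR A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB ATYR A   1       2.000   1.400   0.000  0.70  0.00           C
ATOM      4  CB BTYR A   1       2.000  -1.400   0.000  0.30  0.00           C
END
"""


def test_altloc_default_keeps_highest_occupancy(tmp_path):
    path = tmp_path / "alt.pdb"
    path.write_text(ALTLOC_PDB)
    st = read_structure(path)
    res = st.get_residue("A", 1)
    cbs = [a for a in res.atoms if a.name == "CB"]
    assert len(cbs) == 1
    assert cbs[0].orth[1] == pytest.approx(1.4)  # the 0.70-occupancy conformer


def test_altloc_flag_retains_all_conformers(tmp_path):
    path = tmp_path / "alt.pdb"
    path.write_text(ALTLOC_PDB)
    st = read_structure(path, keep_altlocs=True)
    res = st.get_residue("A", 1)
    assert len([a for a in res.atoms if a.name == "CB"]) == 2


def test_write_read_round_trip(guest_fixture, tmp_path):
    """Writing then re-reading preserves atoms, numbering, cell, space group."""
    st = guest_fixture.structure
    path = tmp_path / "toy.pdb"
    st.write_pdb(path)
    st2 = read_structure(path)
    assert st2.n_atoms == st.n_atoms
    assert st2.space_group == st.space_group
    assert st2.cell.parameters() == pytest.approx(st.cell.parameters(), abs=5e-4)
    assert [r.seq_num for r in st2.chains["A"]] == [r.seq_num for r in st.chains["A"]]
    assert [r.res_name for r in st2.chains["A"]] == [r.res_name for r in st.chains["A"]]


def test_atom_bases_stay_synchronized(guest_fixture):
    st = guest_fixture.structure
    for atom in st.atoms():
        assert np.allclose(orthogonalize(atom.frac, st.cell), atom.orth, atol=1e-6)


def test_hydrogens_dropped(tmp_path):
    path = tmp_path / "h.pdb"
    path.write_text(MINI_P1_PDB.replace(
        "END",
        "ATOM      7  H   SER A   3       9.500   2.500   3.000  1.00  0.00"
        "           H\nEND"))
    st = read_structure(path)
    assert all(a.element != "H" for a in st.atoms())
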