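import math

import numpy as np
import pytest

from latticepocket.lattice_contacts import (
    CANDIDATE_BIOLOGICAL,
    CRYSTAL_CONTACT,
    InterfacePatch,
    LatticeError,
    classify_interface,
    compute_buried_area,
    expand_lattice,
    find_atomic_contacts,
    group_into_interfaces,
    shrake_rupley_sasa,
)
from latticepocket.structure_model import UnitCell
from latticepocket.synthetic_data import brute_force_images

from conftest import cloud_structure, single_atom_structure


# ---------------------------------------------------------------------------
# Lattice expansion
# ---------------------------------------------------------------------------


def test_isolated_atom_sees_no_mates_below_cell_edge():
    st = single_atom_structure(UnitCell(10, 10, 10), (0.5, 0.5, 0.5))
    assert expand_lattice(st, 9.9) == []


def test_cubic_face_neighbours():
    """An atom at the origin of a 10 A cubic P1 cell has 6 face-neighbour
    images at 10 A once the radius admits them."""
    st = single_atom_structure(UnitCell(10, 10, 10), (0.0, 0.0, 0.0))
    mates = expand_lattice(st, 10.5)
    assert len(mates) == 6
    shifts = sorted(m.lattice_shift for m in mates)
    assert shifts == sorted([(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                             (0, -1, 0), (0, 0, 1), (0, 0, -1)])
    for m in mates:
        assert np.linalg.norm(m.orth[0]) == pytest.approx(10.0)


def _brute_mate_keys(structure, radius, window=3):
    ref = structure.atom_table()["orth"]
    keys = set()
    for op_index, shift, orth in brute_force_images(structure, window):
        d = np.linalg.norm(ref[:, None, :] - orth[None, :, :], axis=2)
        if d.min() <= radius:
            keys.add((op_index, shift))
    return keys


@pytest.mark.parametrize("fixture_name", ["guest_fixture", "empty_pocket_fixture"])
def test_expansion_matches_brute_force_window(fixture_name, request):
    st = request.getfixturevalue(fixture_name).structure
    mates = expand_lattice(st, 5.0)
    assert {m.key for m in mates} == _brute_mate_keys(st, 5.0)


def test_expansion_monotone_in_radius(guest_fixture):
    st = guest_fixture.structure
    keys = [{m.key for m in expand_lattice(st, r)} for r in (3.0, 5.0, 8.0)]
    assert keys[0] <= keys[1] <= keys[2]


def test_mate_count_cap():
    st = single_atom_structure(UnitCell(10, 10, 10), (0.0, 0.0, 0.0))
    with pytest.raises(LatticeError, match="smaller radius"):
        expand_lattice(st, 40.0, max_mates=10)


def test_mates_do_not_mutate_reference(guest_fixture):
    st = guest_fixture.structure
    before = st.atom_table()["orth"].copy()
    for m in expand_lattice(st, 5.0):
        m.orth += 1.0
    assert np.array_equal(st.atom_table()["orth"], before)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------


def _two_atom_cloud(distance):
    cell = UnitCell(100, 100, 100)
    from latticepocket.structure_model import Atom, CrystalStructure, Residue, space_group_symops
    residues = [
        Residue("A", 1, "ALA", [Atom.from_orth("CB", "C", (50, 50, 50), cell)]),
        Residue("A", 2, "ALA", [Atom.from_orth("CB", "C", (50 + distance - 100, 50, 50), cell)]),
    ]
    return CrystalStructure("pair", cell, space_group_symops("P 1"),
                            {"A": residues}, space_group="P 1")


@pytest.mark.parametrize("distance,expected", [(4.4, 1), (4.6, 0)])
def test_contact_cutoff_threshold(distance, expected):
    # second atom re-enters at `distance` via the +a lattice translation
    st = _two_atom_cloud(distance)
    mates = expand_lattice(st, 6.0)
    contacts = [c for c in find_atomic_contacts(st, mates, 4.5)
                if c.ref_atom[1] == 1 and c.mate_atom[2] == 2]
    assert len(contacts) == expected
    if contacts:
        assert contacts[0].distance == pytest.approx(distance)


@pytest.mark.parametrize("seed", range(5))
def test_contacts_equal_all_pairs_oracle(seed):
    """k-d-tree contact search reproduces the O(N^2) double loop exactly."""
    rng = np.random.default_rng(seed)
    st = cloud_structure(300, UnitCell(25, 27, 29), rng)
    mates = expand_lattice(st, 4.5)
    got = {(c.mate_key, c.ref_index, c.mate_index)
           for c in find_atomic_contacts(st, mates, 4.5)}
    ref = st.atom_table()["orth"]
    expected = set()
    for mate in mates:
        for mi in range(len(mate.orth)):
            for ri in range(len(ref)):
                d = np.linalg.norm(ref[ri] - mate.orth[mi])
                if 0 < d <= 4.5:
                    expected.add((mate.key, ri, mi))
    assert got == expected


def test_contact_symmetry_under_role_exchange():
    """Pair (a, b) against mate at +a equals pair (b, a) at the -a mate."""
    rng = np.random.default_rng(7)
    st = cloud_structure(150, UnitCell(22, 22, 22), rng)
    mates = {m.lattice_shift: m for m in expand_lattice(st, 4.5)}
    plus = {(c.ref_index, c.mate_index)
            for c in find_atomic_contacts(st, [mates[(1, 0, 0)]], 4.5)}
    minus = {(c.mate_index, c.ref_index)
             for c in find_atomic_contacts(st, [mates[(-1, 0, 0)]], 4.5)}
    assert plus == minus


# ---------------------------------------------------------------------------
# SASA / BSA
# ---------------------------------------------------------------------------


def test_single_sphere_sasa_closed_form():
    r, w = 1.70, 1.4
    area = shrake_rupley_sasa([[0.0, 0, 0]], ["C"], w, 960)
    exact = 4 * math.pi * (r + w) ** 2
    assert abs(area - exact) / exact < 0.01


def test_two_sphere_bsa_closed_form():
    """BSA of two identical spheres equals twice the spherical-cap area."""
    r, w = 1.70, 1.4
    R = r + w
    for d in (2.0, 3.0, 4.0, 5.5):
        bsa = compute_buried_area([("C", (0, 0, 0))], [("C", (d, 0, 0))])
        exact = 2 * (2 * math.pi * R * (R - d / 2))
        assert abs(bsa - exact) / exact < 0.02, f"d={d}"


def test_distant_molecules_bury_nothing():
    bsa = compute_buried_area([("C", (0, 0, 0))], [("C", (50, 0, 0))])
    assert bsa < 1.0


def test_unknown_element_is_an_error():
    with pytest.raises(LatticeError, match="XX"):
        compute_buried_area([("XX", (0, 0, 0))], [("C", (3, 0, 0))])


def test_bsa_estimator_converges(guest_fixture):
    """Point-density refinement changes the area by < 5% on a synthetic dimer."""
    st = guest_fixture.structure
    mates = expand_lattice(st, 5.0)
    a = (st.atom_table()["orth"], st.atom_table()["element"])
    b = (mates[0].orth, mates[0].element)
    coarse = compute_buried_area(a, b, n_points=960)
    fine = compute_buried_area(a, b, n_points=3840)
    assert abs(coarse - fine) / max(coarse, 1.0) < 0.05


# ---------------------------------------------------------------------------
# Interface patches and classification
# ---------------------------------------------------------------------------


def _dummy_patch(bsa):
    return InterfacePatch(mate=None, contacts=[object()], residue_pairs=[], bsa=bsa)


@pytest.mark.parametrize("bsa,expected", [
    (120.0, CRYSTAL_CONTACT),
    (799.9, CRYSTAL_CONTACT),
    (800.0, CANDIDATE_BIOLOGICAL),   # boundary: >= rule
    (1500.0, CANDIDATE_BIOLOGICAL),
])
def test_classification_threshold(bsa, expected):
    assert classify_interface(_dummy_patch(bsa), 800.0) == expected


def test_grouping_partitions_contacts(guest_fixture):
    st = guest_fixture.structure
    mates = expand_lattice(st, 5.0)
    contacts = find_atomic_contacts(st, mates)
    patches = group_into_interfaces(contacts, st, mates, n_points=96)
    assert sum(p.n_contacts for p in patches) == len(contacts)
    assert len(patches) == len({c.mate_key for c in contacts})
    assert all(p.bsa > 0 for p in patches)


def test_empty_contacts_give_no_patches(guest_fixture):
    st = guest_fixture.structure
    assert group_into_interfaces([], st, []) == []


def test_planted_large_interface_is_the_only_biological_call():
    from latticepocket.synthetic_data import make_toy_lattice
    fx = make_toy_lattice("P212121", plant_guest=True, plant_large_interface=True,
                          seed=2)
    st = fx.structure
    mates = expand_lattice(st, 5.0)
    contacts = find_atomic_contacts(st, mates)
    patches = group_into_interfaces(contacts, st, mates, n_points=240)
    biological = {p.mate.key for p in patches if p.label == CANDIDATE_BIOLOGICAL}
    assert biological == fx.truth_interface_mates
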