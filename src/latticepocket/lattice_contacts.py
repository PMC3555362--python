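"""Lattice expansion, inter-protomer contacts and interface scoring.

Expands the asymmetric unit into the symmetry mates that touch it, finds
heavy-atom contacts between the reference protomer and each mate, scores
each interface patch by buried surface area (BSA) and labels it as a mere
crystal-packing contact or a candidate biological interface.

BSA is the standard SASA(A) + SASA(B) - SASA(A u B), computed with a
Shrake-Rupley numerical SASA on a deterministic golden-spiral point lattice
(no RNG), so repeated runs give bit-identical areas.  The default
crystal-vs-biological threshold of 800 A^2 follows the literature convention
for distinguishing packing contacts from physiological interfaces and is a
configurable heuristic, not a sharp physical boundary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from latticepocket.structure_model import Atom, CrystalStructure, SymOp

#: Van der Waals radii (Angstrom) for the heavy elements of proteins.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

DEFAULT_CONTACT_CUTOFF = 4.5    # A, heavy-atom van der Waals contact bound
DEFAULT_BSA_THRESHOLD = 800.0   # A^2, crystal-contact vs candidate-biological
DEFAULT_PROBE = 1.4             # A, water probe
DEFAULT_N_POINTS = 960

CRYSTAL_CONTACT = "crystal_contact"
CANDIDATE_BIOLOGICAL = "candidate_biological"


class LatticeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Symmetry mates
# ---------------------------------------------------------------------------


@dataclass
class SymmetryMate:
    """A transformed copy of the reference protomer adjacent to it.

    Atom coordinates are copies; transforming never mutates the parent.
    ``meta``/``sidechain``/``element`` are shared with the parent's flat atom
    table (the transform permutes nothing).
    """

    op_index: int
    op: SymOp
    lattice_shift: tuple[int, int, int]
    orth: np.ndarray
    meta: list[tuple[str, int, str, str]]
    sidechain: np.ndarray
    element: list[str]

    @property
    def label(self) -> str:
        return f"{self.op.triplet()} + {self.lattice_shift}"

    @property
    def key(self) -> tuple[int, tuple[int, int, int]]:
        return (self.op_index, self.lattice_shift)

    def __repr__(self) -> str:
        return f"<SymmetryMate {self.label}, {len(self.orth)} atoms>"


def expand_lattice(structure: CrystalStructure, radius: float, *,
                   max_mates: int = 2000) -> list[SymmetryMate]:
    """Enumerate symmetry mates with >= 1 atom within ``radius`` of the ASU.

    The lattice-shift window per axis is derived from the fractional bounding
    boxes of the reference and transformed copies plus a margin of
    ``radius`` converted with the row norms of the fractionalization matrix,
    so elongated and oblique cells are covered.  Ordering is deterministic:
    by operator index, then lexicographic lattice shift.  The identity
    operator with zero shift (the reference itself) is never emitted.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    table = structure.atom_table()
    ref_orth, ref_frac = table["orth"], table["frac"]
    if len(ref_orth) == 0:
        return []
    cell = structure.cell
    tree = cKDTree(ref_orth)
    margins = radius * np.linalg.norm(cell.frac_matrix, axis=1)
    ref_lo, ref_hi = ref_frac.min(axis=0), ref_frac.max(axis=0)

    mates: list[SymmetryMate] = []
    for op_index, op in enumerate(structure.symops):
        tfrac = ref_frac @ op.rot.T + op.trans
        t_lo, t_hi = tfrac.min(axis=0), tfrac.max(axis=0)
        lo = np.floor(ref_lo - t_hi - margins).astype(int)
        hi = np.ceil(ref_hi - t_lo + margins).astype(int)
        shifts = itertools.product(*(range(lo[i], hi[i] + 1) for i in range(3)))
        for shift in shifts:
            if op_index == 0 and shift == (0, 0, 0) and op.is_identity():
                continue
            orth = (tfrac + np.asarray(shift, dtype=float)) @ cell.orth_matrix.T
            d, _ = tree.query(orth, k=1, distance_upper_bound=radius)
            if not np.any(np.isfinite(d)):
                continue
            mates.append(SymmetryMate(op_index, op, tuple(shift), orth,
                                      table["meta"], table["sidechain"],
                                      table["element"]))
            if len(mates) > max_mates:
                raise LatticeError(
                    f"more than {max_mates} symmetry mates within {radius} A; "
                    "use a smaller radius (or raise max_mates)"
                )
    return mates


# ---------------------------------------------------------------------------
# Atomic contacts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contact:
    """One heavy-atom pair across an interface, within the contact cutoff."""

    ref_atom: tuple[str, int, str]              # (chain, seq_num, atom name)
    mate_atom: tuple[str, str, int, str]        # (mate label, chain, seq_num, atom name)
    distance: float
    ref_index: int = 0
    mate_index: int = 0
    mate_key: tuple = ()


def find_atomic_contacts(structure: CrystalStructure, mates: Sequence[SymmetryMate],
                         cutoff: float = DEFAULT_CONTACT_CUTOFF) -> list[Contact]:
    """All heavy-atom pairs (reference atom, mate atom) within ``cutoff``.

    Neighbor search uses a k-d tree; the result is contractually identical to
    the all-pairs double loop (tested against it).  Each pair is reported
    once, ordered by mate, then reference atom index, then mate atom index.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    table = structure.atom_table()
    ref_orth, meta = table["orth"], table["meta"]
    if len(ref_orth) == 0:
        return []
    tree = cKDTree(ref_orth)
    contacts: list[Contact] = []
    for mate in mates:
        label = mate.label
        hits = tree.query_ball_point(mate.orth, r=cutoff)
        pairs = [(ri, mi) for mi, refs in enumerate(hits) for ri in refs]
        pairs.sort()
        for ri, mi in pairs:
            dist = float(np.linalg.norm(ref_orth[ri] - mate.orth[mi]))
            if dist == 0.0:
                continue  # coincident atoms are a degenerate input, not a contact
            rc, rs, _, ra = meta[ri]
            mc, ms, _, ma = mate.meta[mi]
            contacts.append(Contact((rc, rs, ra), (label, mc, ms, ma), dist,
                                    ref_index=ri, mate_index=mi, mate_key=mate.key))
    return contacts


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA and buried area
# ---------------------------------------------------------------------------


def _golden_spiral(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _radii_for(elements: Iterable[str]) -> np.ndarray:
    radii = []
    for el in elements:
        r = VDW_RADII.get(el.upper())
        if r is None:
            raise LatticeError(f"no van der Waals radius for element {el!r}")
        radii.append(r)
    return np.array(radii)


def shrake_rupley_sasa(coords: np.ndarray, elements: Sequence[str],
                       probe: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_N_POINTS) -> float:
    """Total solvent-accessible surface area (A^2) of a heavy-atom set."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = _radii_for(elements) + probe
    if len(coords) == 0:
        return 0.0
    sphere = _golden_spiral(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    total = 0.0
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], radii[i] + rmax):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= radii[j] ** 2
        total += 4.0 * math.pi * radii[i] ** 2 * accessible.mean()
    return float(total)


def _as_coords_elements(atoms) -> tuple[np.ndarray, list[str]]:
    """Accept a list of Atom objects or (element, xyz) pairs, or a pair of arrays."""
    if isinstance(atoms, tuple) and len(atoms) == 2 and not isinstance(atoms[0], str):
        coords, elements = atoms
        return np.asarray(coords, dtype=float).reshape(-1, 3), list(elements)
    coords, elements = [], []
    for a in atoms:
        if isinstance(a, Atom):
            coords.append(a.orth)
            elements.append(a.element)
        else:
            el, xyz = a
            coords.append(xyz)
            elements.append(el)
    return np.asarray(coords, dtype=float).reshape(-1, 3), elements


def compute_buried_area(ref_atoms, mate_atoms, probe: float = DEFAULT_PROBE,
                        n_points: int = DEFAULT_N_POINTS) -> float:
    """Interface buried area: SASA(A) + SASA(B) - SASA(A u B), in A^2.

    ``ref_atoms``/``mate_atoms`` may be Atom lists, (element, xyz) pairs, or
    a ``(coords, elements)`` tuple.  Requires ``n_points >= 92`` for a usable
    point density; clamps small negative Monte-Carlo-style noise to 0.
    """
    if probe <= 0:
        raise ValueError(f"probe must be positive, got {probe}")
    if n_points < 92:
        raise ValueError(f"n_points must be >= 92, got {n_points}")
    ca, ea = _as_coords_elements(ref_atoms)
    cb, eb = _as_coords_elements(mate_atoms)
    if len(ca) == 0 or len(cb) == 0:
        return 0.0
    sasa_a = shrake_rupley_sasa(ca, ea, probe, n_points)
    sasa_b = shrake_rupley_sasa(cb, eb, probe, n_points)
    sasa_ab = shrake_rupley_sasa(np.vstack([ca, cb]), ea + eb, probe, n_points)
    return max(0.0, sasa_a + sasa_b - sasa_ab)


# ---------------------------------------------------------------------------
# Interface patches
# ---------------------------------------------------------------------------


@dataclass
class InterfacePatch:
    """All contacts between the reference protomer and one symmetry mate."""

    mate: SymmetryMate
    contacts: list[Contact]
    residue_pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    bsa: float
    label: str = CRYSTAL_CONTACT

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)


def classify_interface(patch: InterfacePatch,
                       threshold: float = DEFAULT_BSA_THRESHOLD) -> str:
    """Label a patch: below ``threshold`` A^2 buried -> crystal contact."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    label = CRYSTAL_CONTACT if patch.bsa < threshold else CANDIDATE_BIOLOGICAL
    patch.label = label
    return label


def group_into_interfaces(contacts: Sequence[Contact], structure: CrystalStructure,
                          mates: Sequence[SymmetryMate], *,
                          probe: float = DEFAULT_PROBE,
                          n_points: int = DEFAULT_N_POINTS,
                          bsa_threshold: float = DEFAULT_BSA_THRESHOLD
                          ) -> list[InterfacePatch]:
    """One patch per mate with >= 1 contact; BSA over the two whole protomers."""
    by_mate: dict[tuple, list[Contact]] = {}
    for c in contacts:
        by_mate.setdefault(c.mate_key, []).append(c)
    table = structure.atom_table()
    ref = (table["orth"], table["element"])
    patches: list[InterfacePatch] = []
    for mate in mates:
        clist = by_mate.get(mate.key)
        if not clist:
            continue
        pairs = sorted({((c.ref_atom[0], c.ref_atom[1]),
                         (c.mate_atom[1], c.mate_atom[2])) for c in clist})
        bsa = compute_buried_area(ref, (mate.orth, mate.element), probe, n_points)
        patch = InterfacePatch(mate, clist, pairs, bsa)
        classify_interface(patch, bsa_threshold)
        patches.append(patch)
    return patches
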