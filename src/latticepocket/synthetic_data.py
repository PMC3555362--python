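"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Two generators:

* :func:`make_toy_lattice` builds a ~30-residue mock protomer carrying a
  seven-residue pocket (3 bottom + 4 side residues with full side chains,
  numbered like the Plk1 polo-box-domain site) inside a chiral space group,
  and *solves* the placement of one leucine so that a symmetry mate presents
  its side chain into the pocket -- emulating a guest-donating crystal
  contact.  Optionally a pair of flat residue walls is added so one lattice
  neighbour buries enough area to cross the biological-interface threshold.

* :func:`make_sequence_db` builds a phosphosite-annotated FASTA-style decoy
  database with motif instances planted at known positions; decoys are
  rejection-filtered with a brute-force scanner so they contain no match
  even if every S/T were phosphorylated.

Every fixture is verified against an independent brute-force oracle (plain
double loops, no spatial indexing, no pattern engine) before it is returned;
a fixture that fails its own truth check raises instead of being emitted.
The same oracles are exported for use in equivalence tests.

Geometry is idealized (template bond lengths/angles, no energies); fixtures
are geometric test articles, not physically realistic proteins.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from latticepocket._geom import place_atom, rotation_about, rotation_aligning
from latticepocket.motif_search import PhosphoSequence
from latticepocket.structure_model import (
    Atom,
    CrystalStructure,
    Residue,
    SymOp,
    UnitCell,
    space_group_symops,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Idealized residue templates (internal-coordinate construction)
# ---------------------------------------------------------------------------


def _element_of(name: str) -> str:
    return name[0] if name[0] in "NOS" else "C"


def build_residue_template(res_name: str, chi1: float = -65.0,
                           chi2: float | None = None) -> list[tuple[str, np.ndarray]]:
    """Heavy atoms of one residue in a local frame, with exact chi angles.

    chi1 (N-CA-CB-G) and chi2 are imposed by internal-coordinate placement,
    so the returned geometry reproduces them to machine precision.
    """
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = ca + 1.525 * np.array([math.cos(math.radians(69.0)),
                               math.sin(math.radians(69.0)), 0.0])
    o = place_atom(n, ca, c, 1.231, 120.5, 180.0)
    atoms = [("N", n), ("CA", ca), ("C", c), ("O", o)]
    if res_name == "GLY":
        return atoms
    cb = place_atom(c, n, ca, 1.53, 110.4, -122.0)
    atoms.append(("CB", cb))
    if res_name == "ALA":
        return atoms

    if chi2 is None:
        chi2 = {"TYR": 90.0, "PHE": 90.0, "LEU": 65.0, "PRO": -30.0}.get(res_name, 180.0)

    if res_name == "VAL":
        atoms.append(("CG1", place_atom(n, ca, cb, 1.52, 111.0, chi1)))
        atoms.append(("CG2", place_atom(n, ca, cb, 1.52, 111.0, chi1 - 122.0)))
    elif res_name == "LEU":
        cg = place_atom(n, ca, cb, 1.53, 116.3, chi1)
        atoms.append(("CG", cg))
        atoms.append(("CD1", place_atom(ca, cb, cg, 1.52, 110.7, chi2)))
        atoms.append(("CD2", place_atom(ca, cb, cg, 1.52, 110.7, chi2 + 122.0)))
    elif res_name == "PRO":
        cg = place_atom(n, ca, cb, 1.49, 104.5, chi1)
        atoms.append(("CG", cg))
        atoms.append(("CD", place_atom(ca, cb, cg, 1.50, 106.1, chi2)))
    elif res_name in ("PHE", "TYR"):
        cg = place_atom(n, ca, cb, 1.51, 113.8, chi1)
        cd1 = place_atom(ca, cb, cg, 1.39, 120.8, chi2)
        cd2 = place_atom(ca, cb, cg, 1.39, 120.8, chi2 + 180.0)
        ce1 = place_atom(cb, cg, cd1, 1.39, 120.0, 180.0)
        ce2 = place_atom(cb, cg, cd2, 1.39, 120.0, 180.0)
        cz = place_atom(cg, cd1, ce1, 1.39, 120.0, 0.0)
        atoms += [("CG", cg), ("CD1", cd1), ("CD2", cd2),
                  ("CE1", ce1), ("CE2", ce2), ("CZ", cz)]
        if res_name == "TYR":
            atoms.append(("OH", place_atom(cd1, ce1, cz, 1.38, 120.0, 180.0)))
    else:
        raise SyntheticError(f"no template for residue {res_name!r}")
    return atoms


def _place_template(atoms: list[tuple[str, np.ndarray]], tip_name: str,
                    tip_target: np.ndarray, direction: np.ndarray,
                    roll_deg: float = 0.0) -> dict[str, np.ndarray]:
    """Rigidly place a template so CA->tip points along ``direction`` and the
    tip atom lands on ``tip_target``; then roll about that axis."""
    lookup = dict(atoms)
    ca, tip = lookup["CA"], lookup[tip_name]
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    rot = rotation_aligning(tip - ca, direction)
    if roll_deg:
        rot = rotation_about(direction, roll_deg) @ rot
    return {name: rot @ (xyz - tip) + tip_target for name, xyz in atoms}


def _residue_from_coords(chain: str, seq: int, res_name: str,
                         coords: dict[str, np.ndarray], cell: UnitCell) -> Residue:
    atoms = [Atom.from_orth(name, _element_of(name), xyz, cell)
             for name, xyz in coords.items()]
    return Residue(chain, seq, res_name, atoms)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the k-d-tree / pattern-engine paths)
# ---------------------------------------------------------------------------


def brute_force_images(structure: CrystalStructure, window: int = 2):
    """Yield (op_index, shift, orth_coords) for every non-reference image in
    a fixed [-window, window]^3 lattice-shift block."""
    table = structure.atom_table()
    frac = table["frac"]
    m = structure.cell.orth_matrix
    for op_index, op in enumerate(structure.symops):
        tfrac = frac @ op.rot.T + op.trans
        for shift in itertools.product(range(-window, window + 1), repeat=3):
            if op_index == 0 and shift == (0, 0, 0):
                continue
            yield op_index, shift, (tfrac + np.asarray(shift, dtype=float)) @ m.T


def _bbox_gap_exceeds(a: np.ndarray, b: np.ndarray, cutoff: float) -> bool:
    return bool(np.any(b.min(axis=0) - a.max(axis=0) > cutoff) or
                np.any(a.min(axis=0) - b.max(axis=0) > cutoff))


def brute_force_contact_pairs(structure: CrystalStructure, cutoff: float = 4.5,
                              window: int = 2) -> set:
    """Residue-level contact pairs ((ref chain, seq), (op, shift, chain, seq))
    by exhaustive all-pairs distance testing."""
    table = structure.atom_table()
    ref = table["orth"]
    meta = table["meta"]
    pairs = set()
    for op_index, shift, orth in brute_force_images(structure, window):
        if _bbox_gap_exceeds(ref, orth, cutoff):
            continue
        d = np.linalg.norm(ref[:, None, :] - orth[None, :, :], axis=2)
        for ri, mi in zip(*np.nonzero((d <= cutoff) & (d > 0))):
            rc, rs, _, _ = meta[ri]
            mc, ms, _, _ = meta[mi]
            pairs.add(((rc, rs), (op_index, shift, mc, ms)))
    return pairs


def brute_force_guests(structure: CrystalStructure, pocket_keys: Sequence[tuple[str, int]],
                       cutoff: float = 4.5, min_pocket_residues: int = 3,
                       window: int = 2) -> set:
    """Symmetry-image residues whose side chain touches side chains of >=
    ``min_pocket_residues`` distinct pocket residues; exhaustive search."""
    table = structure.atom_table()
    meta = table["meta"]
    side = table["sidechain"]
    pocket_keys = set(pocket_keys)
    pocket_coords = []
    for key in sorted(pocket_keys):
        idx = [i for i, (c, s, _, _) in enumerate(meta)
               if (c, s) == key and side[i]]
        pocket_coords.append(table["orth"][idx])
    guests = set()
    all_pocket = np.vstack(pocket_coords)
    for op_index, shift, orth in brute_force_images(structure, window):
        if _bbox_gap_exceeds(all_pocket, orth, cutoff):
            continue
        groups: dict[tuple, list[int]] = {}
        for i, (c, s, rn, _) in enumerate(meta):
            if side[i]:
                groups.setdefault((c, s, rn), []).append(i)
        for (c, s, rn), idx in groups.items():
            coords = orth[idx]
            n_touch = 0
            for pc in pocket_coords:
                d = np.linalg.norm(coords[:, None, :] - pc[None, :, :], axis=2)
                if d.min() <= cutoff:
                    n_touch += 1
            if n_touch >= min_pocket_residues:
                guests.add((op_index, shift, c, s, rn))
    return guests


def brute_force_default_scan(sequence: str, phospho_positions: set[int]
                             ) -> set[tuple[int, int, int]]:
    """All (phi_pos, spacer_len, phospho_pos) matches of the default motif
    (Phi in {F, L}; 0-3 spacers; consensus X, X, S, p[S/T]) by raw window
    enumeration -- deliberately free of the pattern engine."""
    s = sequence.upper()
    hits = set()
    for phi in range(1, len(s) + 1):
        if s[phi - 1] not in "FL":
            continue
        for spacer in range(0, 4):
            p3 = phi + spacer + 3   # the fixed S of the consensus
            p4 = phi + spacer + 4   # the phospho anchor
            if p4 > len(s):
                continue
            if s[p3 - 1] == "S" and s[p4 - 1] in "ST" and p4 in phospho_positions:
                hits.add((phi, spacer, p4))
    return hits


# ---------------------------------------------------------------------------
# Toy crystal lattice
# ---------------------------------------------------------------------------

#: (seq_num, res_name, role); numbering mirrors the Plk1 pocket.
POCKET_RESIDUE_SPEC = [
    (415, "VAL", "bottom"), (417, "TYR", "side"), (421, "TYR", "side"),
    (478, "LEU", "bottom"), (481, "TYR", "side"), (482, "PHE", "bottom"),
    (485, "TYR", "side"),
]

_TIP = {"VAL": "CG1", "LEU": "CD1", "PHE": "CZ", "TYR": "CZ", "ALA": "CB"}

_SUPPORTED_SG = {"P 1", "P 1 21 1", "P 21 21 21"}


@dataclass
class LatticeFixture:
    """A toy lattice plus construction-time ground truth."""

    structure: CrystalStructure
    truth_contacts: set
    truth_guest: tuple | None                 # (op_index, shift, chain, seq, res_name)
    truth_interface_mates: set                # mate keys planted as large interfaces
    seed: int
    params: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.structure.write_pdb(out / "structure.pdb")
        truth = {
            "truth_guest": list(self.truth_guest) if self.truth_guest else None,
            "truth_interface_mates": sorted(map(list, self.truth_interface_mates)),
            "n_truth_contacts": len(self.truth_contacts),
            "seed": self.seed,
            "params": self.params,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1, default=list))
        return out / "structure.pdb"


def _default_cell(sg_hm: str, rng: np.random.Generator) -> UnitCell:
    jit = rng.uniform(-1.5, 1.5, size=3)
    a, b, c = 46.0 + jit[0], 50.0 + jit[1], 54.0 + jit[2]
    return UnitCell(a, b, c, 90.0, 90.0, 90.0)


def make_toy_lattice(space_group: str = "P 21 21 21", cell: UnitCell | None = None,
                     plant_guest: bool = True, plant_large_interface: bool = False,
                     seed: int = 0, *, guest_tip_distance: float = 4.0,
                     n_fillers: int = 20, tyr481_chi1: float = -65.0
                     ) -> LatticeFixture:
    """Build a toy crystal with a mock seven-residue pocket.

    When ``plant_guest`` is set, a leucine (numbered 394, echoing the donated
    loop residue of the real system) is positioned so that under one
    space-group operator + lattice translation its side chain lands tip-first
    in the pocket, touching all seven pocket side chains; feasibility is
    established by trying candidate (operator, shift) images and the result
    is verified with the exhaustive contact oracle before the fixture is
    returned.  ``plant_large_interface`` adds two complementary residue walls
    at opposite cell faces so that the +/-a translated neighbours bury a
    large contact area.  Same seed and parameters -> byte-identical files.
    """
    ops = space_group_symops(space_group)
    import gemmi
    sg_obj = gemmi.find_spacegroup_by_name(space_group)
    hm = sg_obj.hm if sg_obj else space_group
    if hm not in _SUPPORTED_SG:
        raise SyntheticError(
            f"unsupported space group {space_group!r}; pick one of P1, P21, P212121"
        )
    rng = np.random.default_rng(seed)
    if cell is None:
        cell = _default_cell(hm, rng)

    center = cell.orth_matrix @ np.array([0.5, 0.5, 0.5])
    chain = "A"
    residues: list[Residue] = []

    # --- pocket: bottom residues point up from below, sides ring the equator
    bottom_dirs = [_unit(145.0, az) for az in (0.0, 120.0, 240.0)]
    side_dirs = [_unit(90.0, az) for az in (40.0, 130.0, 220.0, 310.0)]
    b_i = s_i = 0
    pocket_keys = []
    for seq, res_name, role in POCKET_RESIDUE_SPEC:
        if role == "bottom":
            u = bottom_dirs[b_i]; b_i += 1
        else:
            u = side_dirs[s_i]; s_i += 1
        chi1 = tyr481_chi1 if seq == 481 else -65.0
        tpl = build_residue_template(res_name, chi1=chi1)
        roll = float(rng.uniform(-15.0, 15.0))
        tip_r = guest_tip_distance + float(rng.uniform(-0.1, 0.1))
        coords = _place_template(tpl, _TIP[res_name], center + tip_r * u, -u, roll)
        residues.append(_residue_from_coords(chain, seq, res_name, coords, cell))
        pocket_keys.append((chain, seq))

    # --- filler ring well away from the pocket
    for i in range(n_fillers):
        az = 360.0 * i / n_fillers
        u = _unit(120.0, az)
        r = 14.0 + float(rng.uniform(-1.0, 1.0))
        tpl = build_residue_template("ALA")
        coords = _place_template(tpl, "CB", center + r * u, u,
                                 float(rng.uniform(-180.0, 180.0)))
        residues.append(_residue_from_coords(chain, 301 + i, "ALA", coords, cell))

    wall_mates: set = set()
    if plant_large_interface:
        wall_rows, wall_cols, spacing = 6, 5, 4.2
        seq = 601
        for x_orth, outward in ((2.0, np.array([1.0, 0, 0])),
                                (cell.a - 2.0, np.array([-1.0, 0, 0]))):
            for i in range(wall_rows):
                for j in range(wall_cols):
                    y = center[1] + (i - (wall_rows - 1) / 2) * spacing
                    z = center[2] + (j - (wall_cols - 1) / 2) * spacing
                    tpl = build_residue_template("ALA")
                    coords = _place_template(tpl, "CB",
                                             np.array([x_orth, y, z]) + 1.5 * (-outward),
                                             -outward, 0.0)
                    residues.append(_residue_from_coords(chain, seq, "ALA", coords, cell))
                    seq += 1
        wall_mates = {(0, (-1, 0, 0)), (0, (1, 0, 0))}

    base = {r.seq_num: r for r in residues}

    def build_structure(extra: list[Residue]) -> CrystalStructure:
        ordered = sorted(list(base.values()) + extra, key=lambda r: r.seq_num)
        return CrystalStructure("toy", cell, ops, {chain: ordered},
                                peptides=(), space_group=hm)

    truth_guest = None
    guest_extra: list[Residue] = []
    if plant_guest:
        # guest template approaching tip-first from above the pocket
        tpl = build_residue_template("LEU", chi1=-60.0, chi2=65.0)
        target_coords = _place_template(tpl, "CD1", center, np.array([0.0, 0, -1.0]),
                                        float(rng.uniform(-180.0, 180.0)))
        t_frac = {n: np.asarray(cell.frac_matrix @ xyz)
                  for n, xyz in target_coords.items()}
        candidates = _guest_candidates(ops)
        placed = False
        for op_index, shift in candidates:
            inv = ops[op_index].inverse()
            home = {n: cell.orth_matrix @ inv.apply(f - np.asarray(shift, dtype=float))
                    for n, f in t_frac.items()}
            guest = _residue_from_coords(chain, 394, "LEU", home, cell)
            # keep the guest's home copy clear of everything already placed
            protomer_coords = np.array([a.orth for r in base.values() for a in r.atoms])
            gcoords = np.array([a.orth for a in guest.atoms])
            if np.linalg.norm(protomer_coords[:, None, :] - gcoords[None, :, :],
                              axis=2).min() < 6.0:
                continue
            st = build_structure([guest])
            found = brute_force_guests(st, pocket_keys)
            expected = (op_index, shift, chain, 394, "LEU")
            if found == {expected}:
                truth_guest = expected
                guest_extra = [guest]
                placed = True
                break
        if not placed:
            raise SyntheticError(
                "could not place a symmetry-mate guest without clashes; "
                "try a larger cell"
            )

    structure = build_structure(guest_extra)
    if not plant_guest:
        found = brute_force_guests(structure, pocket_keys)
        if found:
            raise SyntheticError(f"unplanted fixture has accidental guests: {found}")
    truth_contacts = brute_force_contact_pairs(structure)
    params = {
        "space_group": hm, "cell": cell.parameters(),
        "plant_guest": plant_guest, "plant_large_interface": plant_large_interface,
        "guest_tip_distance": guest_tip_distance, "n_fillers": n_fillers,
        "tyr481_chi1": tyr481_chi1,
    }
    return LatticeFixture(structure, truth_contacts, truth_guest, wall_mates,
                          seed, params)


def _unit(polar_deg: float, az_deg: float) -> np.ndarray:
    p, a = math.radians(polar_deg), math.radians(az_deg)
    return np.array([math.sin(p) * math.cos(a), math.sin(p) * math.sin(a), math.cos(p)])


def _guest_candidates(ops: Sequence[SymOp]) -> list[tuple[int, tuple[int, int, int]]]:
    """Deterministic (op_index, shift) trial order: non-identity ops first
    with small shifts, then pure lattice translations."""
    shifts = sorted(itertools.product((-1, 0, 1), repeat=3),
                    key=lambda s: (sum(abs(x) for x in s), s))
    out = []
    for op_index in range(1, len(ops)):
        for shift in shifts:
            out.append((op_index, shift))
    for shift in shifts:
        if shift != (0, 0, 0):
            out.append((0, shift))
    return out


# ---------------------------------------------------------------------------
# Sequence database
# ---------------------------------------------------------------------------

#: Printed match contexts of the two screen positives, with the phospho
#: anchor at local position 8 (pThr78 of PBIP1; pSer106 of TCERG1).
PLANTED_PBIP1 = PhosphoSequence("PBIP1_frag", "FDPPLHSTA", frozenset({8}))
PLANTED_TCERG1 = PhosphoSequence("TCERG1_frag", "FMPPPMSSM", frozenset({8}))


@dataclass
class SequenceDbFixture:
    """A decoy database with planted motif instances and their coordinates."""

    db: list[PhosphoSequence]
    truth_hits: set[tuple[str, int, int]]      # (protein_id, phi_pos, phospho_pos)
    seed: int
    params: dict = field(default_factory=dict)

    def write_fasta(self, path: str | Path) -> None:
        """FASTA with lower-case letters at annotated phosphosites."""
        with open(path, "w") as fh:
            for seq in self.db:
                chars = list(seq.sequence)
                for p in seq.phospho_positions:
                    chars[p - 1] = chars[p - 1].lower()
                fh.write(f">{seq.id}\n")
                body = "".join(chars)
                for i in range(0, len(body), 60):
                    fh.write(body[i:i + 60] + "\n")


def make_sequence_db(n_decoys: int, planted: Sequence[PhosphoSequence] | None = None,
                     seed: int = 0, *, length_range: tuple[int, int] = (200, 1200),
                     sites_per_decoy: int = 3, max_reject_rate: float = 0.99
                     ) -> SequenceDbFixture:
    """Decoy database with planted motif instances.

    Decoys are uniform over the 20 amino acids with lengths uniform in
    ``length_range`` and are rejection-filtered with the brute-force scanner
    under the worst case (every S/T phosphorylated), so they cannot match the
    default pattern under any annotation.  Planted sequences are inserted
    verbatim.  The emitted database is self-checked: a brute-force scan must
    reproduce exactly the planted hit set.
    """
    if n_decoys < 0:
        raise SyntheticError("n_decoys must be >= 0")
    planted = list(planted) if planted is not None else []
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
    db: list[PhosphoSequence] = []
    attempts = accepted = 0
    while accepted < n_decoys:
        attempts += 1
        if attempts > 50 and 1.0 - accepted / attempts > max_reject_rate:
            raise SyntheticError(
                "decoy rejection rate exceeds limit; the pattern is too "
                "permissive to build a clean decoy set"
            )
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = bytes(rng.choice(alphabet, size=length)).decode()
        if brute_force_default_scan(seq, set(range(1, length + 1))):
            continue
        st_positions = [i + 1 for i, ch in enumerate(seq) if ch in "ST"]
        k = min(sites_per_decoy, len(st_positions))
        sites = (rng.choice(st_positions, size=k, replace=False).tolist()
                 if k else [])
        accepted += 1
        db.append(PhosphoSequence(f"DECOY_{accepted:04d}", seq,
                                  frozenset(int(p) for p in sites)))
    db.extend(planted)

    truth_hits = set()
    for seq in planted:
        for phi, _, ppos in brute_force_default_scan(seq.sequence,
                                                     set(seq.phospho_positions)):
            truth_hits.add((seq.id, phi, ppos))
    # self-check: the whole database scans to exactly the planted hits
    scanned = set()
    for seq in db:
        for phi, _, ppos in brute_force_default_scan(seq.sequence,
                                                     set(seq.phospho_positions)):
            scanned.add((seq.id, phi, ppos))
    if scanned != truth_hits:
        raise SyntheticError(
            f"generator self-check failed: scan found {scanned ^ truth_hits} "
            "beyond/missing the planted hits"
        )
    params = {"n_decoys": n_decoys, "length_range": length_range,
              "sites_per_decoy": sites_per_decoy,
              "planted": [s.id for s in planted]}
    return SequenceDbFixture(db, truth_hits, seed, params)
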