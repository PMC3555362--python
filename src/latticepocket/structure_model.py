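"""Crystal-structure data model and I/O.

Holds atoms/residues/chains together with the unit cell and the space-group
operators, and provides the fractional/orthogonal coordinate math that all
lattice-expansion code builds on.  Parsing of mmCIF/PDB files and the
Hermann-Mauguin symbol -> operator-list lookup are delegated to gemmi, whose
compiled-in space-group table covers all 230 groups; only the 65 Sohncke
(chiral) groups relevant to protein crystals are accepted here.

Conventions: author (PDB) residue numbering is kept as-is, hydrogens are
dropped on reading, and coordinates are stored in both the fractional and the
orthogonal basis (standard a-along-x orthogonalization).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Backbone heavy-atom names; everything else in an amino acid is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

AMINO3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class StructureError(ValueError):
    """A structure file is missing a required record or is malformed."""


class SpaceGroupError(ValueError):
    """Unknown or unsupported (non-chiral) space-group symbol."""


# ---------------------------------------------------------------------------
# Unit cell and coordinate transforms
# ---------------------------------------------------------------------------


class UnitCell:
    """Triclinic unit cell: edge lengths in Angstrom, angles in degrees.

    The orthogonalization matrix follows the standard crystallographic
    convention (a along x, b in the xy plane).
    """

    __slots__ = ("a", "b", "c", "alpha", "beta", "gamma", "_orth", "_frac")

    def __init__(self, a: float, b: float, c: float,
                 alpha: float = 90.0, beta: float = 90.0, gamma: float = 90.0):
        for name, v in (("a", a), ("b", b), ("c", c)):
            if not v > 0:
                raise ValueError(f"cell edge {name} must be positive, got {v}")
        for name, v in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
            if not 0 < v < 180:
                raise ValueError(f"cell angle {name} must be in (0, 180), got {v}")
        ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
        sg = math.sin(math.radians(gamma))
        metric = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if metric <= 0:
            raise ValueError(
                f"degenerate cell: angles ({alpha}, {beta}, {gamma}) give a "
                "non-positive metric determinant"
            )
        self.a, self.b, self.c = float(a), float(b), float(c)
        self.alpha, self.beta, self.gamma = float(alpha), float(beta), float(gamma)
        v = math.sqrt(metric)  # V / (abc)
        self._orth = np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, c * v / sg],
            ]
        )
        self._frac = np.linalg.inv(self._orth)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self._orth))

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix taking fractional column vectors to Angstrom."""
        return self._orth

    @property
    def frac_matrix(self) -> np.ndarray:
        """Inverse of :attr:`orth_matrix`."""
        return self._frac

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def __eq__(self, other) -> bool:
        return isinstance(other, UnitCell) and self.parameters() == other.parameters()

    def __repr__(self) -> str:
        return "UnitCell(%g, %g, %g, %g, %g, %g)" % self.parameters()


def orthogonalize(frac: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Fractional -> orthogonal (Angstrom). Accepts a 3-vector or (N, 3)."""
    return np.asarray(frac, dtype=float) @ cell.orth_matrix.T


def fractionalize(orth: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Orthogonal (Angstrom) -> fractional. Accepts a 3-vector or (N, 3)."""
    return np.asarray(orth, dtype=float) @ cell.frac_matrix.T


# ---------------------------------------------------------------------------
# Symmetry operators
# ---------------------------------------------------------------------------

_FRACTIONS = [(0.0, ""), (1 / 6, "+1/6"), (0.25, "+1/4"), (1 / 3, "+1/3"),
              (0.5, "+1/2"), (2 / 3, "+2/3"), (0.75, "+3/4"), (5 / 6, "+5/6")]


@dataclass(frozen=True)
class SymOp:
    """A space-group operator in the fractional basis: x -> rot @ x + trans."""

    rot: np.ndarray
    trans: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rot", np.asarray(self.rot, dtype=float).reshape(3, 3))
        object.__setattr__(self, "trans", np.asarray(self.trans, dtype=float).reshape(3))
        det = np.linalg.det(self.rot)
        if not math.isclose(det, 1.0, abs_tol=1e-9):
            raise SpaceGroupError(
                f"operator rotation determinant is {det:g}, expected +1 "
                "(only chiral space groups are supported)"
            )

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymOp":
        op = gemmi.Op(triplet)
        return cls(np.array(op.rot) / op.DEN, np.array(op.tran) / op.DEN)

    def is_identity(self) -> bool:
        return bool(np.allclose(self.rot, np.eye(3)) and np.allclose(self.trans % 1.0, 0.0))

    def apply(self, frac: np.ndarray, lattice_shift: Sequence[int] = (0, 0, 0)) -> np.ndarray:
        """rot @ frac + trans + lattice_shift; frac may be (3,) or (N, 3)."""
        frac = np.asarray(frac, dtype=float)
        return frac @ self.rot.T + self.trans + np.asarray(lattice_shift, dtype=float)

    def inverse(self) -> "SymOp":
        rinv = np.linalg.inv(self.rot)
        return SymOp(rinv, -rinv @ self.trans)

    def triplet(self) -> str:
        """Human-readable operator string, e.g. ``-x,y+1/2,-z+1/2``."""
        parts = []
        for i in range(3):
            term = ""
            for j, letter in enumerate("xyz"):
                c = self.rot[i, j]
                if abs(c) < 1e-9:
                    continue
                sign = "-" if c < 0 else ("+" if term else "")
                term += f"{sign}{letter}"
            t = self.trans[i] % 1.0
            frac_str = min(_FRACTIONS, key=lambda f: abs(f[0] - t))[1]
            parts.append(term + frac_str if term else frac_str.lstrip("+") or "0")
        return ",".join(parts)

    def __eq__(self, other) -> bool:
        return (isinstance(other, SymOp) and np.allclose(self.rot, other.rot)
                and np.allclose(self.trans, other.trans))

    def __hash__(self) -> int:
        return hash(self.triplet())


def space_group_symops(symbol: str) -> list[SymOp]:
    """Resolve a Hermann-Mauguin symbol to its operator list (identity first).

    Only Sohncke (chiral) groups are accepted, since protein crystals cannot
    contain mirror or inversion symmetry.
    """
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise SpaceGroupError(
            f"unknown space group symbol {symbol!r}; supported symbols are the "
            "65 Sohncke groups in Hermann-Mauguin notation, e.g. 'P 1', "
            "'P 21', 'C 2', 'P 21 21 21', 'P 43 21 2'"
        )
    if not sg.is_sohncke():
        raise SpaceGroupError(
            f"space group {sg.hm!r} is not chiral (Sohncke); protein crystals "
            "only occur in the 65 Sohncke groups"
        )
    ops = []
    for op in sg.operations():
        ops.append(SymOp(np.array(op.rot) / op.DEN, np.array(op.tran) / op.DEN))
    # gemmi lists the identity first; assert rather than trust silently
    if not ops[0].is_identity():
        ops.sort(key=lambda o: not o.is_identity())
    return ops


def apply_symop(op: SymOp, frac: np.ndarray,
                lattice_shift: Sequence[int] = (0, 0, 0)) -> np.ndarray:
    """Apply a symmetry operator plus integer lattice translation to ``frac``."""
    return op.apply(frac, lattice_shift)


# ---------------------------------------------------------------------------
# Atoms, residues, structures
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    """One heavy atom with coordinates kept in both bases."""

    name: str
    element: str
    frac: np.ndarray
    orth: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    @classmethod
    def from_orth(cls, name: str, element: str, orth: Sequence[float], cell: UnitCell,
                  occupancy: float = 1.0, altloc: str = "") -> "Atom":
        orth = np.asarray(orth, dtype=float)
        return cls(name, element, fractionalize(orth, cell), orth, occupancy, altloc)

    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class Residue:
    """A residue identified by chain id and author sequence number."""

    chain_id: str
    seq_num: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def side_chain_atoms(self) -> list[Atom]:
        """Heavy atoms beyond the backbone (CB and outward; ring for Pro)."""
        return [a for a in self.atoms if not a.is_backbone()]

    def is_amino(self) -> bool:
        return self.res_name in AMINO3

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_num)

    def __repr__(self) -> str:
        return f"<Residue {self.res_name}{self.seq_num}/{self.chain_id}>"


class CrystalStructure:
    """Chains of residues plus the unit cell and space-group operators.

    ``peptides`` is the subset of chain ids regarded as bound ligand peptides
    (relevant to pocket-guest detection); by default short all-amino-acid
    chains are flagged on reading.
    """

    def __init__(self, id: str, cell: UnitCell, symops: Sequence[SymOp],
                 chains: dict[str, list[Residue]], peptides: Iterable[str] = (),
                 space_group: str = "P 1"):
        n_identity = sum(op.is_identity() for op in symops)
        if n_identity != 1:
            raise StructureError(
                f"symmetry operator list must contain the identity exactly once "
                f"(found {n_identity})"
            )
        self.id = id
        self.cell = cell
        self.symops = list(symops)
        self.chains = chains
        self.peptides = set(peptides)
        self.space_group = space_group
        for atom in self.atoms():
            if not np.all(np.isfinite(atom.orth)):
                raise StructureError(f"atom {atom.name} has non-finite coordinates")
        self._table: dict | None = None

    # -- iteration ---------------------------------------------------------

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    def get_residue(self, chain_id: str, seq_num: int) -> Residue | None:
        for res in self.chains.get(chain_id, ()):
            if res.seq_num == seq_num:
                return res
        return None

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    # -- flat atom table (used by the lattice machinery) -------------------

    def atom_table(self) -> dict:
        """Flattened view: coordinate arrays plus per-atom residue metadata.

        Returns a dict with keys ``orth`` (N, 3), ``frac`` (N, 3),
        ``meta`` (list of (chain_id, seq_num, res_name, atom_name)) and
        ``sidechain`` (bool array).  Cached; invalidate with
        :meth:`invalidate_cache` after mutating coordinates.
        """
        if self._table is None:
            meta, orth, frac, side, elem = [], [], [], [], []
            for res in self.residues():
                for a in res.atoms:
                    meta.append((res.chain_id, res.seq_num, res.res_name, a.name))
                    orth.append(a.orth)
                    frac.append(a.frac)
                    side.append(not a.is_backbone())
                    elem.append(a.element)
            self._table = {
                "meta": meta,
                "orth": np.array(orth).reshape(-1, 3),
                "frac": np.array(frac).reshape(-1, 3),
                "sidechain": np.array(side, dtype=bool),
                "element": elem,
            }
        return self._table

    def invalidate_cache(self) -> None:
        self._table = None

    # -- output ------------------------------------------------------------

    def write_pdb(self, path: str | Path) -> None:
        """Write a minimal PDB file (CRYST1 + ATOM records), deterministic."""
        with open(path, "w") as fh:
            fh.write(
                "CRYST1%9.3f%9.3f%9.3f%7.2f%7.2f%7.2f %-11s%4d\n"
                % (*self.cell.parameters(), self.space_group, len(self.symops))
            )
            serial = 0
            for chain_id, residues in self.chains.items():
                for res in residues:
                    for a in res.atoms:
                        serial += 1
                        fh.write(format_pdb_atom(serial, a.name, a.altloc, res.res_name,
                                                 chain_id, res.seq_num, a.orth,
                                                 a.occupancy, a.element))
                fh.write("TER\n")
            fh.write("END\n")

    def __repr__(self) -> str:
        return (f"<CrystalStructure {self.id}: {len(self.chains)} chains, "
                f"{self.n_atoms} atoms, {self.space_group}>")


def format_pdb_atom(serial: int, name: str, altloc: str, res_name: str, chain_id: str,
                    seq_num: int, orth: np.ndarray, occupancy: float, element: str) -> str:
    pdb_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        "ATOM  %5d %-4s%1s%-3s %1s%4d    %8.3f%8.3f%8.3f%6.2f%6.2f          %2s\n"
        % (serial % 100000, pdb_name, altloc or " ", res_name, chain_id, seq_num,
           orth[0], orth[1], orth[2], occupancy, 0.0, element)
    )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _is_dummy_cell(cell: gemmi.UnitCell) -> bool:
    return cell.a == 1.0 and cell.b == 1.0 and cell.c == 1.0


def _altloc_of(at: gemmi.Atom) -> str:
    return "" if at.altloc in ("", " ", "\x00") else at.altloc


def _select_altloc(res: gemmi.Residue) -> str:
    """Pick the conformer letter with the highest mean occupancy."""
    occ: dict[str, list[float]] = {}
    for at in res:
        alt = _altloc_of(at)
        if alt:
            occ.setdefault(alt, []).append(at.occ)
    if not occ:
        return ""
    return max(sorted(occ), key=lambda k: sum(occ[k]) / len(occ[k]))


def read_structure(path: str | Path, format: str = "auto", *,
                   keep_altlocs: bool = False,
                   peptide_chains: Iterable[str] | None = None,
                   max_peptide_len: int = 15) -> CrystalStructure:
    """Read a crystal structure from an mmCIF or PDB file.

    Hydrogens are dropped.  By default one conformer (highest occupancy) is
    kept per residue; ``keep_altlocs=True`` retains all, which matters when
    a deposited model records both rotamers of a gating side chain.  Chains
    listed in ``peptide_chains`` are flagged as bound peptides; when omitted,
    chains of at most ``max_peptide_len`` standard amino acids are flagged.

    Raises :class:`StructureError` if the unit cell or space-group record is
    absent, and :class:`SpaceGroupError` for unknown/achiral symbols.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif}.get(format)
    if fmt is None:
        raise ValueError(f"format must be one of auto/pdb/mmcif, got {format!r}")
    st = gemmi.read_structure(str(path), format=fmt)
    if _is_dummy_cell(st.cell):
        raise StructureError(
            f"{path.name}: missing unit cell (no CRYST1 record / _cell block)"
        )
    if not st.spacegroup_hm:
        raise StructureError(
            f"{path.name}: missing space-group record "
            "(CRYST1 symbol / _symmetry.space_group_name_H-M)"
        )
    cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                    st.cell.alpha, st.cell.beta, st.cell.gamma)
    symops = space_group_symops(st.spacegroup_hm)

    chains: dict[str, list[Residue]] = {}
    model = st[0]
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            chosen = "" if keep_altlocs else _select_altloc(res)
            atoms: list[Atom] = []
            seen: set[tuple[str, str]] = set()
            for at in res:
                if at.element.is_hydrogen:
                    continue
                alt = _altloc_of(at)
                if not keep_altlocs and alt and alt != chosen:
                    continue
                key = (at.name, alt)
                if key in seen:
                    continue
                seen.add(key)
                orth = np.array([at.pos.x, at.pos.y, at.pos.z])
                atoms.append(Atom(at.name, at.element.name.upper(), fractionalize(orth, cell),
                                  orth, at.occ, alt if keep_altlocs else ""))
            if atoms:
                residues.append(Residue(ch.name, res.seqid.num, res.name, atoms))
        if residues:
            chains[ch.name] = residues

    if peptide_chains is not None:
        peptides = set(peptide_chains)
        unknown = peptides - set(chains)
        if unknown:
            raise StructureError(f"peptide chain(s) not in structure: {sorted(unknown)}")
    else:
        peptides = {
            cid for cid, residues in chains.items()
            if len(residues) <= max_peptide_len and all(r.is_amino() for r in residues)
        }
        if peptides:
            logger.info("flagged peptide chain(s): %s", sorted(peptides))

    return CrystalStructure(path.stem, cell, symops, chains, peptides,
                            space_group=st.spacegroup_hm)
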