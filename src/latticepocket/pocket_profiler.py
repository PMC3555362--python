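"""Hydrophobic-pocket profiling: guests, gating rotamers, pocket state.

The pocket is defined by a residue list (a *pocket profile*), not detected
de novo.  The packaged default is the seven-residue site on the Plk1
polo-box domain: Val415, Leu478 and Phe482 form the bottom of the pocket,
Tyr417, Tyr421, Tyr481 and Tyr485 its sides.  Three of these side chains
gate the pocket -- Tyr417, Tyr481 and Phe482 -- and Tyr481 is the primary
gate: in the resting state its ring stacks onto Phe482 and fills the cavity,
while rotamer changes open the site to accept a hydrophobic residue donated
by a symmetry-related protomer or by a bound peptide (a *guest*).

Guest detection is deliberately side-chain-only on both sides: a residue is
"in the pocket" when its side-chain heavy atoms touch the side chains of at
least ``min_pocket_residues`` distinct pocket residues, which excludes
grazing backbone-mediated lattice contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from latticepocket._geom import dihedral, wrap_angle
from latticepocket.lattice_contacts import DEFAULT_CONTACT_CUTOFF, SymmetryMate
from latticepocket.structure_model import CrystalStructure, Residue

logger = logging.getLogger(__name__)

CLOSED = "closed"
OPEN = "open"
GUEST_OCCUPIED = "guest_occupied"

#: chi1 is N-CA-CB-X; the fourth atom by residue type.
CHI1_FOURTH_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}

#: chi2 is CA-CB-G-X; (third, fourth) atoms by residue type.
CHI2_ATOMS = {
    "ARG": ("CG", "CD"), "GLN": ("CG", "CD"), "GLU": ("CG", "CD"),
    "HIS": ("CG", "ND1"), "ILE": ("CG1", "CD1"), "LEU": ("CG", "CD1"),
    "LYS": ("CG", "CD"), "MET": ("CG", "SD"), "PHE": ("CG", "CD1"),
    "PRO": ("CG", "CD"), "TRP": ("CG", "CD1"), "TYR": ("CG", "CD1"),
    "ASN": ("CG", "OD1"), "ASP": ("CG", "OD1"),
}

DEFAULT_MIN_POCKET_RESIDUES = 3
DEFAULT_CLOSED_HALFWIDTH = 40.0  # degrees around the stacked-rotamer chi1


class PocketError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Chi angles
# ---------------------------------------------------------------------------


def chi_angles(residue: Residue) -> tuple[float | None, float | None]:
    """(chi1, chi2) in degrees, IUPAC convention, range (-180, 180].

    Missing atoms (truncated side chains in real files, Gly/Ala for chi1,
    residues without a chi2) yield ``None`` for that angle, with a warning.
    """
    chi1 = chi2 = None
    fourth = CHI1_FOURTH_ATOM.get(residue.res_name)
    if fourth is not None:
        atoms = [residue.atom(n) for n in ("N", "CA", "CB", fourth)]
        if all(a is not None for a in atoms):
            chi1 = dihedral(*(a.orth for a in atoms))
        else:
            missing = [n for n, a in zip(("N", "CA", "CB", fourth), atoms) if a is None]
            logger.warning("%s: cannot compute chi1, missing %s", residue, missing)
    c2 = CHI2_ATOMS.get(residue.res_name)
    if c2 is not None:
        names = ("CA", "CB") + c2
        atoms = [residue.atom(n) for n in names]
        if all(a is not None for a in atoms):
            chi2 = dihedral(*(a.orth for a in atoms))
        else:
            missing = [n for n, a in zip(names, atoms) if a is None]
            logger.warning("%s: cannot compute chi2, missing %s", residue, missing)
    return chi1, chi2


# ---------------------------------------------------------------------------
# Pocket definition
# ---------------------------------------------------------------------------


@dataclass
class PocketDefinition:
    """Residue-list definition of a pocket, with roles and gating flags.

    ``residues`` is an ordered list of (chain, seq_num, res_name); ``bottom``
    and ``sides`` partition it by role; ``gates`` are the residues whose
    rotamer state opens/closes the pocket and ``primary_gate`` is the one
    whose chi1 discriminates closed from open.
    """

    residues: list[tuple[str, int, str]]
    bottom: set[tuple[str, int]]
    sides: set[tuple[str, int]]
    gates: list[tuple[str, int]] = field(default_factory=list)
    primary_gate: tuple[str, int] | None = None
    closed_chi1_ref: float = -65.0
    closed_halfwidth: float = DEFAULT_CLOSED_HALFWIDTH
    name: str = "pocket"

    def __post_init__(self):
        keys = {(c, s) for c, s, _ in self.residues}
        if self.bottom | self.sides != keys or self.bottom & self.sides:
            raise PocketError("bottom/sides must partition the pocket residues")

    @classmethod
    def from_file(cls, path: str | Path) -> "PocketDefinition":
        """Parse a pocket profile: one residue per line,
        ``chain seq_num res_name role(bottom|side) gate(yes|no|primary)``;
        ``#key value`` comment lines set ``closed_chi1_ref``/``closed_halfwidth``."""
        path = Path(path)
        residues: list[tuple[str, int, str]] = []
        bottom: set = set()
        sides: set = set()
        gates: list = []
        primary = None
        opts: dict[str, float] = {}
        for ln, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] in ("closed_chi1_ref", "closed_halfwidth"):
                    opts[parts[0]] = float(parts[1])
                continue
            parts = line.split()
            if len(parts) != 5:
                raise PocketError(f"{path.name}:{ln}: expected 5 fields, got {len(parts)}")
            chain, seq, res_name, role, gate = parts
            key = (chain, int(seq))
            residues.append((chain, int(seq), res_name))
            if role == "bottom":
                bottom.add(key)
            elif role == "side":
                sides.add(key)
            else:
                raise PocketError(f"{path.name}:{ln}: role must be bottom|side, got {role!r}")
            if gate in ("yes", "primary"):
                gates.append(key)
                if gate == "primary":
                    primary = key
            elif gate != "no":
                raise PocketError(f"{path.name}:{ln}: gate must be yes|no|primary, got {gate!r}")
        return cls(residues, bottom, sides, gates, primary, name=path.stem, **opts)

    @classmethod
    def plk1_default(cls) -> "PocketDefinition":
        """The packaged seven-residue Plk1 polo-box-domain pocket profile."""
        ref = resources.files("latticepocket") / "data" / "plk1_pbd.profile"
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def lookup(self, structure: CrystalStructure) -> dict[tuple[str, int], Residue]:
        out = {}
        for chain, seq, res_name in self.residues:
            res = structure.get_residue(chain, seq)
            if res is None:
                raise PocketError(
                    f"pocket residue {res_name}{seq} (chain {chain}) absent from "
                    f"structure {structure.id}"
                )
            out[(chain, seq)] = res
        return out


# ---------------------------------------------------------------------------
# Guests
# ---------------------------------------------------------------------------


@dataclass
class GuestResidue:
    """A residue whose side chain is inserted into the pocket."""

    source: str                       # "symmetry_mate" or "peptide_chain"
    identity: tuple[str, int, str]    # (chain or chain[mate label], seq_num, res_name)
    n_pocket_residues_contacted: int
    min_distance: float
    contacted: list[tuple[str, int]] = field(default_factory=list)
    side_chain_only: bool = True


def _candidate_residues(structure: CrystalStructure, mates: Sequence[SymmetryMate]):
    """Yield (source, identity, side-chain coords) for every candidate residue."""
    for mate in mates:
        groups: dict[tuple, list[int]] = {}
        for i, (chain, seq, res_name, _) in enumerate(mate.meta):
            if mate.sidechain[i]:
                groups.setdefault((chain, seq, res_name), []).append(i)
        for (chain, seq, res_name), idx in sorted(groups.items()):
            identity = (f"{chain}[{mate.label}]", seq, res_name)
            yield "symmetry_mate", identity, mate.orth[idx]
    for chain_id in sorted(structure.peptides):
        for res in structure.chains.get(chain_id, ()):
            sc = res.side_chain_atoms()
            if sc:
                coords = np.array([a.orth for a in sc])
                yield "peptide_chain", (chain_id, res.seq_num, res.res_name), coords


def find_pocket_guests(structure: CrystalStructure, mates: Sequence[SymmetryMate],
                       pocket: PocketDefinition,
                       cutoff: float = DEFAULT_CONTACT_CUTOFF,
                       min_pocket_residues: int = DEFAULT_MIN_POCKET_RESIDUES
                       ) -> list[GuestResidue]:
    """Residues from symmetry mates or peptide chains inserted into the pocket.

    A candidate qualifies when >= 1 of its side-chain heavy atoms lies within
    ``cutoff`` of side-chain heavy atoms of at least ``min_pocket_residues``
    distinct pocket residues.  Result is sorted by contacted-pocket-residue
    count (desc), then minimum distance (asc).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if min_pocket_residues < 1:
        raise ValueError("min_pocket_residues must be >= 1")
    pocket_res = pocket.lookup(structure)
    pocket_coords = {}
    for key, res in pocket_res.items():
        sc = res.side_chain_atoms()
        if not sc:
            logger.warning("pocket residue %s has no side-chain atoms", res)
            continue
        pocket_coords[key] = np.array([a.orth for a in sc])

    guests: list[GuestResidue] = []
    for source, identity, coords in _candidate_residues(structure, mates):
        if identity[:2] in pocket_res and source == "peptide_chain":
            continue
        contacted = []
        best = np.inf
        for key, pc in pocket_coords.items():
            d = np.linalg.norm(coords[:, None, :] - pc[None, :, :], axis=2)
            dmin = float(d.min())
            best = min(best, dmin)
            if dmin <= cutoff:
                contacted.append(key)
        if len(contacted) >= min_pocket_residues:
            guests.append(GuestResidue(source, identity, len(contacted), best,
                                       sorted(contacted)))
    guests.sort(key=lambda g: (-g.n_pocket_residues_contacted, g.min_distance, g.identity))
    return guests


# ---------------------------------------------------------------------------
# Pocket state
# ---------------------------------------------------------------------------


@dataclass
class PocketState:
    """Gating chi angles plus the closed / open / guest_occupied call."""

    gating_chis: dict[tuple[str, int], tuple[float | None, float | None]]
    state: str
    guest: GuestResidue | None = None

    def __post_init__(self):
        if self.state == GUEST_OCCUPIED and self.guest is None:
            raise PocketError("guest_occupied state requires a guest")


def classify_pocket_state(structure: CrystalStructure, pocket: PocketDefinition,
                          guests: Sequence[GuestResidue],
                          closed_chi1_ref: float | None = None,
                          closed_halfwidth: float | None = None) -> PocketState:
    """Call the pocket conformational state.

    Precedence: any guest -> ``guest_occupied``.  Otherwise the primary-gate
    chi1 (Tyr481 in the default profile) is compared against the closed-state
    reference rotamer: within ``closed_halfwidth`` degrees -> ``closed``,
    else ``open``.  If the primary gate's chi1 cannot be computed the pocket
    is reported ``open`` with a warning (the stacked rotamer cannot be
    established without it).
    """
    ref = pocket.closed_chi1_ref if closed_chi1_ref is None else closed_chi1_ref
    halfwidth = pocket.closed_halfwidth if closed_halfwidth is None else closed_halfwidth
    pocket_res = pocket.lookup(structure)
    chis = {}
    for key in pocket.gates:
        chis[key] = chi_angles(pocket_res[key])
    if guests:
        return PocketState(chis, GUEST_OCCUPIED, guests[0])
    primary = pocket.primary_gate or (pocket.gates[0] if pocket.gates else None)
    if primary is None:
        raise PocketError("pocket definition has no gating residues")
    chi1 = chis.get(primary, (None, None))[0]
    if chi1 is None:
        logger.warning("primary gate %s chi1 unavailable; reporting state=open", primary)
        return PocketState(chis, OPEN)
    state = CLOSED if abs(wrap_angle(chi1 - ref)) <= halfwidth else OPEN
    return PocketState(chis, state)


def compare_states(a: PocketState, b: PocketState
                   ) -> dict[tuple[str, int], tuple[float | None, float | None]]:
    """Per-gate chi deltas (b minus a), wrapped to (-180, 180]; None propagates."""
    if set(a.gating_chis) != set(b.gating_chis):
        raise PocketError("states were computed over different pocket definitions")
    out = {}
    for key in a.gating_chis:
        deltas = []
        for ca, cb in zip(a.gating_chis[key], b.gating_chis[key]):
            deltas.append(None if ca is None or cb is None else wrap_angle(cb - ca))
        out[key] = tuple(deltas)
    return out
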