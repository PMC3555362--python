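"""Bipartite phospho-anchored motif search.

The search string couples the phosphopeptide-groove consensus (anchored on a
phosphorylated S/T) to a secondary hydrophobic pocket-binding residue
(default Phi in {F, L}) located N-terminally at a bounded spacing (default
0-3 spacer residues X):

    Phi - X{spacer_min..spacer_max} - [consensus ... p(S/T)]

The default consensus block is X, X, S, p[S/T].  The engine is
pattern-agnostic: any consensus element list with at least one
phospho-required element can be compiled and scanned.

Sequences carry explicit phosphosite annotations -- lower-case letters in a
FASTA dialect (``FDPPLHStA``) or a sidecar ``id<TAB>position`` table.  An
opt-in mode treats every S/T of an unannotated sequence as potentially
phosphorylated, for databases that list interactors without site data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO1 = set("ACDEFGHIKLMNPQRSTVWY")
PHOSPHO_ACCEPTORS = set("STY")


class MotifError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhosphoSequence:
    """A protein sequence with 1-based phosphosite annotations."""

    id: str
    sequence: str
    phospho_positions: frozenset[int] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "phospho_positions", frozenset(self.phospho_positions))
        for p in self.phospho_positions:
            if not 1 <= p <= len(self.sequence):
                raise MotifError(f"{self.id}: phosphosite {p} outside sequence "
                                 f"of length {len(self.sequence)}")
            if self.sequence[p - 1] not in PHOSPHO_ACCEPTORS:
                raise MotifError(f"{self.id}: phosphosite {p} is "
                                 f"{self.sequence[p - 1]!r}, not S/T/Y")

    def __len__(self) -> int:
        return len(self.sequence)


def load_phospho_fasta(path: str | Path, sites_path: str | Path | None = None,
                       assume_st_phospho: bool = False) -> list[PhosphoSequence]:
    """Read a phosphosite-annotated FASTA database.

    Lower-case letters mark phosphosites.  A sidecar TSV (``id<TAB>position``,
    1-based) may supply sites instead; when a record has both, the lower-case
    annotation wins with a warning.  ``assume_st_phospho=True`` marks every
    S/T of records that end up with no annotation (logged; off by default).
    """
    sidecar: dict[str, set[int]] = {}
    if sites_path is not None:
        for ln, raw in enumerate(Path(sites_path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise MotifError(f"{sites_path}:{ln}: expected id<TAB>position")
            sidecar.setdefault(parts[0], set()).add(int(parts[1]))

    out: list[PhosphoSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        lower = {i + 1 for i, ch in enumerate(raw)
                 if ch.islower() and ch.upper() in PHOSPHO_ACCEPTORS}
        positions = lower
        if rec.id in sidecar:
            if lower and sidecar[rec.id] != lower:
                logger.warning("%s: lower-case phosphosites override sidecar table", rec.id)
            elif not lower:
                positions = sidecar[rec.id]
        if not positions and assume_st_phospho:
            positions = {i + 1 for i, ch in enumerate(raw.upper()) if ch in "ST"}
            logger.info("%s: no site annotation; assuming all S/T phosphorylated", rec.id)
        out.append(PhosphoSequence(rec.id, raw.upper(), frozenset(positions)))
    return out


# ---------------------------------------------------------------------------
# Pattern
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsensusElement:
    """One consensus position: an allowed-residue set (None = wildcard X)
    and whether the position must be an annotated phosphosite."""

    allowed: frozenset[str] | None
    phospho_required: bool = False

    def matches(self, residue: str, is_phospho: bool) -> bool:
        if self.phospho_required and not is_phospho:
            return False
        return self.allowed is None or residue in self.allowed


@dataclass(frozen=True)
class MotifPattern:
    """Phi residues, spacer bounds, and the anchoring consensus block."""

    phi_set: frozenset[str]
    spacer_min: int
    spacer_max: int
    consensus: tuple[ConsensusElement, ...]

    def __post_init__(self):
        if not self.phi_set:
            raise MotifError("pattern has an empty Phi set")
        if not 0 <= self.spacer_min <= self.spacer_max:
            raise MotifError(
                f"invalid spacer range {self.spacer_min}..{self.spacer_max}"
            )
        if not any(e.phospho_required for e in self.consensus):
            raise MotifError("pattern has no phospho anchor")

    @property
    def anchor_offset(self) -> int:
        """Offset (0-based) of the last phospho-required consensus element."""
        return max(i for i, e in enumerate(self.consensus) if e.phospho_required)


def default_pattern() -> MotifPattern:
    """Phi in {F, L}, 0-3 spacers, consensus X, X, S, p[S/T]."""
    return MotifPattern(
        frozenset("FL"), 0, 3,
        (ConsensusElement(None), ConsensusElement(None),
         ConsensusElement(frozenset("S")),
         ConsensusElement(frozenset("ST"), phospho_required=True)),
    )


_ELEMENT_RE = re.compile(r"^(p)?(X|[A-Z]|\[([A-Z]+)\])$")


def compile_pattern(spec: str | None = None) -> MotifPattern:
    """Compile a pattern description, e.g.
    ``PHI={F,L} SPACER=0..3 CONSENSUS=X,X,S,p[ST]``; empty -> default."""
    if spec is None or not spec.strip():
        return default_pattern()
    phi_set, spacer_min, spacer_max = frozenset("FL"), 0, 3
    consensus: tuple[ConsensusElement, ...] | None = None
    for token in spec.split():
        if "=" not in token:
            raise MotifError(f"malformed pattern token {token!r}")
        key, _, value = token.partition("=")
        key = key.upper()
        if key == "PHI":
            letters = re.findall(r"[A-Z]", value.upper())
            if not letters:
                raise MotifError(f"malformed PHI set {value!r}")
            phi_set = frozenset(letters)
        elif key == "SPACER":
            m = re.match(r"^(\d+)\.\.(\d+)$", value)
            if not m:
                raise MotifError(f"malformed SPACER range {value!r} (expected lo..hi)")
            spacer_min, spacer_max = int(m.group(1)), int(m.group(2))
        elif key == "CONSENSUS":
            elements = []
            for el in value.split(","):
                m = _ELEMENT_RE.match(el.strip())
                if not m:
                    raise MotifError(f"malformed consensus element {el!r}")
                phospho = m.group(1) is not None
                body = m.group(2)
                if body == "X":
                    allowed = None
                elif m.group(3):
                    allowed = frozenset(m.group(3))
                else:
                    allowed = frozenset(body)
                elements.append(ConsensusElement(allowed, phospho))
            consensus = tuple(elements)
        else:
            raise MotifError(f"unknown pattern key {key!r}")
    if consensus is None:
        consensus = default_pattern().consensus
    return MotifPattern(phi_set, spacer_min, spacer_max, consensus)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifHit:
    """One motif match: Phi position, anchoring phosphosite, matched span."""

    protein_id: str
    phi_pos: int        # 1-based
    phospho_pos: int    # 1-based, the anchoring pS/pT
    spacer_len: int
    matched_span: str
    has_fxp: bool


def scan_sequence(seq: PhosphoSequence, pattern: MotifPattern) -> list[MotifHit]:
    """All matches of ``pattern`` in ``seq``, every spacer length considered.

    Overlapping hits are all reported.  Ordered by phi_pos, then spacer_len.
    ``has_fxp`` flags matches whose span starts with F-x-P at Phi.
    """
    s = seq.sequence
    n = len(s)
    clen = len(pattern.consensus)
    hits: list[MotifHit] = []
    for phi_pos in range(1, n + 1):
        if s[phi_pos - 1] not in pattern.phi_set:
            continue
        for spacer in range(pattern.spacer_min, pattern.spacer_max + 1):
            start = phi_pos + spacer  # 0-based index of first consensus residue
            if start + clen > n:
                continue
            ok = True
            for i, element in enumerate(pattern.consensus):
                pos = start + i + 1
                if not element.matches(s[pos - 1], pos in seq.phospho_positions):
                    ok = False
                    break
            if not ok:
                continue
            anchor_pos = start + pattern.anchor_offset + 1
            end = start + clen
            span = s[phi_pos - 1:end]
            has_fxp = (s[phi_pos - 1] == "F" and phi_pos + 2 <= end
                       and s[phi_pos + 1] == "P")
            hits.append(MotifHit(seq.id, phi_pos, anchor_pos, spacer, span, has_fxp))
    hits.sort(key=lambda h: (h.phi_pos, h.spacer_len))
    return hits


@dataclass
class DatabaseScanResult:
    """Per-protein hits plus screen-level counts."""

    hits: dict[str, list[MotifHit]]
    n_proteins_scanned: int
    n_proteins_with_hit: int

    def all_hits(self) -> list[MotifHit]:
        return [h for hits in self.hits.values() for h in hits]


def scan_database(db: Iterable[PhosphoSequence],
                  pattern: MotifPattern | None = None) -> DatabaseScanResult:
    """Scan a database; returns hits per protein and how many proteins match."""
    pattern = pattern or default_pattern()
    seqs = sorted(db, key=lambda s: s.id)
    seen: set[str] = set()
    hits: dict[str, list[MotifHit]] = {}
    for seq in seqs:
        if seq.id in seen:
            raise MotifError(f"duplicate protein id {seq.id!r} in database")
        seen.add(seq.id)
        h = scan_sequence(seq, pattern)
        if h:
            hits[seq.id] = h
    return DatabaseScanResult(hits, len(seqs), len(hits))
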