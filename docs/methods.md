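# Methods

This note documents the models, parameters and numerical choices behind
`latticepocket`, and what the synthetic fixtures do and do not establish.

## Crystal model and coordinate math

A structure is a hierarchy of chains → residues → heavy atoms together with
a triclinic unit cell and the space-group operator list. Coordinates are
kept in both the fractional and the orthogonal basis, synchronized at
construction; the orthogonalization matrix follows the standard a-along-x
convention, and fractional→orthogonal→fractional round trips are exact to
well below 1e-9 (tested to machine precision). Operators are resolved from
the Hermann–Mauguin symbol through gemmi's compiled-in table; only the 65
Sohncke (chiral) groups are accepted, since protein crystals admit no mirror
or inversion symmetry, and every operator is validated to have rotation
determinant +1.

Residue numbering is always author (PDB) numbering, so Tyr481 in code is
Tyr481 in the literature. Hydrogens are dropped on reading: the analysis is
heavy-atom geometric, appropriate for X-ray models that rarely carry
reliable hydrogens. Alternate locations default to the highest-occupancy
conformer per residue; `keep_altlocs=True` retains all conformers, which
matters when a deposited model records both rotamers of a gating side
chain. Bound peptides are flagged per chain (by default: chains of ≤ 15
standard amino acids), and the caller can override the flagging explicitly —
one crystal form can hold protomers in different pocket states, so nothing
assumes one-structure-one-state.

## Lattice expansion and contacts

Symmetry mates are transformed atom copies (never views). The lattice-shift
search window per axis is computed from the fractional bounding boxes of
the reference and transformed copies plus a margin of radius × (row norm of
the fractionalization matrix), so elongated or oblique cells are covered
without a fixed ±1 assumption. A mate is emitted iff ≥ 1 atom lies within
the expansion radius of the reference; emission order (operator index, then
lexicographic shift) is deterministic. A configurable cap (default 2000
mates) guards against absurd radii.

Contacts are heavy-atom pairs within a cutoff, default **4.5 Å** — the
conventional upper bound for van der Waals contact. The neighbour search
uses a k-d tree whose output is contractually identical to the all-pairs
double loop; the tests enforce that equality on random 300–500-atom clouds
over many seeds. No numeric contact criterion exists in the source
literature for "a residue accommodated by the pocket"; 4.5 Å is a stated
convention and every CLI run logs the resolved parameters.

## Buried surface area and interface classification

SASA is Shrake–Rupley with a deterministic golden-spiral point lattice
(default 960 points/atom; no RNG anywhere in the geometry), probe 1.4 Å and
van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å. BSA of a
patch is SASA(A) + SASA(B) − SASA(A∪B) over the two whole protomers.
Accuracy anchors: a single sphere reproduces 4π(r+w)² to < 1 % at 960
points, and the two-sphere overlap matches the closed-form spherical-cap
area to < 2 %; refining 960 → 3840 points moves realistic interface areas
by < 5 %.

Patches are labelled `crystal_contact` below **800 Å²** buried and
`candidate_biological` at or above it (≥ rule at the boundary). The
threshold is the common literature convention for separating packing
contacts from physiological interfaces; it is configurable and echoed into
the output header. No ΔG-style significance scoring is attempted.

## Pocket profiling

A pocket is user-supplied data: an ordered residue list with roles
(bottom/side) and gate flags. The packaged default is the Plk1 PBD
seven-residue site with gates Tyr417, Tyr481 (primary) and Phe482.

χ angles use the IUPAC sign convention, range (−180°, 180°], computed from
the standard atom quadruples (χ1: N–CA–CB–γ; χ2: CA–CB–γ–δ); missing atoms
yield an absent angle plus a logged warning rather than an error, since
truncated side chains are routine in real files. χ computation is exactly
rigid-body invariant and recovers constructed dihedrals to 1e-6°.

**Guest detection** is side-chain-only on both sides: a residue from a
symmetry mate or a peptide chain is a guest iff ≥ 1 of its side-chain heavy
atoms lies within the cutoff (default 4.5 Å) of side-chain heavy atoms of
at least `min_pocket_residues` (default **3**) distinct pocket residues. A
residue genuinely *in* the pocket touches the bottom and both sides;
requiring 3 of 7 excludes grazing, backbone-mediated lattice contacts.
Guests are ordered by pocket residues contacted (desc), then minimum
distance (asc), so output is deterministic.

**State call**: any guest ⇒ `guest_occupied`; otherwise the primary gate's
χ1 is compared with the closed-state reference rotamer — within ± 40°
⇒ `closed`, else `open`. The reference χ1 (−65°, the common tyrosine minus
rotamer, stored in the packaged profile) parameterizes the stacked
"Tyr481-on-Phe482" conformation; the source literature reports the stacking
qualitatively, not as an angle, so the bin is calibrated on the synthetic
fixtures and is fully configurable per profile. If the primary gate's χ1
cannot be computed the state is reported `open` with a warning, because the
stacked rotamer cannot be established without it. Tyr417 angles are
reported but do not enter the default rule: whether its open form is
separable by χ1 alone is not established, and `compare_states` reports all
gate deltas (wrapped to (−180°, 180°]) rather than asserting which single
dihedral carries a reported 90° flip.

## Anchored motif search

The pattern is Φ (default {F, L}) separated by `spacer_min..spacer_max`
(default 0..3) wildcards from a consensus element list (default
X, X, S, p[S/T]; the final element must be an annotated phosphosite). The
engine is pattern-agnostic — any element list with ≥ 1 phospho-required
position compiles — because the published search-string figure is not
transcribable to the residue; the default reconstruction reproduces both
known positive contexts (F+3 spacers+⟨L,H,S,pT⟩; F+3 spacers+⟨P,M,S,pS⟩)
with `has_fxp` true. All overlapping hits are reported (no greedy
consumption); coordinates are 1-based throughout. Phosphosites come from
lower-case FASTA letters or a sidecar TSV (lower-case wins on conflict,
with a warning); an opt-in `--assume-st-phospho` mode treats every S/T of
unannotated records as potentially phosphorylated and is clearly logged.
The scanner is verified equivalent to a raw window enumerator on 10³ random
annotated sequences.

## Thermal-shift differencing

ΔΔTm = ΔTm(wild-type) − ΔTm(pocket mutant) is computed with decimal
arithmetic at the input's printed precision, so a one-decimal table
reproduces its printed difference column exactly. A peptide is called
pocket-dependent iff ΔΔTm ≥ **2.0 °C**: the bundled data separate into
≈ 4.3 °C (dependent) versus |Δ| ≤ 0.4 °C (independent), and 2.0 °C splits
those populations with margin on both sides. No statistical test is
applied — shift tables of this kind ship without replicate errors, and the
threshold rule is documented as exactly that. ITC columns are parsed and
carried through untouched.

## Synthetic fixtures

The lattice generator emulates a guest-donating crystal contact: a
~30-residue mock protomer (idealized internal-coordinate residue templates;
no real deposited coordinates) carries the seven-residue pocket arranged as
three bottom residues pointing up and four side residues ringing the
equator, side-chain tips ≈ 4 Å from the pocket centre. A leucine's home
position is then *solved* by inverse-transforming the desired in-pocket
pose through candidate (operator, lattice shift) images until a clash-free
placement exists, so the guest genuinely arrives via crystallographic
symmetry. Supported groups: P1, P2₁, P2₁2₁2₁; cells ≈ 46–54 Å with seeded
jitter. An optional pair of complementary residue walls at opposite cell
faces plants an interface large enough (> 800 Å²) for the ±a translated
neighbours to classify as candidate-biological.

Every fixture self-checks before emission against exhaustive brute-force
oracles (plain double loops over a ±2 lattice window; raw window
enumeration for sequences); a failing fixture raises instead of being
returned. Same seed and parameters give byte-identical files, and fixtures
are written in standard formats (PDB, FASTA + TSV) so tests exercise the
real readers.

The sequence generator draws decoys uniformly over the 20 amino acids with
lengths uniform in [200, 1200] and rejection-filters them so that no decoy
matches the default pattern *even if every S/T were phosphorylated* — the
planted hit set is therefore the exact truth under any annotation. The
standard screen fixture is 629 decoys plus the two printed match contexts,
mirroring a 2-of-631 outcome.

What the fixtures do **not** show: they have no realistic fold, packing
density, B-factors, solvent, or sequence homology structure. Passing the
synthetic suites demonstrates the correctness of the geometry, search and
classification machinery — not field performance on deposited crystal
structures, which additionally face disorder, altlocs, truncated side
chains and non-protein entities (the readers handle those mechanically, but
recovery rates on real lattices are not measured here).

## Problem sizes and determinism

Default test/verification sizes were chosen so the whole suite exercises
each claim meaningfully at interactive speed: 50 generator seeds for guest
recovery, 20 clouds × 500 atoms for contact-oracle equivalence, 10³
sequences for scan equivalence, 960 sphere points for SASA. All stochastic
tests are seeded; hypothesis property tests run derandomized.

## Known limitations

- Interface classification is the single-area criterion; no conservation,
  ΔG or complexation-significance scoring.
- Pocket sites are residue lists; there is no de-novo cavity detection or
  volume/druggability scoring.
- The closed/open χ1 bin is a one-parameter rotamer model; side chains that
  open by χ2 alone would need a custom profile rule.
- The motif engine has no probabilistic (PSSM) scoring; matches are exact.
- P2₁ fixtures are generated with β = 90° for simplicity; the analysis code
  itself handles oblique cells (and is tested on them), only the generator
  restricts itself.
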