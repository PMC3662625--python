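# Methods

This note documents the models, conventions, and numerical choices behind
`ligfam`, and what the synthetic test surface does and does not demonstrate
about real crystal structures.

## Scope and data model

The package analyses protein structures around bound S-adenosyl-L-methionine
(SAM) or S-adenosyl-L-homocysteine (SAH; identical minus the S-methyl carbon
CE). A `Structure` is the heavy-atom content of model 1 of a PDB file; a
`LigandInstance` is one SAM/SAH residue (one per chain/residue-number pair),
analysed independently even when several copies sit in one asymmetric unit.
Parsing policies, applied once at read time so all downstream code sees a
single dialect:

- PDB-v2 asterisk sugar names (`O2*`, `O3*`, `O4*`) become primed names.
- Alternate locations collapse to the highest-occupancy conformer; ties go to
  the earlier altloc letter. This keeps geometry single-valued and
  deterministic.
- Hydrogens are discarded: most X-ray entries lack them, so every criterion
  downstream is heavy-atom-only.
- Residue numbers are taken verbatim from the source file; no renumbering.

## Ribose pseudorotation

Five-membered rings pucker along a pseudorotation cycle rather than discrete
states. With the endocyclic torsions ν0–ν4 (ν2 = C1'-C2'-C3'-C4' as the
reference), the Altona–Sundaralingam reduction is

    tan P = ((ν4 + ν1) − (ν3 + ν0)) / (2 ν2 (sin 36° + sin 72°)),
    Vmax  = ν2 / cos P,

with the model identity νj = Vmax·cos(P + 144°·(j−2)). P is computed with
`atan2`, which resolves the quadrant so Vmax ≥ 0 without a separate 180°
shift; the phase is reported both in [0°, 360°) and as a signed alias in
(−180°, 180°], since published tables use either convention. Conformer names
come from the 20-sector wheel; the reported label is the nearest envelope
midpoint (18° = C3'-endo, 54° = C4'-exo, 90° = O4'-endo, 126° = C1'-exo,
162° = C2'-endo, and their mirror partners at +180°), which covers every name
that occurs in practice for nucleoside-like ligands.

Degenerate handling: rings with max |νj| < 1° are reported as `planar` with
`defined=False` instead of dividing by cos P near its zero. When ν2 ≈ 0
(P near ±90°) the amplitude is taken from the sine term instead.

A useful identity check: mirroring the coordinates negates all five torsions,
which shifts the cosine wave by half a turn — P → (P + 180°) mod 360° with
Vmax unchanged (an envelope maps to its endo/exo partner). All geometry is
invariant under rigid motions to numerical precision.

## Conformational dihedrals and reliability

Extended vs folded ligand shape is described by χ = C4-N9-C1'-O4' (base
orientation about the glycosidic bond), γ = O3'-C4'-C5'-SD and
δ = C4'-C5'-SD-CG (the methionine/homocysteine arm). Note γ is a generalized
four-point dihedral through the non-bonded O3'. Torsions follow the IUPAC
sign convention (clockwise positive viewed down the central bond), reported
in (−180°, 180°]. Missing atoms degrade per-angle (None), never the whole
record. No hard extended/folded threshold is imposed; the three angles are
reported descriptively.

Ligands whose mean B-factor exceeds 80 Å² (strictly greater; a mean of
exactly 80.0 passes) are flagged as conformationally unreliable and excluded
by default from conformation typing.

## Superposition and conformation types

Pairwise superposition uses the Kabsch SVD solution restricted to proper
rotations (the smallest singular direction is flipped when the correlation
determinant is negative — reflections are not physical superpositions).
Pairings are by atom name: the "ribose" set is the five ring atoms, "all" is
the intersection of shared heavy atoms (SAM vs SAH drops CE). The default
two-stage comparison fits on the ribose frame and evaluates RMSD over all
shared atoms, which separates base/arm conformation from sugar geometry; a
direct all-atom fit is also available and, being the least-squares optimum,
never yields a larger all-atom RMSD.

Conformation "Types" are complete-linkage clusters of the RMSD matrix cut at
a threshold (default 1.0 Å, configurable). Complete linkage makes the cut
directly interpretable: every intra-Type pair deviates by at most the
threshold. Types are numbered by descending cluster size, ties broken by the
smallest member id, so labels are deterministic. A target-based mode
(superpose everything onto one reference) is available on the CLI.

## Hydrogen bonds

Without hydrogens, donor/acceptor geometry cannot include an angle term, so
a contact is: ligand N/O/S atom and protein N/O/S atom within 3.35 Å
(configurable) where one side can donate and the other accept per fixed role
tables. Ligand roles: adenine N1/N3/N7 accept, the exocyclic amine N6
donates, the 2'/3' hydroxyls both donate and accept, O4' and the carboxylate
O/OXT accept, the terminal ammonium N donates; the sulfonium SD and ring
junction N9 are excluded (they essentially never hydrogen-bond to protein).
Protein roles follow standard side-chain chemistry plus backbone N (donor,
except proline) and O/OXT (acceptors). Water-mediated bridges are out of
scope. Interaction profiles tally residue types per ligand atom; class
fractions use charged = DEKRH, hydrophobic = AVLIMFWC, polar = STNQYG.

## Sheet topology and the LigFold catalog

Secondary structure is an input (classic-format DSSP or a sidecar TSV of
strand elements plus ladder pairs), never computed internally — this keeps
the module testable and mirrors how topology diagrams are curated in
practice. Strands are numbered 1..n by N→C order; ladder pairs form a graph
whose linearization is the left-to-right spatial strand order. Cyclic graphs
(barrels) and branched graphs are rejected; disconnected graphs use the
largest component (the core sheet) with a warning, renumbering the retained
strands 1..n_core before reading the order string.

A linear sheet reads in two directions. Both readings are matched against
the packaged catalog of 14 strand-order sub-classes of the Rossmann-fold
MTase sheet; if exactly one matches it wins, if both match (the catalog
contains two mutual-reversal pairs) the reading whose first core strand has
the lower N→C number wins and the ambiguity is flagged in the output, and if
neither matches the sheet is NOVEL with the three nearest catalog strings by
edit distance. Consequently a sheet graph built from one member of a
reversal pair resolves deterministically to the lower-first-strand member —
the reading direction is simply not recoverable from ladder connectivity
alone. Structures with two SAM-binding sheets are assigned per domain and
checked against the combined dual-domain catalog entry. Strand orientation
(antiparallel flags) is recorded but does not participate in matching.

The packaged fold-type registry holds the 18 SAM-binding fold types with
their MTase/non-MTase split (9/9). Names for folds beyond the five
established classes are schematic placeholders; only the numerals, the split
and the counts are load-bearing.

## Site rules, propagation, motifs

A family site rule is the intersection of (a) representative residues at
hydrogen-bond distance from the ligand and (b) columns conserved across the
entire family alignment. Two conservation modes: `strict` (one residue type,
no gaps — gaps disqualify a column) and `conservative` (column stays within
one substitution group: DE, KR, ST, NQ, ILVM, FYW, AG). Strict rules are by
construction subsets of conservative ones. Empty rules are valid (warned
about): positions contacting the flexible carboxylate end are typically not
conserved and drop out.

Propagation aligns a query globally to the representative (BLOSUM62, gap
open −10, extend −1) and maps rule positions through the alignment. A
positive match requires every rule position present and allowed; anything
less yields per-position diagnostics and no annotation. This pairwise scheme
replaces profile-HMM scoring; at the scale of a single family with a
designated representative the decision surface is equivalent, and it keeps
the package self-contained.

Motif detection covers the conserved Rossmann-fold MTase elements: Motif I
is purely sequence-based (G/A-x-G/A-x-G/A with an invariant acidic residue
at −2 from the first glycine and hydrophobics at −3/−4); Motifs II, III, IV
and VI are anchored to strand annotations (acidic mid-strand-II with
hydrophobic −3/−4; hydrophilic D/S/T/N at the strand-III N-terminus with
optional C-terminal glycine; acidic near the strand-IV N-terminus with V/I
at +2; glycine at the strand-V start with hydrophobics at +2/+3) and are
skipped with a notice when annotations are absent. Motif V has no conserved
residues and is reported only as the region between strands IV and V.

## Synthetic structures

The generators are inverse problems of the analysis modules, and their
defaults are the study conditions of the test suite:

- `make_ribose(P, Vmax)` refines 15 Cartesian coordinates by least squares
  against target bond lengths (C–C 1.52 Å, C–O 1.45 Å) and the five target
  torsions, from a planar-pentagon seed with a pseudorotation-like
  out-of-plane wave (several seed phases tried in fixed order —
  deterministic). Torsion residuals are weighted 10:3 over bond residuals
  with a weak bond-angle regularizer (target 104°): the five-torsion cosine
  wave is not exactly closure-consistent, so bonds flex by up to ~0.06 Å at
  Vmax 55° to absorb the residual. Acceptance: max torsion error < 0.5°,
  max bond error < 0.06 Å, else a generation error.
- `make_conformer` grows the remaining atoms by natural-extension-reference-
  frame placement from idealized internal coordinates (PDB chemical-component
  geometry of SAM), with χ and δ set directly as placement torsions and γ
  solved by a one-shot rotation about C4'-C5' (rotating SD shifts the
  generalized γ one-to-one). Exocyclic face choices put the base and the
  hydroxyls on opposite faces; stereochemistry is idealized, not refined.
  Non-bonded pairs (graph distance ≥ 3) closer than 1.8 Å abort generation
  with a clash report — genuinely strained (P, χ, γ, δ) combinations are
  rejected rather than emitted.
- `make_pocket` places each requested protein atom at its exact contact
  distance along a deterministically searched direction that keeps every
  other polar ligand atom beyond 3.45 Å, so the constructed contact set is
  exactly the requested one; decoy carbons land ≥ 5 Å away.
- `make_family` builds seeded alignments with exactly controlled strict /
  conservative / non-conserved columns (group membership is enforced by
  construction, never left to chance).

What passing on this surface shows: the analysis pipeline is internally
consistent, numerically correct against closed forms and independent oracles,
and deterministic. What it does not show: robustness to real crystallographic
noise — partial occupancy, misfit ligands, chain breaks, non-standard residue
naming beyond the asterisk dialect, or genuinely ambiguous sheet topologies.
Those require curated PDB inputs, which the package reads but does not ship.

## Problem sizes and tolerances

The test suite and the acceptance script use: the 80-point pseudorotation
grid (P every 18°, Vmax ∈ {10°, 25°, 40°, 55°}, recovery within 1°), 100
seeded 10-atom clouds for the Kabsch-vs-quaternion comparison (agreement to
1e-6 Å), 200 random strand permutations (n = 5–8) for topology round-trips,
four-contact pockets with 20 decoys, and 100 seeded toy families for the
rule-conservation audit. Each block runs in seconds on one CPU; the full
acceptance script completes in well under a minute.
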