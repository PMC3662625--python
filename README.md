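# ligfam

Ligand-centric structural analysis of SAM/SAH-binding proteins.

S-adenosyl-L-methionine (SAM) is, after ATP, the most widely used small-molecule
cofactor: methyltransferases (MTases) and a long tail of non-MTase enzymes bind
it across at least 18 distinct protein folds. Because the *ligand* is the common
denominator of these otherwise unrelated families, annotating them works best
from the ligand outwards. `ligfam` implements that ligand-centric toolkit for
structural bioinformaticians and curators:

- **Structure I/O** — fixed-column PDB parsing with atom-name dialect
  normalization (`O2*` → `O2'`), altloc collapsing, and SAM/SAH ligand
  extraction (`ligfam.structio`).
- **Ligand geometry** — ribose pseudorotation in the Altona–Sundaralingam
  convention: endocyclic torsions ν0–ν4, phase angle *P*, amplitude *V*max,
  conformer naming on the 20-sector wheel (C3'-endo, C1'-exo, …), the
  extended/folded dihedrals χ (C4-N9-C1'-O4'), γ (O3'-C4'-C5'-SD) and
  δ (C4'-C5'-SD-CG), and the mean-B-factor reliability flag (> 80 Å² means the
  pose is too mobile to trust) (`ligfam.geometry`).
- **Superposition and conformation typing** — Kabsch least-squares fits on the
  ribose frame or all shared atoms (SAM∩SAH drops the S-methyl CE), all-vs-all
  RMSD matrices, complete-linkage clustering into conformation "Types"
  (`ligfam.superpose`).
- **Hydrogen-bond profiling** — heavy-atom donor/acceptor contacts within
  3.35 Å, per-ligand-atom residue-type profiles with charged / hydrophobic /
  polar fractions (`ligfam.contacts`).
- **Sheet topology** — β-strand order strings (e.g. `3214567`) from DSSP or
  sidecar TSV annotations, matched against the packaged 14-entry LigFold
  catalog of Rossmann-fold sub-classes and the 18-fold registry, including
  dual-domain structures (`ligfam.topology`).
- **Site rules and motifs** — family rules anchoring conserved ligand-binding
  residues to a representative structure, rule propagation to structure-less
  sequences by BLOSUM62 global alignment, and detection of the conserved MTase
  motifs (glycine-rich `GxGxG` Motif I and the strand-anchored Motifs II–VI)
  (`ligfam.siterules`).
- **Synthetic structures** — deterministic generators for puckered riboses,
  full SAM/SAH conformers at prescribed (P, Vmax, χ, γ, δ), toy pockets with
  exact contact geometry, and toy family alignments; the package's
  download-free test surface (`ligfam.synthconf`).

The core pseudorotation relations, with ν2 as the reference torsion:

    tan P = ((ν4 + ν1) − (ν3 + ν0)) / (2 ν2 (sin 36° + sin 72°))
    Vmax  = ν2 / cos P,          νj = Vmax · cos(P + 144°·(j − 2))

## Worked example

Generate a synthetic SAM pocket (default conformer: C1'-exo ribose, χ = −60°,
γ = 75°, δ = 180°, with an Asp and a Glu at exact hydrogen-bond distances and
ten decoy carbons), then analyse it:

```bash
$ ligfam synth pocket --entry "N6:ASP:OD1:2.9" --entry "O2':GLU:OE1:3.1" \
      --decoys 10 --seed 2 --out pocket.pdb
$ ligfam pucker pocket.pdb
structure_id  chain  ligand_code  nu0    nu1   nu2    nu3  nu4   P      P_signed  Vmax  conformer  chi    gamma  delta   mean_b  flagged
POCKET        L      SAM          -38.1  38.1  -23.5  0.0  23.6  126.0  126.0     40.0  C1'-exo    -60.0  75.0   -180.0  20.0    False
$ ligfam contacts pocket.pdb
structure_id  ligand_atom  chain  resnum  resname  protein_atom  distance
POCKET        N6           P      1       ASP      OD1           2.90
POCKET        O2'          P      2       GLU      OE1           3.10
```

The pucker line reads: endocyclic torsions ν0–ν4, phase P = 126° (a C1'-exo
envelope, the conformation most common in Rossmann-fold MTase ligands),
amplitude Vmax = 40°, the three conformational dihedrals, and the mean
B-factor with its reliability flag. The contact table lists exactly the two
constructed hydrogen bonds — the decoy carbons are correctly ignored.

Other entry points: `ligfam superpose` (RMSD matrix + Type labels),
`ligfam topology --ssa file.tsv --ladders pairs.tsv` (strand order + LigFold
class), `ligfam rules build|apply` (site rules), and `ligfam analyze` for the
full JSON report over many structures.

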