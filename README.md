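# cif2smiles

Curated chemical-connectivity SMILES from crystallographic CIF files.

Crystal-structure databases store unit cells, symmetry operators and atom
coordinates — not the bonding picture a chemist works with. `cif2smiles`
derives that picture: it reads CIF 1.1 files, decides how each entry must
be treated (Z′, disorder, bonds crossing the asymmetric-unit boundary),
reconstructs the finite "molecule" by symmetry expansion, perceives bonds
from geometry (covalent-radius sum plus offset, with a dedicated window
for metal–metal contacts), assigns bond orders, aromaticity and formal
charges following the representation conventions used for open
crystallographic collections, applies tetrahedral stereochemistry with
Sohncke-group-aware racemate handling, runs a rule-based curation pass,
and writes tab-separated `SMILES<TAB>ID` collection files plus the
haloanion-recharged companion collection.

It is aimed at database curators and cheminformaticians who need
substructure-searchable connectivity for small-molecule crystal
structures, including the species plain organic toolkits refuse to
represent: metal carbonyls (`[Ni](C#[O])(C#[O])(C#[O])C#[O]`),
metallocenes with bracketed aromatic carbons, η²/η³/η⁴ ligands, borane
cages, chelates with a single chosen resonance form, and disconnected
ionic frameworks (`[Na+].[Cl-]`).

## Core conventions

* **Bond perception** — atoms `i, j` are bonded when
  `d(i,j) ≤ r(i) + r(j) + Δ` with single-bond covalent radii and
  Δ = 0.40 Å; hydrogen bonds only to its nearest heavy neighbor.
  Transition-metal pairs: always bonded below 2.85 Å, never bonded above
  3.0 Å when a bridging ligand supports the contact, and between the two
  thresholds the authors' `_geom_bond` listing decides.
* **Bond orders** — unsaturation is placed by maximum matching over atoms
  short of a standard valence (OpenSMILES organic-subset valences), then
  convention rules override: terminal M–C–O becomes `M–C#[O]`, bridging
  CO becomes ketone-like `C(=O)`, oxoanions get double bonds to neutral
  oxygens and single bonds to charged ones, metal–metal bonds are always
  single.
* **Aromaticity** — Hückel's 4n+2 rule on Kekulé structures; endocyclic
  singly-bonded N/O/S do not break aromaticity; a ring carrying exocyclic
  double bonds is aromatic exactly when an in-ring single bond flanked by
  two in-ring double bonds survives (quinones: no; cyclopentadienone and
  2-pyridone: yes). η⁵/η⁶ rings on metals are aromatic with mandatory
  brackets (`[cH]`).
* **Brackets** — an atom is bracketed whenever its bond-order sum differs
  from a standard valence, with hydrogens always written as in-bracket
  counts.
* **Stereochemistry** — tetrahedral centres only, from the sign of the
  signed volume of the substituent tetrahedron. In a Sohncke space group
  (all operator determinants +1) marks are kept; in a racemic crystal a
  single mark is stripped, while multi-centre moieties are written twice,
  the second copy with every `@`/`@@` inverted; meso moieties once.
* **Haloanions** — the main collection puts the charge on a terminal
  halogen (`[P](F)(F)(F)(F)(F)[F-]`); the alternative collection moves it
  to the centre (`[P-](F)(F)(F)(F)(F)F`), checked for charge
  conservation.

## Worked example

The package generates its own test crystals; no external data is needed.

```
$ cif2smiles fixtures --write /tmp/fx
wrote 43 fixtures to /tmp/fx

$ cif2smiles triage /tmp/fx/nacl.cif /tmp/fx/disorder_two_site.cif
nacl	1/48	sub_one	False	False
disorder_two_site	1	one	True	False
```

`nacl` has Z′ = 4/192 (rock-salt cell, 192 operators listed), no disorder
and no cross-unit bonds; the ethanol entry is flagged disordered.

```
$ cif2smiles convert /tmp/fx/pyrrole.cif /tmp/fx/pf6_salt.cif --out out.smi
$ cat out.smi
[F-][P](F)(F)(F)(F)F.C[N+](C)(C)C	pf6_salt
c(cc[nH]1)c1	pyrrole
```

Pyrrole comes out aromatic with the `[nH]` bracket (canonically equal to
`c1ccc[nH]1`); the hexafluorophosphate salt carries −1 on a fluorine and
+1 on the ammonium nitrogen. The recharged companion collection moves the
haloanion charge onto phosphorus:

```
$ cif2smiles recharge out.smi
F[P-](F)(F)(F)(F)F.C[N+](C)(C)C	pf6_salt
```

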