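# Methods

## Scope and model

`cif2smiles` converts a crystal structure — unit cell, symmetry operator
list, atom sites with fractional coordinates and occupancies, and
optionally author-listed `_geom_bond_*` records — into a curated SMILES
string for the chemist's "molecule": the finite set of atoms one would
draw for the compound, possibly several moieties with stoichiometric
multiplicities. The chemistry model is valence-bond: bonds are pairwise
with integer orders (plus an aromatic bond type), which is why extended
ionic frameworks, metals and 2-D/3-D covalent polymers are represented as
disconnected ions/atoms or rejected with a structured error rather than
forced into a string.

## Pipeline and assumptions

1. **Triage.** Z′ = Z / (number of listed operators) as an exact
   rational. The operator count is taken verbatim from the file: implied
   centring translations must be listed to be counted, mirroring a
   pipeline that trusts the CIF over the space-group symbol. An entry is
   "disordered" when any occupancy is below 1 − 10⁻⁶ (the tolerance
   absorbs "0.9999999" formatting noise) and "cross-unit" when any
   `_geom_bond_site_symmetry_2` differs from "." / "1_555". Entries
   without Z are rejected rather than defaulted.
2. **Expansion.** The asymmetric unit seeds a cluster growth: a symmetry
   image (operator + lattice shift) is added only if it lies within
   bonding distance of an already-placed atom. Images coinciding with a
   placed atom within 0.2 Å are merged (special positions); 0.2 Å is far
   below any bonding distance and far above coordinate noise. The growth
   also runs for "fast-path" entries because it is a no-op for a clean
   finite molecule and is what reveals hidden polymerism. A self-image of
   a cluster under a pure lattice translation marks it polymeric; the
   rank of the collected translation lattice is the polymer dimension.
   Growth is bounded at 3 cells span and 800 atoms.
3. **Disorder.** Within each disorder assembly the group with the largest
   occupancy sum is kept (ties broken by lexicographically smallest group
   label, logged); moieties with mean occupancy below 0.1 are dropped
   (mineral-style substitutional mixtures); fractional-occupancy solvent
   survives and is later counted once.
4. **Bond perception.** Distance rule r₁ + r₂ + 0.40 Å over Cordero
   single-bond covalent radii (one radius per element). The offset is a
   convention parameter: 0.40 Å reproduces every fixture connectivity
   with standard bond lengths while keeping 1,3-distances unbonded.
   Hydrogen binds only its nearest heavy neighbor. Transition-metal pairs
   (d-block Z 21–30, 39–48, 72–80) use the 2.85 / 3.0 Å window: below
   2.85 Å always bonded, between 2.85 and 3.0 Å bonded exactly when the
   authors listed the contact, above 3.0 Å removed when a third atom
   bridges both metals. Listed bonds can be ignored (`perceived`), used
   alone (`geom`) or unioned (`merged`); the pipeline runs `perceived`
   and `merged` and flags the entry for review when their canonical
   results differ, defaulting to the perceived-only result (a documented
   package choice — the interactive original left this to an operator).
5. **Bond orders.** Valence deficits (lowest standard valence ≥ σ-degree,
   metals excluded from degrees) are satisfied by maximum-cardinality
   maximum-weight matching, iterated so triple bonds form. Weights prefer
   ring–ring pairs and disfavor pairs involving metal-bound donors, which
   selects the benzenoid form for metal phenolates while still forming
   the exocyclic C=O of cyclopentadienone; for symmetric chelates
   (acetate, acetylacetonate) the two resonance forms are canonically
   identical, so the matching tie-break cannot affect output. Convention
   overrides: terminal M–C–O → M–C#[O]; μ₂-CO → C=O; isocyanides like
   carbonyls; hypervalent oxo centres (N 5, P 5, S 6, Cl/Br/I 7, As 5,
   Se 6) raise X=O bonds before leftover oxygens become charged;
   metal-bound atoms with leftover deficit act as anionic donors, a
   deficit of two raising the metal bond to a double (carbene).
6. **Aromaticity.** Evaluated on 5–6-rings of the metal-free graph.
   Rings without exocyclic double bonds use Hückel counting: each in-ring
   double contributes 2, a singly-bonded N/O/S contributes its lone pair,
   carbanions and metal-absorbed donors contribute 2, and any sp³ member
   vetoes. Rings with exocyclic double bonds are aromatic exactly when an
   in-ring single bond flanked by two in-ring doubles survives, where
   flanking doubles owned by an already-aromatic ring do not count — this
   keeps the central rings of anthraquinone and 9-methylene-fluorene
   non-aromatic for every Kekulé variant while cyclopentadienone and
   2-pyridone stay aromatic. Carbocycles fully bonded to one metal
   (η⁵/η⁶) are aromatic with mandatory brackets. An all-carbon
   3-connected cage of ≥ 60 atoms is aromatic wholesale; substituted
   cages are only partially handled (see limitations).
7. **Charges.** None in metal-containing moieties (coordination
   compounds), except pure centre-plus-halogen haloanions, where
   (degree − max valence) terminal halogens take −1. Monoatomic moieties
   are charged by group (alkali +1, alkaline-earth +2, halide −1);
   quaternary N/P get +1; remaining valence deficits become negative
   charges (oxoanion and carboxylate oxygens, cyclopentadienide carbon).
8. **Stereochemistry.** Tetrahedral only. A centre needs four
   substituents with distinct canonical ranks (implicit H counts, its
   position idealized when unknown); parity comes from the sign of the
   substituent-tetrahedron determinant, refused below a signed volume of
   0.1 Å³ so poor or disordered geometry cannot emit spurious marks.
   Sohncke groups (all rotation determinants +1) keep their marks;
   otherwise one mark is stripped, several marks trigger enantiomer
   doubling via `@`↔`@@` inversion, and meso moieties (canonically equal
   to their mirror image) stay single. The policy is idempotent.
9. **Stoichiometry.** Isomorphic moieties (canonical-SMILES equality)
   merge with multiplicities, divided by their gcd; when the main species
   still has multiplicity k > 1, whitelisted solvents with fractional
   share are rounded up to one rather than duplicating the main species.
   The solvent whitelist (water through toluene, configurable) caps at
   toluene-sized molecules.
10. **Curation.** Graph-level rewrites for the recurring repair families
    (carbonyl, isocyanide, perchlorate, nitrate, coordinated azide and
    nitrile solvents, wrong-single imines, phosphane hydrogens, bare
    water, neutral haloanions), applied in catalog order, each
    exhaustively, with a replayable change log and a validity re-parse;
    a rule whose output fails to parse is rejected for that record. A
    text find/replace mode exists for fidelity testing. The catalog
    implements the named families and is deliberately extensible — it is
    not a complete inventory of every repair a production collection
    accumulates.

## SMILES dialect and canonicalization

The writer brackets any atom whose bond-order sum is off a standard
valence, writes hydrogens only as in-bracket counts, reuses ring-closure
digits after closure (`%nn` past 9) and joins moieties with ".". One
dialect decision: a single bond between two aromatic atoms is written
bare; the parser resolves an implicit aromatic–aromatic bond to
"aromatic" only when it lies in a ring whose atoms are all aromatic
(bridges of the aromatic subgraph — biphenyl linkages, quinoid fusion
bonds — read as single). This matches how such strings are printed in
curated collections but means biphenylene-like cases, where a single bond
between aromatic atoms lies inside an all-aromatic cycle, would misread;
none occur in scope.

Canonicalization refines atom ranks by (element, charge, degree, explicit
H, aromatic flag, bond-order multiset) to a fixed point, then
individualizes each member of the first tied cell in turn and keeps the
lexicographically smallest output string; the search is capped at 10⁴
candidate orders (reachable only for pathologically symmetric cages, in
which case the best string found is used). Stereo parities are rewritten
under each traversal by permutation parity, so mirror images canonicalize
to different strings and meso detection is exact. Equality with published
convention strings is asserted canonically, never byte-wise, since their
ring numbering is serializer-specific.

## Synthetic fixtures

All test data is generated programmatically: idealized geometries from
standard bond lengths (rings inscribed in circles, tetrahedral frames,
icosahedral cages) placed in generous cells so no accidental
intermolecular contact falls below ~3.5 Å, with symmetry-bearing cases
(special positions, racemic P-1 pairs, rock salt with all 192 operators,
1-D chains, graphene sheet) constructed against explicit operator lists.
Fixtures tagged `paper` carry published convention strings the pipeline
must reproduce canonically; `derived` strings follow from the documented
conventions; `review`/`unsupported` fixtures are checked structurally.
What passing these fixtures does *not* show: behavior on real
crystallographic noise (thermal motion, wrong author Z values, missing
hydrogens beyond the water/hydroxyl rules, genuinely ambiguous disorder),
since fixture geometry is exact by construction; the curation families
are exercised on crafted crude strings, not on a production corpus.

## Numerical choices and degenerate inputs

* Occupancy-vs-one tolerance 10⁻⁶; duplicate merge 0.2 Å; planarity
  cutoff 0.1 Å³; hydroxyl inference on terminal C–O above 1.38 Å with no
  counter-ion in the entry; disorder drop threshold 0.1 occupancy.
* The 1-D polymer generator translation is the smallest-norm lattice
  translation mapping the chain onto itself (logged); the fragment is the
  unit plus one translated image, with dangling continuation bonds
  dropped.
* Entries lacking Z fail parsing; Z is never "fixed" and Z′ is reported
  as an exact rational.
* Coordinated azide is emitted as M–N=[N+]=[N-] (terminal-charge
  principle; the convention source names the family without printing a
  string).
* The discrepancy classifier operationalizes the published severity
  taxonomy as an ordered battery of normalization equivalences (strip H →
  stereo → motif depictions → charges → aromatic flags → bond orders →
  connectivity → composition); boundaries between neighboring categories
  that the source taxonomy leaves informal (e.g. "other groups" vs
  "charge settings") are resolved by this battery's order and documented
  as extensible.

## Known limitations

* No E/Z double-bond marks are emitted (the convention corpus itself
  counts their absence against its own output); square-planar, TBP and
  octahedral stereo descriptors are out of scope.
* 2-D/3-D covalent polymers terminate with a structured
  unsupported-polymer failure; only simple ionic/elemental frameworks get
  a disconnected-ion representation.
* Substituted fullerenes: degree-4 cage carbons go non-aromatic, but the
  Kekulé repair of their neighborhoods is not implemented.
* The bidentate-acetate chelate geometry places the carboxylate carbon
  ~0.2 Å beyond the metal bonding cutoff — representative of the real
  four-member-chelate ambiguity the curation literature warns about, and
  the reason the metal–opposite-atom spurious bond family exists in
  manual curation.
* SQUEEZE-removed solvent cannot be reconstructed and is left out.
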