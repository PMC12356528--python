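# Methods

This note records the model behind each pipeline stage, the parameters
that matter, the design choices made where the design was genuinely
open, and what the tests do and do not establish.

## Scaffold model

A scaffold is a bicyclic union of a cyclic secondary amine — azetidine,
pyrrolidine or piperidine — and a cyclopropane, joined either by a
shared C–C edge (*fused*) or a shared carbon (*spiro*).  Two atoms are
distinguished: **C1**, a cyclopropane carbon with at least one
substitutable hydrogen, where the aryl fragment will be installed, and
**N2**, the ring nitrogen, where the cap will be installed.  Attachment
points are annotated as atom maps on real atoms (map 1 = C1, map 2 =
N2) rather than dummy atoms, so they survive canonicalisation and
round-trips through SMILES.

The nine physical building blocks `1a`–`1i` are stored as free
scaffolds: the Boc protecting group and the boronate handle of the
synthesised precursors are abstracted to the N–H amine and the H-capped
C1.  Racemic blocks store one enantiomer and a `racemic` flag.

### The probe surrogate

Several relative configurations exist only with a C1 substituent in
place: the spiro diastereomer pair `1d`/`1e` collapses to one structure
when C1 is a plain CH₂, and the convex/concave (exo/endo) choice at a
fused-ring apex does the same.  Every scaffold therefore also carries a
*probe* structure — the same molecule with a methyl group standing where
the C1 substituent will go.  The probe is stereochemically complete and
is the identity used for deduplication, registry matching and
elaboration.  The free structure is what property filters see.

## Enumeration

Enumeration is a brute force over placements: every C–C bond of the
amine ring as a fusion bond, every ring carbon as a spiro atom, every
substitutable cyclopropane carbon (ring-junction, apex, or spiro
methylene) as C1.  Constitutions are deduplicated by canonical SMILES
of the stereo-free probe form, which absorbs ring symmetry (e.g. the
2,3- and 4,5-fusions of pyrrolidine are one constitution).

Stereochemistry is realised concretely rather than inferred: for each
constitution, every parity assignment of the candidate stereocentres
(ring carbons with ≥ 3 heavy neighbours) is embedded once with ETKDGv3
and classified from the geometry:

* **cis/trans ring fusion** — signed distances of the two amine-ring
  neighbours of the junction carbons from the cyclopropane plane; trans
  arrangements (opposite signs) are rejected as geometrically
  infeasible for these ring sizes.
* **exo/endo** (fused, C1 at the apex) — whether the C1 substituent
  falls on the opposite side of the cyclopropane plane from the amine
  ring (exo, convex face) or the same side (endo, concave face).
* **syn/anti** (spiro, stereogenic spiro carbon) — whether the C1
  substituent and the N-proximal arm of the amine ring lie on the same
  side of the cyclopropane plane.  Spiro atoms whose two ring arms are
  graph-symmetric produce no diastereomers (tag `none`).

Because classification only reads the *signs* of plane distances, any
successfully embedded conformer gives the same answer; the embedding
seed (module constant, default 1910) does not affect the result, and
the acceptance script demonstrates this by re-deriving it from its own
seed.

Enantiomer pairs are collapsed to the lexicographically smaller
canonical SMILES of (molecule, mirror image) — only one enantiomeric
series is analysed, and both members of a pair give identical (r, θ).

**Convention: endo excluded by default.**  A substituent on the concave
face of a cis-fused bicyclo[n.1.0] system points into the fold of the
bicycle; none of the realisable building blocks is endo, and the design
intent is rigid, synthetically accessible vector display.  With endo
excluded the universe contains exactly **26** scaffolds (14 fused + 12
spiro); `include_endo=True` yields 31, and the per-cell reconciliation
table (`reconciliation_table()` / `exitvec enumerate --reconciliation`)
shows that the whole difference sits in the five fused-apex cells.  If
a different convention is ever needed, that table localises the change;
the count is never silently adjusted.

The tropane block (`1f`) — a spiro cyclopropane on the nortropane
3-position — lies outside the three-amine universe and is appended
explicitly.  Its cyclopropanation is face-selective (carbene delivered
opposite the two-carbon bridge), so only the anti diastereomer enters
the set, giving **27** scaffolds in total.

## Elaboration

Fragment attachment and capping are attachment-point graph edits, not
reaction templates: the design phase reasons about products, and
modelling boronate hydrolysis or Pd catalysis would add nothing to the
geometry.  C1 attachment swaps the probe methyl for the fragment's
attachment atom with `Chem.molzip`, which preserves the parity
bookkeeping at C1 — this is how the syn/anti and exo/endo assignments
propagate into products.  Capping forms the N–X bond directly (amine
nitrogens are not stereocentres).  Caps are encoded as complete
substituents with their attachment atom annotated (methanesulfonyl
attaches through S), removing any ambiguity.  Hydrogen placeholders act
as identities, and capping an already-capped nitrogen is an error.

Every product tracks the four vector-defining atoms by atom map:
C1 (map 1, green), N2 (map 2, orange), the fragment atom bonded to C1
(map 3, blue), and the cap atom bonded to N2 (map 4, red).  Mass
balance holds by construction: each H-displacing attachment loses
exactly two hydrogen masses.

The full grid — 27 scaffolds × 1 fragment × 4 caps — gives **108**
distinct products after canonical deduplication.  A larger published
figure of 112 for this grid would correspond to 28 × 4, i.e. to
elaborating both tropane cyclopropane diastereomers; this package
reports its own count together with the reconciliation table and does
not force agreement.

## Conformers

Lowest-energy conformations come from ETKDGv3 distance-geometry
embedding followed by force-field minimisation.  Defaults: **200
embeddings**, RMSD pruning at **0.5 Å**, **MMFF94** (UFF fallback for
unparameterised atoms), **seed 42**.  Every design-set compound has at
most a handful of rotatable bonds, for which 200 pruned embeddings is a
conventional, saturating ensemble; all defaults are recorded in the
ensemble's `method` tag.  Selection is the single minimum-energy
conformer (ties to the lowest index) — no Boltzmann weighting, since
the analysis targets the single preferred geometry.

Supplied coordinates (SDF, e.g. crystallographic models) enter the same
analysis with energies marked absent; multi-model files yield one
conformer per model and *all* models are retained in the vector table,
the appropriate treatment when an asymmetric unit contains several
conformations.  Files without z-variation are rejected as 2D.

Reproducibility is claimed at the level of measured geometry (±0.2 Å in
r, ±15° in θ across embedding stacks), never at the level of identical
coordinates: distance geometry is stochastic across implementations.
Within one installation, a fixed seed reproduces energies and
coordinates exactly.

## Exit vectors

r is the Euclidean C1–N2 distance; θ is the dihedral of
red–orange–green–blue, computed as the angle between the normals of the
(red, orange, green) and (orange, green, blue) planes, clamped and
folded into [0°, 180°].  The four-point torsion formulation and the
"angle between two planes" phrasing are equivalent; one well-tested
code path implements it, and an independent atan2-based torsion serves
as the test oracle (agreement to 1e-6 degrees on 1000 random
quadruples).  θ is unsigned because torsion signs flip between
enantiomers and only one series is plotted; a [0°, 90°] fold is
available as an option (`fold=90`) for symmetric-display analyses.
Collinear triples make a plane undefined and raise rather than return a
junk angle.  When C1 and N2 are directly bonded (the junction-handle
pyrrolidine scaffold), r degenerates to that bond's length, ≈ 1.5 Å —
the floor of the design set's r range.

### Diversity selection

Subset selection works in normalised space (r scaled by its observed
range, θ by 180°) under the maximin objective: maximise the minimum
pairwise distance.  For small problems (≤ 10⁵ candidate subsets) the
exact optimum is found by exhaustive search with a deterministic
lexicographic tie-break; beyond that a greedy heuristic seeds at the
point nearest the centroid and grows by farthest-point insertion.  The
exact branch exists because greedy-from-centroid provably misses the
optimum already for three collinear points with k = 2 (it keeps the
centre point); the design-set sizes here are always in the exact
regime.

## Properties

MW is the standard average molecular weight of the neutral free base;
clogP is the Crippen atom-contribution estimate; Fsp³ the fraction of
sp³ carbons.  Filters follow the printed inequalities verbatim:
Rule-of-Two strict (MW < 200 and clogP < 2), lead-like with strict
clogP bounds and inclusive MW bounds (−1 < clogP < 3, 200 ≤ MW ≤ 350).
Crippen clogP differs from proprietary calculators by several tenths of
a log unit, so externally computed clogP summaries are cross-checked
qualitatively (±0.5) and never asserted numerically.

## Problem sizes used in the shipped analyses

The test suite and acceptance script run the enumeration at its full,
natural size (26/27 scaffolds; a few hundred classification embeddings,
a few seconds) and the conformer analysis on the nine-compound
methanesulfonamide series at the default 200 embeddings per compound
(≈ half a minute).  The full 108-compound library is elaborated and
profiled in tests; its conformer stage is exercised through the
pipeline on the nine-block subset, since the remaining compounds add
runtime but no new code paths.

## What the fixtures do and do not show

The randomized fixture generator decorates enumerated scaffolds with
small substituents (F, Cl, Me, OMe, CN) to stress parsing, valence
checking and property bounds.  It emulates the structural variety of a
real building-block collection, not its synthetic accessibility or its
vendor availability; passing tests show the machinery is
self-consistent on chemically valid inputs, not that any fixture
compound is makeable.  Likewise, computed exit vectors describe
force-field gas-phase minima; crystal packing or protein binding can
select other conformers (which is why supplied-coordinate ingestion
keeps every model).

## Known limitations

* Stereochemistry classification depends on a successful 3D embedding;
  a hypothetical scaffold that ETKDG cannot embed would be dropped as
  infeasible.  For this universe every cis-fused/spiro placement embeds.
* The 1d/1e syn/anti label-to-name assignment is a transcription choice
  (the original assignment rests on unpublished crystallographic
  detail); swapping the labels permutes two compound ids and changes no
  geometry.
* clogP-dependent statements are method-dependent, as above.
* No docking, pharmacophore scoring, quantum refinement, solvation or
  crystal-packing analysis; the pipeline characterises scaffold
  geometry, not binding.
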