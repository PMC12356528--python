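# exitvec

Computational design pipeline for fragment elaboration in three
dimensions with **bifunctional cyclopropane building blocks**.

In fragment-based drug discovery (FBDD), a low-molecular-weight hit —
often a flat (hetero)aromatic — must be "grown" along spatial vectors to
pick up additional protein interactions.  A family of rigid, sp³-rich
scaffolds that each combine a cyclic secondary amine (azetidine,
pyrrolidine or piperidine) with a fused or spirocyclic cyclopropane
offers a systematic way to do this: the cyclopropane carbon **C1**
carries the aryl fragment (installed by Suzuki–Miyaura coupling of a
boron handle) and the ring nitrogen **N2** carries a medicinal-chemistry
capping group (sulfonamide, amide, alkyl, aryl).  Because the bicyclic
core is rigid, each scaffold presents its two substituents along a
well-defined pair of **exit vectors**.

`exitvec` implements the whole design phase of that platform:

1. **Enumeration** of every symmetry-distinct amine + cyclopropane
   scaffold (brute force over fusion bonds, spiro atoms and handle
   positions; diastereomers kept, enantiomer pairs collapsed) — 26
   scaffolds, plus a tropane-derived block, for 27 in total.
2. **Virtual elaboration**: attachment-point graph edits place an aryl
   fragment at C1 and a cap at N2, tracking the four vector-defining
   atoms through every transformation.
3. **Conformer generation** (RDKit ETKDGv3 distance geometry + MMFF94
   minimisation) to find each compound's lowest-energy conformation,
   or ingestion of user-supplied 3D coordinates (e.g. X-ray models).
4. **Exit-vector analysis**: for the four atoms red–orange–green–blue
   (cap atom, N2, C1, fragment atom),

   * *r* = |C1 − N2|, the through-space distance between the variation
     points (Å),
   * *θ* = the unsigned dihedral of the red–orange–green–blue sequence,
     folded into [0°, 180°] — the angle between the planes spanned by
     the two exit vectors and the C1–N2 axis.

   A scatter of *r* vs *θ* (the exit-vector plot) maps the 3D chemical
   space the scaffold set can reach; a maximin picker selects diverse
   subsets.
5. **Property profiling**: MW, Crippen clogP and Fsp³ with the two
   design filters — "Rule-of-Two" for building blocks (MW < 200,
   clogP < 2) and lead-like space for elaborated compounds
   (−1 < clogP < 3, 200–350 Da).

All required structures (building blocks `1a`–`1i`, the pyrimidin-5-yl
fragment, the four caps, a set of fragment-style aryls) ship with the
package as annotated SMILES registries; nothing is downloaded.

## Worked example

Enumerate the design set, elaborate the nine named blocks into their
pyrimidine methanesulfonamides, and measure the exit vectors:

```python
import exitvec
from exitvec import elaboration, conformers

scaffolds = exitvec.augment_with_tropane(exitvec.enumerate_scaffolds())
print(len(scaffolds))                      # 27

blocks = exitvec.load_registry("building_blocks")
mapping, virtual_only = exitvec.match_named_blocks(scaffolds, blocks)
print(len(mapping), len(virtual_only))     # 9 18

frag  = [e for e in exitvec.load_registry("fragments") if e.id == "pyrimidin-5-yl"]
mesyl = [e for e in exitvec.load_registry("caps") if e.id == "mesyl"]
library = elaboration.enumerate_library([mapping[k] for k in sorted(mapping)], frag, mesyl)
ensembles = {c.compound_id: conformers.embed_and_minimize(c) for c in library}
table = exitvec.vectors_for_library(library, ensembles)
print(table[["compound_id", "r_angstrom", "theta_degrees"]].round(2).to_string(index=False))
```

which prints (seed 42, 200 embeddings per compound):

```
                                compound_id  r_angstrom  theta_degrees
  azetidine-s3-me-none~pyrimidin-5-yl~mesyl        3.51          68.80
 piperidine-f23-ap-exo~pyrimidin-5-yl~mesyl        2.63          55.49
 piperidine-f34-ap-exo~pyrimidin-5-yl~mesyl        3.10          66.46
 piperidine-s4-me-none~pyrimidin-5-yl~mesyl        4.40         122.61
pyrrolidine-f23-j2-cis~pyrimidin-5-yl~mesyl        1.50          83.61
pyrrolidine-f34-ap-exo~pyrimidin-5-yl~mesyl        2.96         180.00
pyrrolidine-s3-me-anti~pyrimidin-5-yl~mesyl        3.77         176.82
 pyrrolidine-s3-me-syn~pyrimidin-5-yl~mesyl        3.80          51.52
    tropane-t3-me-anti~pyrimidin-5-yl~mesyl        4.34          75.80
```

The nine compounds span r from **1.50 Å** — forced to a C–N single-bond
length because C1 and N2 are directly bonded in the junction-handle
pyrrolidine scaffold — up to **4.40 Å** for the spiro piperidine, with θ
covering 50°–180°: each building block presents a distinct 3D vector.

The same analysis is available from the shell:

```bash
exitvec enumerate -o scaffolds.csv          # 26 + tropane = 27
exitvec elaborate --scaffolds scaffolds.csv -o library.csv
exitvec vectors   --library library.csv -o exit_vectors.csv
exitvec profile   --input library.csv -o properties.csv
exitvec pipeline  -o run/                   # everything + JSON manifest
```

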