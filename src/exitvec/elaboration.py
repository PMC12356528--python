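"""Virtual elaboration: aryl attachment at C1 and N-capping at N2.

The two transformations of the synthesis phase — Suzuki–Miyaura
cross-coupling of the boron handle with an aryl bromide, and
N-functionalisation of the freed amine — are modelled as attachment-point
graph edits: a new C–C bond from C1 to the fragment's attachment atom
and a new N–X bond from N2 to the cap's attachment atom, each displacing
one hydrogen.  No boron or halide chemistry is represented; coupling is
taken as configuration-retentive, so the scaffold's stereocentres pass
through unchanged.

Bond formation at C1 goes through the scaffold's methyl-probe surrogate
(the probe carbon is swapped for the incoming fragment atom with
``Chem.molzip``), which is what preserves the spiro syn/anti and apex
exo/endo relative configurations that the free scaffold cannot express.

The four vector-defining atoms are tracked by atom maps through every
edit: C1 (map 1, "green"), N2 (map 2, "orange"), the fragment atom
bonded to C1 (map 3, "blue") and the cap atom bonded to N2 (map 4,
"red").
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
from rdkit import Chem

from . import _chem
from ._chem import ChemistryError, MAP_BLUE, MAP_C1, MAP_N2, MAP_RED
from .enumeration import ScaffoldSpec
from .registry import RegistryEntry


@dataclass(frozen=True)
class ElaboratedCompound:
    """A scaffold with an aryl fragment at C1 and (optionally) a cap at N2."""

    compound_id: str
    structure: str
    scaffold_id: str
    fragment_id: str
    cap_id: str | None = None

    def mol(self) -> Chem.Mol:
        return _chem.mol_from_smiles(self.structure)

    @property
    def atom_indices(self) -> dict[str, int | None]:
        """Indices of the four vector-defining atoms in :meth:`mol` order."""
        mol = self.mol()
        out = {}
        for role, num in (("atom_c1", MAP_C1), ("atom_n2", MAP_N2),
                          ("atom_blue", MAP_BLUE), ("atom_red", MAP_RED)):
            hits = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() == num]
            out[role] = hits[0] if hits else None
        return out


def _attachment_atom(entry: RegistryEntry) -> tuple[Chem.Mol, int]:
    mol = entry.mol()
    n = _chem.count_maps(mol, _chem.MAP_C1)
    if n != 1:
        raise ChemistryError(
            f"{entry.role} {entry.id!r} must have exactly one attachment point, found {n}"
        )
    return mol, _chem.find_map(mol, _chem.MAP_C1)


def _take_hydrogen(atom: Chem.Atom, context: str) -> None:
    """Remove one H (implicit or explicit) to free a valence."""
    if atom.GetTotalNumHs() < 1:
        raise ChemistryError(context)
    if atom.GetNumExplicitHs() > 0:
        atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
    else:
        atom.SetNoImplicit(False)


_ZIP_FRAGMENT = 91
_ZIP_CAP = 92


def attach_fragment(scaffold: ScaffoldSpec, fragment: RegistryEntry) -> ElaboratedCompound:
    """Form the C1–aryl bond, standing in for the cross-coupling step."""
    if fragment.is_hydrogen:
        return ElaboratedCompound(
            compound_id=scaffold.scaffold_id,
            structure=scaffold.structure,
            scaffold_id=scaffold.scaffold_id,
            fragment_id=fragment.id,
        )
    frag_mol, frag_at = _attachment_atom(fragment)

    # scaffold side: swap the probe methyl for a labelled dummy at C1
    rw = Chem.RWMol(scaffold.probe_mol())
    c1 = _chem.find_map(rw, MAP_C1)
    probe = _chem.probe_neighbor(rw, c1)
    dummy = rw.GetAtomWithIdx(probe)
    dummy.SetAtomicNum(0)
    dummy.SetAtomMapNum(_ZIP_FRAGMENT)
    dummy.SetNoImplicit(True)
    dummy.SetNumExplicitHs(0)
    scaf = rw.GetMol()
    Chem.SanitizeMol(scaf)

    # fragment side: labelled dummy on the attachment atom
    frw = Chem.RWMol(frag_mol)
    atom = frw.GetAtomWithIdx(frag_at)
    _take_hydrogen(atom, f"fragment {fragment.id!r} attachment atom has no substitutable H")
    atom.SetAtomMapNum(MAP_BLUE)
    d = frw.AddAtom(Chem.Atom(0))
    frw.GetAtomWithIdx(d).SetAtomMapNum(_ZIP_FRAGMENT)
    frw.AddBond(frag_at, d, Chem.BondType.SINGLE)
    frag = frw.GetMol()
    Chem.SanitizeMol(frag)

    product = Chem.molzip(Chem.CombineMols(scaf, frag))
    Chem.SanitizeMol(product)
    return ElaboratedCompound(
        compound_id=f"{scaffold.scaffold_id}~{fragment.id}",
        structure=Chem.MolToSmiles(product),
        scaffold_id=scaffold.scaffold_id,
        fragment_id=fragment.id,
    )


def attach_cap(compound: ElaboratedCompound, cap: RegistryEntry) -> ElaboratedCompound:
    """Form the N2–cap bond (sulfonyl, acyl, alkyl and aryl caps alike)."""
    if compound.cap_id is not None:
        raise ChemistryError(f"compound {compound.compound_id!r} is already capped")
    if cap.is_hydrogen:
        return replace(compound, cap_id=cap.id)
    cap_mol, cap_at = _attachment_atom(cap)

    rw = Chem.RWMol(compound.mol())
    n2 = _chem.find_map(rw, MAP_N2)
    natom = rw.GetAtomWithIdx(n2)
    if natom.GetTotalNumHs() < 1:
        raise ChemistryError(
            f"N2 of {compound.compound_id!r} has no hydrogen: not a free amine"
        )
    _take_hydrogen(natom, "N2 has no substitutable H")

    crw = Chem.RWMol(cap_mol)
    atom = crw.GetAtomWithIdx(cap_at)
    _take_hydrogen(atom, f"cap {cap.id!r} attachment atom has no substitutable H")
    atom.SetAtomMapNum(MAP_RED)

    product = Chem.RWMol(Chem.CombineMols(rw.GetMol(), crw.GetMol()))
    product.AddBond(n2, rw.GetMol().GetNumAtoms() + cap_at, Chem.BondType.SINGLE)
    mol = product.GetMol()
    Chem.SanitizeMol(mol)
    return ElaboratedCompound(
        compound_id=f"{compound.compound_id}~{cap.id}",
        structure=Chem.MolToSmiles(mol),
        scaffold_id=compound.scaffold_id,
        fragment_id=compound.fragment_id,
        cap_id=cap.id,
    )


def elaborate(scaffold: ScaffoldSpec, fragment: RegistryEntry, cap: RegistryEntry) -> ElaboratedCompound:
    return attach_cap(attach_fragment(scaffold, fragment), cap)


def enumerate_library(
    scaffolds: list[ScaffoldSpec],
    fragments: list[RegistryEntry],
    caps: list[RegistryEntry],
) -> list[ElaboratedCompound]:
    """Full scaffold x fragment x cap grid, deduplicated by canonical structure.

    Order is deterministic: the grid is traversed in input order and the
    first occurrence of each distinct product is kept.
    """
    out: list[ElaboratedCompound] = []
    seen: set[str] = set()
    for scaffold in scaffolds:
        for fragment in fragments:
            core = attach_fragment(scaffold, fragment)
            for cap in caps:
                product = attach_cap(core, cap)
                key = Chem.MolToSmiles(_chem.strip_maps(product.mol()))
                if key in seen:
                    continue
                seen.add(key)
                out.append(product)
    return out


def library_table(library: list[ElaboratedCompound]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                compound_id=c.compound_id,
                scaffold_id=c.scaffold_id,
                fragment_id=c.fragment_id,
                cap_id=c.cap_id,
                canonical_structure=c.structure,
            )
            for c in library
        ]
    )


def write_library(library: list[ElaboratedCompound], csv_path, smiles_path=None) -> None:
    library_table(library).to_csv(csv_path, index=False)
    if smiles_path is not None:
        with open(smiles_path, "w") as fh:
            for c in library:
                fh.write(f"{c.structure}\t{c.compound_id}\n")
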