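"""Shared RDKit helpers: mapped-atom bookkeeping, canonicalization and
3D classification of ring-fusion stereochemistry.

Attachment points are encoded as atom-map numbers on real atoms (no dummy
atoms), so they survive canonicalization:

=====  =======================================================
map    role
=====  =======================================================
1      C1, the cyclopropane carbon that carries the aryl fragment
2      N2, the ring nitrogen that carries the cap
3      first fragment atom bonded to C1 ("blue")
4      first cap atom bonded to N2 ("red")
=====  =======================================================
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.rdchem import ChiralType

RDLogger.DisableLog("rdApp.*")

MAP_C1 = 1
MAP_N2 = 2
MAP_BLUE = 3
MAP_RED = 4

#: seed for the single-conformer embeddings used to classify diastereomers;
#: classification only reads signs of distances to a plane, so any
#: successfully embedded conformer gives the same answer.
CLASSIFY_SEED = 1910

CW = ChiralType.CHI_TETRAHEDRAL_CW
CCW = ChiralType.CHI_TETRAHEDRAL_CCW


class ChemistryError(ValueError):
    """Raised for unparseable or chemically inconsistent structures."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse and sanitize, raising :class:`ChemistryError` with diagnostics."""
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise ChemistryError(f"unparseable structure: {smiles!r}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # noqa: BLE001 - rdkit raises several types
        raise ChemistryError(f"structure failed valence sanitization: {smiles!r} ({exc})") from exc
    return mol


def canonical(smiles_or_mol) -> str:
    mol = smiles_or_mol
    if isinstance(mol, str):
        mol = mol_from_smiles(mol)
    return Chem.MolToSmiles(mol)


def strip_maps(mol: Chem.Mol) -> Chem.Mol:
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return out


def find_map(mol: Chem.Mol, map_num: int) -> int:
    """Index of the unique atom with the given map number."""
    hits = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() == map_num]
    if len(hits) != 1:
        raise ChemistryError(
            f"expected exactly one atom with map {map_num}, found {len(hits)} "
            f"in {Chem.MolToSmiles(mol)}"
        )
    return hits[0]


def count_maps(mol: Chem.Mol, map_num: int) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomMapNum() == map_num)


def mirror(mol: Chem.Mol) -> Chem.Mol:
    """Mirror image: invert every tetrahedral parity (no stereobonds here)."""
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        if atom.GetChiralTag() == CW:
            atom.SetChiralTag(CCW)
        elif atom.GetChiralTag() == CCW:
            atom.SetChiralTag(CW)
    return out


def enantiomer_representative(mol: Chem.Mol) -> str:
    """Canonical SMILES of the lexicographically smaller enantiomer.

    Collapsing enantiomer pairs to a single deterministic representative
    mirrors plotting only one enantiomeric series: r and theta (unsigned)
    are identical for both members of a pair.
    """
    return min(Chem.MolToSmiles(mol), Chem.MolToSmiles(mirror(mol)))


def embed_single(mol: Chem.Mol, seed: int | None = None) -> Chem.Mol | None:
    """One ETKDG conformer with hydrogens, or None if embedding fails.

    Used for diastereomer classification; infeasible stereochemistry
    (e.g. trans ring fusion onto a cyclopropane) fails here.  The seed
    defaults to the module-level ``CLASSIFY_SEED`` (read at call time).
    """
    molh = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = CLASSIFY_SEED if seed is None else seed
    if AllChem.EmbedMolecule(molh, params) < 0:
        return None
    return molh


def cyclopropane_ring(mol: Chem.Mol) -> tuple[int, ...]:
    rings = [r for r in mol.GetRingInfo().AtomRings() if len(r) == 3]
    if len(rings) != 1:
        raise ChemistryError(
            f"expected exactly one cyclopropane, found {len(rings)} in {Chem.MolToSmiles(mol)}"
        )
    return rings[0]


def _positions(mol: Chem.Mol) -> np.ndarray:
    return mol.GetConformer().GetPositions()


def plane_sides(mol: Chem.Mol, plane_atoms, query_atoms) -> list[float]:
    """Signed distances of query atoms from the plane through three atoms."""
    pos = _positions(mol)
    p = pos[list(plane_atoms)]
    normal = np.cross(p[1] - p[0], p[2] - p[0])
    normal = normal / np.linalg.norm(normal)
    centroid = p.mean(axis=0)
    return [float(np.dot(pos[q] - centroid, normal)) for q in query_atoms]


def bestfit_plane_sides(mol: Chem.Mol, plane_atoms, query_atoms) -> list[float]:
    """Signed distances from the least-squares plane through `plane_atoms`."""
    pos = _positions(mol)
    p = pos[list(plane_atoms)]
    centroid = p.mean(axis=0)
    _, _, vt = np.linalg.svd(p - centroid)
    normal = vt[2]
    return [float(np.dot(pos[q] - centroid, normal)) for q in query_atoms]


def probe_neighbor(mol: Chem.Mol, handle_idx: int) -> int:
    """The exocyclic carbon bonded to C1 (probe methyl or fragment atom)."""
    ring = cyclopropane_ring(mol)
    for nb in mol.GetAtomWithIdx(handle_idx).GetNeighbors():
        if nb.GetAtomicNum() == 6 and nb.GetIdx() not in ring:
            # junction handles also neighbour amine-ring carbons; the probe
            # is the one outside every ring
            if not nb.IsInRing():
                return nb.GetIdx()
    raise ChemistryError("C1 carries no exocyclic carbon substituent")


def classify_diastereomer(molh: Chem.Mol, topology: str) -> str | None:
    """Relative-configuration tag of an embedded, C1-substituted scaffold.

    Returns one of ``cis`` (fused, handle on a ring-junction carbon),
    ``exo``/``endo`` (fused, handle on the cyclopropane apex), ``syn``/
    ``anti`` (spiro with a stereogenic spiro carbon; tropane relative to
    the two-carbon bridge), ``none`` (spiro with symmetric amine arms: no
    relative descriptor applies), or None for geometrically infeasible
    arrangements (trans ring fusion).
    """
    cp = cyclopropane_ring(molh)
    n2 = find_map(molh, MAP_N2)
    c1 = find_map(molh, MAP_C1)
    probe = probe_neighbor(molh, c1)
    rings = molh.GetRingInfo().AtomRings()

    if topology == "fused":
        amine = next(r for r in rings if n2 in r and len(r) > 3)
        junctions = [i for i in cp if i in amine]
        apex = next(i for i in cp if i not in amine)
        ring_neighbors = []
        for j in junctions:
            for nb in molh.GetAtomWithIdx(j).GetNeighbors():
                if nb.GetIdx() in amine and nb.GetIdx() not in cp:
                    ring_neighbors.append(nb.GetIdx())
        sides = plane_sides(molh, cp, ring_neighbors)
        if (sides[0] > 0) != (sides[1] > 0):
            return None  # trans fusion: not closable without severe distortion
        if c1 == apex:
            probe_side, = plane_sides(molh, cp, [probe])
            ring_side = float(np.mean(sides))
            return "exo" if (probe_side > 0) != (ring_side > 0) else "endo"
        return "cis"

    if topology == "spiro":
        spiro = next(i for i in cp if i != c1 and any(i in r for r in rings if len(r) > 3))
        arms = [nb.GetIdx() for nb in molh.GetAtomWithIdx(spiro).GetNeighbors() if nb.GetIdx() not in cp]
        dist = {
            a: (0 if a == n2 else len(Chem.GetShortestPath(molh, a, n2)) - 1)
            for a in arms
        }
        if dist[arms[0]] == dist[arms[1]]:
            return "none"
        proximal = min(arms, key=dist.get)
        probe_side, prox_side = plane_sides(molh, cp, [probe, proximal])
        return "syn" if (probe_side > 0) == (prox_side > 0) else "anti"

    if topology == "tropane":
        # handle position relative to the two-carbon bridge, judged against
        # the mean plane of the six-membered ring that contains N
        six = next(r for r in rings if len(r) == 6 and n2 in r)
        bridge = [
            a.GetIdx()
            for a in molh.GetAtoms()
            if a.GetAtomicNum() == 6
            and a.IsInRing()
            and a.GetIdx() not in six
            and a.GetIdx() not in cp
        ]
        sides = bestfit_plane_sides(molh, six, [probe] + bridge)
        probe_side, bridge_side = sides[0], float(np.mean(sides[1:]))
        return "syn" if (probe_side > 0) == (bridge_side > 0) else "anti"

    raise ValueError(f"unknown topology {topology!r}")


def remove_probe(probe_mol: Chem.Mol) -> Chem.Mol:
    """Free (hydrogen-capped) scaffold from its methyl-probe surrogate.

    Stereocentres that exist only by virtue of the C1 substituent (spiro
    pairs, apex exo/endo) lose their tags here; the stereo tag field keeps
    that information.
    """
    rw = Chem.RWMol(probe_mol)
    c1 = find_map(rw, MAP_C1)
    probe = probe_neighbor(rw, c1)
    rw.RemoveAtom(probe)
    handle = rw.GetAtomWithIdx(c1 if c1 < probe else c1 - 1)
    handle.SetNumExplicitHs(0)
    handle.SetNoImplicit(False)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return mol
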