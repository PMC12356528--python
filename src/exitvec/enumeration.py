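"""Brute-force enumeration of bifunctional cyclopropane–cyclic-amine scaffolds.

The design universe combines a cyclic secondary amine (azetidine,
pyrrolidine or piperidine) with a cyclopropane that either shares an
edge with the amine ring (fused) or a single atom (spiro).  One
cyclopropane carbon, C1, is the aryl-fragment handle; the ring nitrogen,
N2, is the capping handle.  Enumeration is a plain brute force over

* every C–C bond of the amine ring as a fusion bond,
* every amine ring carbon as a spiro atom,
* every substitutable cyclopropane carbon as the handle C1,

followed by deduplication under molecular symmetry (canonical SMILES of
the methyl-probe form) and expansion into relative-configuration
diastereomers.  Stereochemistry is realised concretely: every parity
assignment of the candidate stereocentres is embedded in 3D and
classified geometrically, which rejects trans ring fusions outright and
labels each survivor (cis / exo / endo / syn / anti).

By default the concave-face (endo) diastereomers of fused apex handles
are excluded: an endo substituent points into the fold of the bicycle
and none of the physically realised building blocks is endo.  Under this
convention the azetidine/pyrrolidine/piperidine universe contains
exactly 26 scaffolds; ``include_endo=True`` raises it to 31 and the
per-cell reconciliation table localises the difference.

The tropane scaffold (spiro cyclopropane on the nortropane 3-position)
lies outside that universe and is appended by
:func:`augment_with_tropane`, giving the 27-scaffold design set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd
from rdkit import Chem

from . import _chem
from ._chem import CCW, CW, ChemistryError, MAP_C1, MAP_N2
from .registry import RegistryEntry

RING_NAMES = {4: "azetidine", 5: "pyrrolidine", 6: "piperidine"}
TOPOLOGIES = ("fused", "spiro")

#: preference order used when diastereomers are collapsed to one per cell
_TAG_ORDER = ("cis", "exo", "syn", "anti", "endo", "none")


@dataclass(frozen=True)
class ScaffoldSpec:
    """One symmetry-distinct bifunctional scaffold.

    ``structure`` is the free scaffold (handle H-capped, amine N–H) with
    atom maps 1 (C1) and 2 (N2).  ``probe`` is the stereochemically
    complete surrogate with a methyl group in the C1 substituent
    position; it is the identity used for deduplication, matching and
    elaboration, because spiro and apex diastereomers are degenerate
    without a C1 substituent.
    """

    scaffold_id: str
    ring_size: int
    topology: str
    attachment_locants: tuple[int, ...]
    handle_position: str
    stereo: str
    structure: str
    probe: str

    def mol(self) -> Chem.Mol:
        return _chem.mol_from_smiles(self.structure)

    def probe_mol(self) -> Chem.Mol:
        return _chem.mol_from_smiles(self.probe)


def _make_probe(ring_size: int, topology: str, bond: tuple[int, int] | None,
                spiro_at: int | None, handle: str) -> Chem.Mol:
    """Constitution of one placement, methyl probe attached, maps set."""
    rw = Chem.RWMol()
    ring = [rw.AddAtom(Chem.Atom(7 if i == 0 else 6)) for i in range(ring_size)]
    for i in range(ring_size):
        rw.AddBond(ring[i], ring[(i + 1) % ring_size], Chem.BondType.SINGLE)
    if topology == "fused":
        a, b = bond
        apex = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(ring[a], apex, Chem.BondType.SINGLE)
        rw.AddBond(ring[b], apex, Chem.BondType.SINGLE)
        handle_idx = {"junction_a": ring[a], "junction_b": ring[b], "apex": apex}[handle]
    else:
        x = rw.AddAtom(Chem.Atom(6))
        y = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(ring[spiro_at], x, Chem.BondType.SINGLE)
        rw.AddBond(ring[spiro_at], y, Chem.BondType.SINGLE)
        rw.AddBond(x, y, Chem.BondType.SINGLE)
        handle_idx = x
    probe = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(handle_idx, probe, Chem.BondType.SINGLE)
    rw.GetAtomWithIdx(handle_idx).SetAtomMapNum(MAP_C1)
    rw.GetAtomWithIdx(ring[0]).SetAtomMapNum(MAP_N2)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _constitutions(ring_sizes, topologies):
    """All placements, deduplicated by canonical (stereo-free) probe SMILES."""
    seen = {}
    for n in sorted(ring_sizes):
        for topo in (t for t in TOPOLOGIES if t in topologies):
            if topo == "fused":
                placements = [
                    (bond, None, handle)
                    for bond in [(i, i + 1) for i in range(1, n - 1)]
                    for handle in ("junction_a", "junction_b", "apex")
                ]
            else:
                placements = [(None, c, "spiro_methylene") for c in range(1, n)]
            for bond, spiro_at, handle in placements:
                mol = _make_probe(n, topo, bond, spiro_at, handle)
                key = Chem.MolToSmiles(mol)  # no stereo yet: constitution key
                if key in seen:
                    continue
                if topo == "fused":
                    locants = (bond[0] + 1, bond[1] + 1)
                    hpos = "apex" if handle == "apex" else f"junction@{bond[0 if handle == 'junction_a' else 1] + 1}"
                else:
                    locants = (spiro_at + 1,)
                    hpos = "methylene"
                seen[key] = dict(ring_size=n, topology=topo, locants=locants,
                                 handle_position=hpos, mol=mol)
    return list(seen.values())


def _stereo_candidates(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.IsInRing() and len(a.GetNeighbors()) >= 3
    ]


def _wanted_tags(con) -> set[str]:
    if con["topology"] == "fused":
        return {"exo", "endo"} if con["handle_position"] == "apex" else {"cis"}
    # spiro: stereogenic iff the two amine-ring arms of the spiro atom
    # reach N by paths of different length (graph property, no 3D needed)
    mol = con["mol"]
    n2 = _chem.find_map(mol, MAP_N2)
    cp = _chem.cyclopropane_ring(mol)
    spiro = next(
        i for i in cp
        if any(i in r for r in mol.GetRingInfo().AtomRings() if len(r) > 3)
    )
    arms = [nb.GetIdx() for nb in mol.GetAtomWithIdx(spiro).GetNeighbors() if nb.GetIdx() not in cp]
    dist = {a: (0 if a == n2 else len(Chem.GetShortestPath(mol, a, n2)) - 1) for a in arms}
    return {"none"} if dist[arms[0]] == dist[arms[1]] else {"syn", "anti"}


def _realise_stereo(con) -> dict[str, str]:
    """tag -> enantiomer-collapsed canonical probe SMILES for one constitution."""
    mol0 = con["mol"]
    cands = _stereo_candidates(mol0)
    wanted = _wanted_tags(con)
    found: dict[str, str] = {}
    seen: set[str] = set()
    for combo in itertools.product((CW, CCW), repeat=len(cands)):
        mol = Chem.Mol(mol0)
        for idx, tag in zip(cands, combo):
            mol.GetAtomWithIdx(idx).SetChiralTag(tag)
        smi = Chem.MolToSmiles(mol)
        if smi in seen:
            continue
        seen.add(smi)
        parsed = _chem.mol_from_smiles(smi)
        embedded = _chem.embed_single(parsed)
        if embedded is None:
            continue  # geometrically infeasible (e.g. trans fusion)
        label = _chem.classify_diastereomer(embedded, con["topology"])
        if label is None or label not in wanted:
            continue
        rep = _chem.enantiomer_representative(parsed)
        found.setdefault(label, rep)
        if set(found) == wanted:
            break
    return found


_HANDLE_CODE = {"apex": "ap", "methylene": "me"}


def _spec_from(con, tag: str, probe_smi: str) -> ScaffoldSpec:
    probe = _chem.mol_from_smiles(probe_smi)
    structure = Chem.MolToSmiles(_chem.remove_probe(probe))
    hcode = _HANDLE_CODE.get(con["handle_position"], "j" + con["handle_position"].split("@")[-1])
    name = RING_NAMES.get(con["ring_size"], "ring") if con["topology"] != "tropane" else "tropane"
    sid = f"{name}-{con['topology'][0]}{''.join(map(str, con['locants']))}-{hcode}-{tag}"
    return ScaffoldSpec(
        scaffold_id=sid,
        ring_size=con["ring_size"],
        topology=con["topology"],
        attachment_locants=con["locants"],
        handle_position=con["handle_position"],
        stereo=tag,
        structure=structure,
        probe=probe_smi,
    )


_CACHE: dict[tuple, list[ScaffoldSpec]] = {}


def enumerate_scaffolds(
    ring_sizes: set[int] = frozenset({4, 5, 6}),
    topologies: set[str] = frozenset(TOPOLOGIES),
    include_diastereomers: bool = True,
    include_endo: bool = False,
) -> list[ScaffoldSpec]:
    """All symmetry-distinct scaffolds, one representative per enantiomer pair.

    Diastereomers are kept distinct when ``include_diastereomers`` is set;
    otherwise one representative per constitution is kept.  Output is
    sorted deterministically by canonical structure.
    """
    ring_sizes = frozenset(ring_sizes)
    topologies = frozenset(topologies)
    if not ring_sizes <= {4, 5, 6}:
        raise ValueError(f"ring_sizes must be a subset of {{4, 5, 6}}, got {sorted(ring_sizes)}")
    if not topologies <= set(TOPOLOGIES):
        raise ValueError(f"topologies must be a subset of {TOPOLOGIES}, got {sorted(topologies)}")
    key = (ring_sizes, topologies, include_diastereomers, include_endo)
    if key in _CACHE:
        return list(_CACHE[key])

    specs: list[ScaffoldSpec] = []
    for con in _constitutions(ring_sizes, topologies):
        tags = _realise_stereo(con)
        if not include_endo:
            tags.pop("endo", None)
        if not include_diastereomers and len(tags) > 1:
            keep = next(t for t in _TAG_ORDER if t in tags)
            tags = {keep: tags[keep]}
        for tag in sorted(tags):
            specs.append(_spec_from(con, tag, tags[tag]))
    specs.sort(key=lambda s: (s.structure, s.stereo))
    _CACHE[key] = specs
    return list(specs)


def _tropane_probe() -> Chem.Mol:
    """Spiro cyclopropane at C3 of 8-azabicyclo[3.2.1]octane, probe methyl."""
    rw = Chem.RWMol()
    atoms = [rw.AddAtom(Chem.Atom(s)) for s in
             (6, 6, 6, 6, 6, 6, 6, 7, 6, 6, 6)]  # C1..C7, N8, X, Y, probe
    for a, b in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 0),
                 (0, 7), (4, 7), (2, 8), (2, 9), (8, 9), (8, 10)]:
        rw.AddBond(atoms[a], atoms[b], Chem.BondType.SINGLE)
    rw.GetAtomWithIdx(8).SetAtomMapNum(MAP_C1)
    rw.GetAtomWithIdx(7).SetAtomMapNum(MAP_N2)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def tropane_scaffold() -> ScaffoldSpec:
    """The single tropane scaffold: handle anti to the two-carbon bridge.

    The cyclopropanation that forms this block is face-selective, with
    the carbene delivered opposite the bridge, so only the anti
    diastereomer is realisable and only it enters the design set.
    """
    con = dict(ring_size=6, topology="tropane", locants=(3,),
               handle_position="methylene", mol=_tropane_probe())
    cands = _stereo_candidates(con["mol"])
    for combo in itertools.product((CW, CCW), repeat=len(cands)):
        mol = Chem.Mol(con["mol"])
        for idx, tag in zip(cands, combo):
            mol.GetAtomWithIdx(idx).SetChiralTag(tag)
        smi = Chem.MolToSmiles(mol)
        parsed = _chem.mol_from_smiles(smi)
        embedded = _chem.embed_single(parsed)
        if embedded is None:
            continue
        if _chem.classify_diastereomer(embedded, "tropane") == "anti":
            return _spec_from(con, "anti", _chem.enantiomer_representative(parsed))
    raise ChemistryError("could not realise the anti tropane diastereomer")


def augment_with_tropane(scaffolds: list[ScaffoldSpec]) -> list[ScaffoldSpec]:
    """Append the tropane scaffold; idempotent under repeated application."""
    trop = tropane_scaffold()
    if any(s.probe == trop.probe for s in scaffolds):
        return list(scaffolds)
    return list(scaffolds) + [trop]


def match_named_blocks(
    scaffolds: list[ScaffoldSpec], registry: list[RegistryEntry]
) -> tuple[dict[str, ScaffoldSpec], list[ScaffoldSpec]]:
    """Map registry building blocks onto enumerated scaffolds one-to-one.

    Matching is by enantiomer-collapsed canonical probe SMILES (falling
    back to free structure + stereo tag for entries without a probe).
    Returns ``(mapping, virtual_only)`` where ``virtual_only`` lists the
    scaffolds not covered by any named block.  A registry entry with no
    match signals an enumeration-convention bug and raises.
    """
    mapping: dict[str, ScaffoldSpec] = {}
    used: set[str] = set()
    for entry in registry:
        if entry.role != "building_block":
            continue
        hit = None
        if entry.probe:
            target = _chem.enantiomer_representative(entry.probe_mol())
            hit = next((s for s in scaffolds if s.probe == target), None)
        else:
            target = (_chem.canonical(entry.structure), entry.stereo)
            hit = next((s for s in scaffolds
                        if (s.structure, s.stereo) == target), None)
        if hit is None:
            raise ChemistryError(
                f"registry block {entry.id!r} matches no enumerated scaffold; "
                "the enumeration conventions do not cover it"
            )
        if hit.scaffold_id in used:
            raise ChemistryError(
                f"registry block {entry.id!r} maps onto already-matched scaffold {hit.scaffold_id}"
            )
        used.add(hit.scaffold_id)
        mapping[entry.id] = hit
    virtual_only = [s for s in scaffolds if s.scaffold_id not in used]
    return mapping, virtual_only


def reconciliation_table(
    ring_sizes: set[int] = frozenset({4, 5, 6}),
    topologies: set[str] = frozenset(TOPOLOGIES),
) -> pd.DataFrame:
    """Per-cell scaffold counts under both apex-diastereomer conventions.

    One row per (ring size, topology, locants, handle position) cell with
    the diastereomer count excluding and including concave-face (endo)
    apex isomers.  This is the declared reconciliation mechanism: if a
    different convention is needed to match an external count, the cell
    where it acts is visible here.
    """
    rows = []
    for con in _constitutions(ring_sizes, topologies):
        tags = _realise_stereo(con)
        rows.append(
            dict(
                ring=RING_NAMES[con["ring_size"]],
                ring_size=con["ring_size"],
                topology=con["topology"],
                locants=",".join(map(str, con["locants"])),
                handle=con["handle_position"],
                tags="/".join(sorted(tags)),
                n_scaffolds=len([t for t in tags if t != "endo"]),
                n_with_endo=len(tags),
            )
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["ring_size", "topology", "locants", "handle"]).reset_index(drop=True)


def write_scaffolds(scaffolds: list[ScaffoldSpec], csv_path, smiles_path=None) -> None:
    """Write the enumerated set as CSV (and optionally a SMILES file)."""
    df = pd.DataFrame(
        [
            dict(
                id=s.scaffold_id,
                ring_size=s.ring_size,
                topology=s.topology,
                locants=",".join(map(str, s.attachment_locants)),
                handle_position=s.handle_position,
                stereo=s.stereo,
                canonical_structure=s.structure,
                probe=s.probe,
            )
            for s in scaffolds
        ]
    )
    df.to_csv(csv_path, index=False)
    if smiles_path is not None:
        with open(smiles_path, "w") as fh:
            for s in scaffolds:
                fh.write(f"{s.structure}\t{s.scaffold_id}\n")
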