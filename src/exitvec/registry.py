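"""Packaged registries of building blocks, fragments and caps.

Every structure the pipeline needs ships with the package as annotated
line notation (SMILES with atom-map attachment points), so the whole
design pipeline runs without any download:

* ``building_blocks`` — the nine bifunctional cyclopropane building
  blocks ``1a``–``1i``, stored as free scaffolds (amine N–H, handle
  carbon H-capped; the Boc and boronate handles of the synthesised
  precursors are abstracted away).  Map 1 marks C1, map 2 marks N2.
* ``fragments`` — aryl substituents standing in for cross-coupled aryl
  bromides; one mapped attachment atom each.
* ``caps`` — N-capping groups (methanesulfonyl, acetyl, methyl, phenyl);
  one mapped attachment atom each.
* ``fraglite_aryls`` — a set of small halogenated-fragment-style aryl
  substituents for larger virtual libraries.

Because the free scaffolds of a spiro diastereomer pair (``1d``/``1e``)
are identical once the handle carbon is H-capped, each building block
also carries a ``probe`` structure — the scaffold with a methyl group
standing where the C1 substituent will go — which is stereochemically
complete and serves as the identity used for matching and elaboration.
"""

from __future__ import annotations

import csv
import io
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem

from . import _chem
from ._chem import ChemistryError, MAP_C1, MAP_N2

ROLES = ("building_block", "fragment", "cap")
REGISTRY_NAMES = ("building_blocks", "fragments", "caps", "fraglite_aryls")

#: structures treated as "no substituent" placeholders by the elaboration step
HYDROGEN_PLACEHOLDER = "[H:1]"


@dataclass(frozen=True)
class RegistryEntry:
    """One registry structure with its attachment annotation."""

    id: str
    role: str
    structure: str
    stereo: str = "none"
    racemic: bool = False
    probe: str = ""
    notes: str = ""

    def mol(self) -> Chem.Mol:
        return _chem.mol_from_smiles(self.structure)

    def probe_mol(self) -> Chem.Mol:
        if not self.probe:
            raise ChemistryError(f"entry {self.id!r} has no probe structure")
        return _chem.mol_from_smiles(self.probe)

    @property
    def is_hydrogen(self) -> bool:
        return _chem.canonical(self.structure) == _chem.canonical(HYDROGEN_PLACEHOLDER)

    def validate(self) -> None:
        mol = self.mol()
        if self.role not in ROLES:
            raise ChemistryError(f"entry {self.id!r}: unknown role {self.role!r}")
        n_c1 = _chem.count_maps(mol, MAP_C1)
        n_n2 = _chem.count_maps(mol, MAP_N2)
        if self.role == "building_block":
            if n_c1 != 1 or n_n2 != 1:
                raise ChemistryError(
                    f"building block {self.id!r} must annotate exactly one C1 "
                    f"and one N2 attachment atom (got {n_c1} and {n_n2})"
                )
        else:
            if n_c1 != 1 or n_n2 != 0:
                raise ChemistryError(
                    f"{self.role} {self.id!r} must annotate exactly one attachment atom"
                )


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters for the randomized decorated-scaffold generator."""

    seed: int = 0
    n_random: int = 10
    ring_sizes: tuple[int, ...] = (4, 5, 6)

    def __post_init__(self):
        if self.n_random < 0:
            raise ValueError("n_random must be >= 0")
        if not set(self.ring_sizes) <= {4, 5, 6}:
            raise ValueError("ring_sizes must be a subset of {4, 5, 6}")


_FIELDS = ("id", "role", "structure", "stereo", "racemic", "probe", "notes")


def _parse_rows(text: str, source: str) -> list[RegistryEntry]:
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    entries = []
    seen = set()
    for row in reader:
        entry = RegistryEntry(
            id=row["id"],
            role=row["role"],
            structure=row["structure"],
            stereo=row.get("stereo") or "none",
            racemic=(row.get("racemic", "") or "").lower() in ("1", "true", "yes"),
            probe=row.get("probe") or "",
            notes=row.get("notes") or "",
        )
        if entry.id in seen:
            raise ChemistryError(f"duplicate id {entry.id!r} in registry {source}")
        seen.add(entry.id)
        entry.validate()
        entries.append(entry)
    return entries


def load_registry(name: str) -> list[RegistryEntry]:
    """Load a packaged registry by name, or any registry TSV by path."""
    path = Path(name)
    if path.suffix == ".tsv" and path.exists():
        return _parse_rows(path.read_text(), str(path))
    if name not in REGISTRY_NAMES:
        raise KeyError(
            f"unknown registry {name!r}; valid names: {', '.join(REGISTRY_NAMES)} "
            "(or a path to a .tsv file)"
        )
    text = resources.files("exitvec.data").joinpath(f"{name}.tsv").read_text()
    return _parse_rows(text, name)


def write_registry(entries: list[RegistryEntry], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_FIELDS)
        for e in entries:
            writer.writerow([e.id, e.role, e.structure, e.stereo,
                             "true" if e.racemic else "false", e.probe, e.notes])


def hydrogen_placeholder(role: str = "fragment") -> RegistryEntry:
    """Identity entry: attaching it leaves the scaffold unchanged."""
    return RegistryEntry(id="hydrogen", role=role, structure=HYDROGEN_PLACEHOLDER,
                         notes="identity placeholder")


_SUBSTITUENTS = ["F", "Cl", "C", "OC", "C#N"]


def generate_fixtures(cfg: FixtureConfig) -> list[RegistryEntry]:
    """Randomized decorated scaffolds for stress testing.

    Draws enumerated scaffolds for the requested ring sizes and sprinkles
    0–2 small substituents (F, Cl, Me, OMe, CN) onto ring CH positions
    away from the two attachment points.  Deterministic for a fixed seed.
    """
    from .enumeration import enumerate_scaffolds  # deferred: avoids cycle

    if cfg.n_random == 0:
        return []
    rng = random.Random(cfg.seed)
    pool = enumerate_scaffolds(ring_sizes=set(cfg.ring_sizes))
    if not pool:
        return []
    out = []
    for i in range(cfg.n_random):
        spec = rng.choice(pool)
        mol = Chem.RWMol(_chem.mol_from_smiles(spec.structure))
        mapped = {_chem.find_map(mol, MAP_C1), _chem.find_map(mol, MAP_N2)}
        sites = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0 and a.GetIdx() not in mapped
        ]
        for _ in range(rng.randint(0, 2)):
            if not sites:
                break
            site = rng.choice(sites)
            sub = Chem.MolFromSmiles(rng.choice(_SUBSTITUENTS))
            combined = Chem.RWMol(Chem.CombineMols(mol, sub))
            combined.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
            try:
                test = combined.GetMol()
                Chem.SanitizeMol(test)
            except Exception:  # noqa: BLE001
                continue
            mol = Chem.RWMol(test)
        final = mol.GetMol()
        Chem.SanitizeMol(final)
        out.append(
            RegistryEntry(
                id=f"fx-{i:03d}",
                role="building_block",
                structure=Chem.MolToSmiles(final),
                stereo=spec.stereo,
                notes=f"random fixture from {spec.scaffold_id}",
            )
        )
    return out
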