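"""Conformer generation and ingestion of supplied 3D coordinates.

The exit-vector geometry is measured on the lowest-energy conformer of
each compound.  Conformers come from distance-geometry embedding
(ETKDGv3) followed by force-field minimisation — MMFF94 where the
molecule is parameterised, UFF as fallback — or from user-supplied 3D
structure files (SDF), e.g. crystallographic models.  Supplied files may
contain several models of the same compound; each becomes one conformer
with no energy assigned, and all of them are retained for analysis.

Defaults (200 embeddings, RMSD pruning at 0.5 Å, seed 42) are
conventional for molecules of this size (every design-set compound has
at most a handful of rotatable bonds) and are recorded in the ensemble's
``method`` tag for provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import _chem
from ._chem import ChemistryError
from .elaboration import ElaboratedCompound

DEFAULT_N_CONFS = 200
DEFAULT_SEED = 42
DEFAULT_PRUNE_RMS = 0.5
MIN_INTERATOMIC = 0.6  # Å, sanity floor


@dataclass
class ConformerEnsemble:
    """3D conformers of one compound with their force-field energies.

    ``mol`` holds the conformers (hydrogens included); atom indices of
    the parent heavy atoms are unchanged, so mapped-atom lookups work on
    it directly.  ``energies`` is None-free for computed ensembles; for
    supplied coordinates every energy is ``nan`` and ``lowest_index`` is
    0 by convention (all models are retained downstream anyway).
    """

    compound_id: str
    mol: Chem.Mol
    energies: np.ndarray
    method: str
    source: str = "computed"

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if self.mol.GetNumConformers() != len(self.energies):
            raise ValueError("energies and conformers must have equal length")
        if len(self.energies) < 1:
            raise ValueError("ensemble must contain at least one conformer")
        self._check_distances()

    def _check_distances(self) -> None:
        for conf in self.mol.GetConformers():
            pos = conf.GetPositions()
            delta = pos[:, None, :] - pos[None, :, :]
            dist = np.sqrt((delta**2).sum(-1))
            np.fill_diagonal(dist, np.inf)
            if dist.min() < MIN_INTERATOMIC:
                raise ChemistryError(
                    f"conformer of {self.compound_id!r} has interatomic distance "
                    f"{dist.min():.2f} Å below the {MIN_INTERATOMIC} Å sanity floor"
                )

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()

    @property
    def lowest_index(self) -> int:
        """Index of the minimum-energy conformer; ties and all-nan -> lowest index."""
        if np.all(np.isnan(self.energies)):
            return 0
        return int(np.nanargmin(self.energies))

    def coordinates(self, index: int) -> np.ndarray:
        return self.mol.GetConformer(self.mol.GetConformers()[index].GetId()).GetPositions()

    def atom_position(self, index: int, atom_idx: int) -> np.ndarray:
        return self.coordinates(index)[atom_idx]


def embed_and_minimize(
    compound: ElaboratedCompound | Chem.Mol,
    n_confs: int = DEFAULT_N_CONFS,
    seed: int = DEFAULT_SEED,
    prune_rms: float = DEFAULT_PRUNE_RMS,
    compound_id: str | None = None,
) -> ConformerEnsemble:
    """Distance-geometry embeddings, each minimised; deterministic per seed.

    RMSD pruning means the returned ensemble may hold fewer than
    ``n_confs`` members.  Raises if embedding produces nothing.
    """
    if n_confs < 1:
        raise ValueError("n_confs must be >= 1")
    if isinstance(compound, ElaboratedCompound):
        mol = compound.mol()
        cid = compound.compound_id
    else:
        mol = Chem.Mol(compound)
        cid = compound_id or Chem.MolToSmiles(compound)
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = prune_rms
    conf_ids = AllChem.EmbedMultipleConfs(molh, n_confs, params)
    if len(conf_ids) == 0:
        raise ChemistryError(f"embedding failed for {cid!r}")

    if AllChem.MMFFHasAllMoleculeParams(molh):
        forcefield = "MMFF94"
        results = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=2000)
    else:
        forcefield = "UFF"
        warnings.warn(f"{cid!r}: MMFF94 parameters missing, using UFF", stacklevel=2)
        results = AllChem.UFFOptimizeMoleculeConfs(molh, maxIters=2000)
    energies = np.array([e for _, e in results], dtype=float)
    method = f"ETKDGv3/{forcefield};n_confs={n_confs};prune_rms={prune_rms};seed={seed}"
    return ConformerEnsemble(compound_id=cid, mol=molh, energies=energies, method=method)


def load_coordinates(path, compound_id: str | None = None) -> ConformerEnsemble:
    """Build an ensemble from the 3D models of an SDF file.

    Every record becomes one conformer (e.g. the several crystallographic
    conformations of one compound); energies are marked absent.  Files
    with no 3D information (all z = 0) are rejected.
    """
    try:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        mols = [m for m in supplier if m is not None]
    except OSError as exc:
        raise ChemistryError(f"cannot read {path}: {exc}") from exc
    if not mols:
        raise ChemistryError(f"no readable 3D models in {path}")
    base = mols[0]
    if base.GetNumConformers() == 0:
        raise ChemistryError(f"{path}: first model carries no coordinates")
    for extra in mols[1:]:
        if extra.GetNumAtoms() != base.GetNumAtoms():
            raise ChemistryError(f"{path}: models differ in atom count; expected conformers of one compound")
        base.AddConformer(extra.GetConformer(), assignId=True)
    coords = np.concatenate([c.GetPositions() for c in base.GetConformers()])
    if np.allclose(coords[:, 2], 0.0):
        raise ChemistryError(f"{path}: all z coordinates are zero; 2D files carry no exit-vector geometry")
    energies = np.full(base.GetNumConformers(), np.nan)
    return ConformerEnsemble(
        compound_id=compound_id or (base.GetProp("_Name") if base.HasProp("_Name") else str(path)),
        mol=base,
        energies=energies,
        method="supplied_coordinates",
        source="supplied_coordinates",
    )


def write_ensemble(ensemble: ConformerEnsemble, path) -> None:
    """Multi-record SDF with energy and method as SD data fields."""
    writer = Chem.SDWriter(str(path))
    try:
        for i, conf in enumerate(ensemble.mol.GetConformers()):
            mol = Chem.Mol(ensemble.mol)
            mol.SetProp("_Name", f"{ensemble.compound_id} conformer {i}")
            mol.SetProp("energy_kcal_mol", f"{ensemble.energies[i]:.4f}")
            mol.SetProp("method", ensemble.method)
            writer.write(mol, confId=conf.GetId())
    finally:
        writer.close()
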