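"""Physicochemical descriptors and the two design filters.

* Rule-of-Two (building-block scaffolds): MW < 200 and clogP < 2, both
  strict.
* Lead-like space (elaborated compounds): −1 < clogP < 3 (strict) and
  200 ≤ MW ≤ 350 Da (inclusive), following the printed inequalities.

clogP is the Crippen atom-contribution estimate; different logP
calculators disagree by several tenths, so clogP-based comparisons
against externally computed values are qualitative (±0.5 is a realistic
method-to-method spread).  MW is the standard average molecular weight
of the neutral free base.  Fsp3 is the fraction of sp3-hybridised
carbons.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from . import _chem

FILTERS = ("rule_of_two", "leadlike")


@dataclass(frozen=True)
class PropertyRecord:
    compound_id: str
    mw: float
    clogp: float
    fsp3: float

    @property
    def rule_of_two_pass(self) -> bool:
        return self.mw < 200 and self.clogp < 2

    @property
    def leadlike_pass(self) -> bool:
        return -1 < self.clogp < 3 and 200 <= self.mw <= 350


def profile(structure, compound_id: str | None = None) -> PropertyRecord:
    """Descriptors of one structure (SMILES, mol, or an object with .structure)."""
    if hasattr(structure, "structure"):
        compound_id = compound_id or getattr(structure, "compound_id", None) \
            or getattr(structure, "scaffold_id", None) or getattr(structure, "id", None)
        structure = structure.structure
    mol = structure if isinstance(structure, Chem.Mol) else _chem.mol_from_smiles(structure)
    mol = _chem.strip_maps(mol)
    return PropertyRecord(
        compound_id=compound_id or Chem.MolToSmiles(mol),
        mw=float(Descriptors.MolWt(mol)),
        clogp=float(Crippen.MolLogP(mol)),
        fsp3=float(Lipinski.FractionCSP3(mol)),
    )


def summarize(records: list[PropertyRecord]) -> dict:
    """Means and filter pass-rates over a nonempty record list."""
    if not records:
        raise ValueError("cannot summarize an empty record list")
    n = len(records)
    n_r2 = sum(r.rule_of_two_pass for r in records)
    n_ll = sum(r.leadlike_pass for r in records)
    return dict(
        n=n,
        mean_mw=sum(r.mw for r in records) / n,
        mean_clogp=sum(r.clogp for r in records) / n,
        mean_fsp3=sum(r.fsp3 for r in records) / n,
        n_rule_of_two=n_r2,
        frac_rule_of_two=n_r2 / n,
        n_leadlike=n_ll,
        frac_leadlike=n_ll / n,
    )


def apply_filter(records: list[PropertyRecord], filter_name: str) -> list[PropertyRecord]:
    """Order-preserving subset passing the named filter."""
    if filter_name not in FILTERS:
        raise KeyError(f"unknown filter {filter_name!r}; valid filters: {', '.join(FILTERS)}")
    attr = "rule_of_two_pass" if filter_name == "rule_of_two" else "leadlike_pass"
    return [r for r in records if getattr(r, attr)]


def property_table(records: list[PropertyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                compound_id=r.compound_id,
                mw=r.mw,
                clogp=r.clogp,
                fsp3=r.fsp3,
                rule_of_two_pass=r.rule_of_two_pass,
                leadlike_pass=r.leadlike_pass,
            )
            for r in records
        ]
    )
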