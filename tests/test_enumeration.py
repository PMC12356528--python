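"""Scaffold enumeration: counts, dedup, stereo conventions, matching."""

import itertools

import pytest
from rdkit import Chem
from rdkit.Chem.rdchem import ChiralType

import exitvec
from exitvec import _chem
from exitvec.enumeration import (
    enumerate_scaffolds,
    augment_with_tropane,
    match_named_blocks,
    reconciliation_table,
    tropane_scaffold,
)
from exitvec.registry import RegistryEntry


def test_full_universe_contains_26_scaffolds(scaffolds26):
    assert len(scaffolds26) == 26


def test_tropane_augmentation_gives_27_and_is_idempotent(scaffolds26, scaffolds27):
    assert len(scaffolds27) == 27
    assert len(augment_with_tropane(scaffolds27)) == 27
    assert len(augment_with_tropane([])) == 1


def test_empty_ring_sizes_yield_empty_set():
    assert enumerate_scaffolds(ring_sizes=set()) == []


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        enumerate_scaffolds(ring_sizes={3})
    with pytest.raises(ValueError):
        enumerate_scaffolds(topologies={"bridged"})


def _oracle_spiro_count(ring_size: int) -> int:
    """Independent brute force for the spiro-only cell of one amine ring.

    Builds every (spiro position, parity assignment) placement from
    SMILES strings, keeps 3D-embeddable isomers, and counts distinct
    compounds with enantiomers collapsed via the InChI stereo layer.
    """
    n_carbons = ring_size - 1
    seen = set()
    for pos in range(n_carbons):  # spiro carbon position among ring carbons
        chain = ["C"] * n_carbons
        chain[pos] = "C2(CC2C)"  # spiro cyclopropane with a methyl probe
        base = "N1" + "".join(chain) + "1"
        mol = Chem.MolFromSmiles(base)
        assert mol is not None
        centers = [a.GetIdx() for a in mol.GetAtoms()
                   if a.GetAtomicNum() == 6 and a.IsInRing() and len(a.GetNeighbors()) >= 3]
        for combo in itertools.product(
            (ChiralType.CHI_TETRAHEDRAL_CW, ChiralType.CHI_TETRAHEDRAL_CCW),
            repeat=len(centers),
        ):
            iso = Chem.Mol(mol)
            for idx, tag in zip(centers, combo):
                iso.GetAtomWithIdx(idx).SetChiralTag(tag)
            iso = Chem.MolFromSmiles(Chem.MolToSmiles(iso))
            if _chem.embed_single(iso) is None:
                continue
            inchi = Chem.MolToInchi(iso)
            # enantiomers differ only in the /m and /s layers
            key = inchi.replace("/m0", "/m").replace("/m1", "/m").replace("/s1", "")
            seen.add(key)
    return len(seen)


@pytest.mark.parametrize("ring_size,expected_cells", [(4, 3), (5, 4), (6, 5)])
def test_spiro_cells_match_independent_graph_oracle(ring_size, expected_cells):
    oracle = _oracle_spiro_count(ring_size)
    assert oracle == expected_cells
    ours = enumerate_scaffolds(ring_sizes={ring_size}, topologies={"spiro"})
    assert len(ours) == oracle


def test_reconciliation_table_localises_the_endo_convention():
    table = reconciliation_table()
    assert table["n_scaffolds"].sum() == 26
    assert table["n_with_endo"].sum() == 31
    apex = table[table["handle"] == "apex"]
    # the whole difference sits in the five fused-apex cells
    assert len(apex) == 5
    assert (apex["n_with_endo"] - apex["n_scaffolds"]).sum() == 5
    assert (table[table["handle"] != "apex"]["n_with_endo"]
            == table[table["handle"] != "apex"]["n_scaffolds"]).all()


def test_counts_monotone_in_universe_size():
    n_sub = len(enumerate_scaffolds(ring_sizes={4, 5}, topologies={"spiro"}))
    n_topo = len(enumerate_scaffolds(ring_sizes={4, 5}))
    n_full = len(enumerate_scaffolds())
    assert n_sub <= n_topo <= n_full


def test_deduplication_is_idempotent(scaffolds26):
    again = enumerate_scaffolds()
    merged = {s.probe: s for s in [*scaffolds26, *again]}
    assert len(merged) == len(scaffolds26)
    assert [s.probe for s in again] == [s.probe for s in scaffolds26]


def test_collapsing_diastereomers_keeps_one_per_constitution():
    collapsed = enumerate_scaffolds(include_diastereomers=False)
    assert len(collapsed) == 21  # one per distinct constitution


def test_scaffold_invariants_hold_for_every_member(scaffolds27):
    seen_probe = set()
    for spec in scaffolds27:
        mol = spec.mol()
        cp = _chem.cyclopropane_ring(mol)
        c1 = _chem.find_map(mol, _chem.MAP_C1)
        n2 = _chem.find_map(mol, _chem.MAP_N2)
        assert c1 in cp
        assert mol.GetAtomWithIdx(c1).GetTotalNumHs() >= 1
        assert mol.GetAtomWithIdx(n2).GetSymbol() == "N"
        amine_rings = [r for r in mol.GetRingInfo().AtomRings() if n2 in r]
        assert amine_rings
        shared = {a for r in amine_rings for a in r} & set(cp)
        if spec.topology == "fused":
            assert len(shared) == 2
        elif spec.topology == "spiro":
            assert len(shared) == 1
        assert spec.probe not in seen_probe
        seen_probe.add(spec.probe)


def test_stored_probes_are_enantiomer_collapsed(scaffolds27):
    for spec in scaffolds27:
        assert spec.probe == _chem.enantiomer_representative(spec.probe_mol())


def test_tropane_scaffold_matches_block_1f(blocks):
    trop = tropane_scaffold()
    entry = next(e for e in blocks if e.id == "1f")
    assert _chem.enantiomer_representative(entry.probe_mol()) == trop.probe
    assert trop.stereo == "anti"


class TestMatching:
    def test_nine_blocks_match_leaving_18_virtual_only(self, nine_mapping):
        mapping, virtual_only = nine_mapping
        assert len(mapping) == 9
        assert len(virtual_only) == 18
        assert len({s.scaffold_id for s in mapping.values()}) == 9

    def test_empty_registry_gives_empty_mapping(self, scaffolds27):
        mapping, virtual_only = match_named_blocks(scaffolds27, [])
        assert mapping == {}
        assert len(virtual_only) == 27

    def test_non_cyclopropane_decoy_raises(self, scaffolds27):
        # cyclobutane-fused analog: outside the enumerated universe
        decoy = RegistryEntry(
            id="decoy", role="building_block",
            structure="C1CC2(CC2)C[NH:2]C1",
            probe="C[CH:1]1CCC12CC[NH:2]CC2",
        )
        with pytest.raises(_chem.ChemistryError, match="decoy"):
            match_named_blocks(scaffolds27, [decoy])


def test_enumeration_writer_round_trips(tmp_path, scaffolds26):
    import pandas as pd

    from exitvec.enumeration import write_scaffolds

    csv = tmp_path / "scaffolds.csv"
    write_scaffolds(scaffolds26, csv, tmp_path / "scaffolds.smi")
    df = pd.read_csv(csv)
    assert len(df) == 26
    assert set(df.columns) >= {"id", "ring_size", "topology", "stereo", "canonical_structure", "probe"}
    assert df["canonical_structure"].notna().all()
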