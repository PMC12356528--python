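"""Exit-vector geometry: dihedral correctness, invariances, selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from exitvec import _chem, vectors
from exitvec.vectors import compute_exit_vector, diversity_select, fold_theta, vectors_for_library

RNG = np.random.default_rng(20260923)


def oracle_dihedral(red, orange, green, blue) -> float:
    """Independent signed-torsion formula (atan2 of cross products), unsigned."""
    b1 = np.asarray(orange) - np.asarray(red)
    b2 = np.asarray(green) - np.asarray(orange)
    b3 = np.asarray(blue) - np.asarray(green)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return abs(angle)


@pytest.mark.parametrize(
    "blue,expected_theta",
    [((1.5, 1.0, 0.0), 0.0), ((1.5, -1.0, 0.0), 180.0), ((1.5, 0.0, 1.0), 90.0)],
)
def test_planar_reference_geometries(blue, expected_theta):
    r, theta = compute_exit_vector((0, 1, 0), (0, 0, 0), (1.5, 0, 0), blue)
    assert r == pytest.approx(1.5)
    assert theta == pytest.approx(expected_theta, abs=1e-9)


def test_dihedral_matches_independent_oracle_on_1000_random_quadruples():
    count = 0
    while count < 1000:
        pts = RNG.normal(scale=3.0, size=(4, 3))
        red, orange, green, blue = pts
        axis = green - orange
        if (np.linalg.norm(np.cross(orange - red, axis)) < 1e-3
                or np.linalg.norm(np.cross(axis, blue - green)) < 1e-3):
            continue  # skip near-degenerate draws; degeneracy is its own test
        r, theta = compute_exit_vector(red, orange, green, blue)
        assert r == pytest.approx(np.linalg.norm(green - orange), abs=1e-12)
        assert theta == pytest.approx(oracle_dihedral(red, orange, green, blue), abs=1e-6)
        count += 1


def test_rigid_motions_leave_r_and_theta_unchanged():
    from scipy.spatial.transform import Rotation

    pts = RNG.normal(scale=2.0, size=(4, 3))
    base = compute_exit_vector(*pts)
    for _ in range(25):
        rot = Rotation.random(random_state=np.random.RandomState(int(RNG.integers(2**31))))
        shift = RNG.normal(scale=10.0, size=3)
        moved = rot.apply(pts) + shift
        transformed = compute_exit_vector(*moved)
        assert transformed[0] == pytest.approx(base[0], abs=1e-9)
        assert transformed[1] == pytest.approx(base[1], abs=1e-7)


def test_mirror_images_give_identical_r_and_theta():
    """|dihedral| is reflection-invariant: both enantiomers plot at one point."""
    for _ in range(25):
        pts = RNG.normal(scale=2.0, size=(4, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        assert compute_exit_vector(*pts) == pytest.approx(compute_exit_vector(*mirrored), abs=1e-9)


def test_collinear_triples_raise():
    with pytest.raises(_chem.ChemistryError, match="collinear"):
        compute_exit_vector((0, 0, 2), (0, 0, 1), (0, 0, 0), (1, 1, 1))
    with pytest.raises(_chem.ChemistryError):
        compute_exit_vector((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))


def test_theta_fold_conventions():
    assert fold_theta(135.0, 180) == 135.0
    assert fold_theta(135.0, 90) == 45.0
    with pytest.raises(ValueError):
        fold_theta(10.0, 45)


class TestLibraryTable:
    def test_mesyl_series_table_shape_and_sources(self, mesyl_series):
        table = mesyl_series["table"]
        assert len(table) == 9
        assert (table["source"] == "computed").all()
        assert table["compound_id"].is_monotonic_increasing

    def test_bonded_limit_r_equals_the_c1_n2_bond_length(self, mesyl_series):
        row = mesyl_series["table"][
            mesyl_series["table"]["scaffold_id"] == "pyrrolidine-f23-j2-cis"
        ].iloc[0]
        compound = next(c for c in mesyl_series["library"]
                        if c.scaffold_id == "pyrrolidine-f23-j2-cis")
        ens = mesyl_series["ensembles"][compound.compound_id]
        idx = compound.atom_indices
        pos = ens.coordinates(ens.lowest_index)
        bond_length = np.linalg.norm(pos[idx["atom_c1"]] - pos[idx["atom_n2"]])
        assert row["r_angstrom"] == pytest.approx(bond_length, abs=1e-9)

    def test_empty_library_gives_empty_table(self):
        table = vectors_for_library([], {})
        assert len(table) == 0

    def test_missing_ensembles_are_reported_by_id(self, mesyl_series):
        with pytest.raises(_chem.ChemistryError, match=mesyl_series["library"][0].compound_id):
            vectors_for_library(mesyl_series["library"], {})

    def test_supplied_coordinates_keep_every_model(self, mesyl_series):
        compound = mesyl_series["library"][0]
        ens = mesyl_series["ensembles"][compound.compound_id]
        import copy

        supplied = copy.copy(ens)
        supplied.source = "supplied_coordinates"
        table = vectors_for_library([compound], {compound.compound_id: supplied})
        assert len(table) == supplied.n_conformers
        assert (table["source"] == "supplied_coordinates").all()

    def test_uncapped_compounds_are_refused(self, nine_mapping, pyrimidinyl):
        from exitvec import conformers
        from exitvec.elaboration import attach_fragment

        mapping, _ = nine_mapping
        core = attach_fragment(mapping["1b"], pyrimidinyl)
        ens = conformers.embed_and_minimize(core, n_confs=2, seed=1)
        with pytest.raises(_chem.ChemistryError, match="red"):
            vectors_for_library([core], {core.compound_id: ens})


def _table(points):
    return pd.DataFrame(
        [
            dict(compound_id=f"c{i:02d}", scaffold_id="s", fragment_id="f", cap_id="x",
                 conformer_index=0, r_angstrom=p[0], theta_degrees=p[1], source="computed")
            for i, p in enumerate(points)
        ]
    )


def _exhaustive_maximin(points, k):
    """Reference: best min-pairwise-distance subset over all combinations."""
    r = np.array([p[0] for p in points], dtype=float)
    t = np.array([p[1] for p in points], dtype=float)
    rr = np.ptp(r)
    x = np.stack([(r - r.min()) / rr if rr > 0 else np.zeros_like(r), t / 180.0], axis=1)
    ids = [f"c{i:02d}" for i in range(len(points))]
    best, best_key = None, None
    for subset in itertools.combinations(range(len(points)), k):
        score = min(np.linalg.norm(x[i] - x[j]) for i, j in itertools.combinations(subset, 2))
        key = (-score, tuple(ids[i] for i in subset))
        if best_key is None or key < best_key:
            best, best_key = subset, key
    return {ids[i] for i in best}


class TestDiversitySelect:
    def test_k_zero_and_k_n(self, mesyl_series):
        table = mesyl_series["table"]
        assert diversity_select(table, 0) == []
        assert set(diversity_select(table, 9)) == set(table["compound_id"])

    def test_out_of_range_k_rejected(self, mesyl_series):
        with pytest.raises(ValueError):
            diversity_select(mesyl_series["table"], 10)
        with pytest.raises(ValueError):
            diversity_select(mesyl_series["table"], -1)

    def test_collinear_points_pick_the_extremes(self):
        table = _table([(1.0, 10.0), (2.0, 60.0), (3.0, 110.0)])
        assert set(diversity_select(table, 2)) == {"c00", "c02"}

    @pytest.mark.parametrize("n,k", [(5, 2), (7, 3), (10, 4), (10, 2)])
    def test_matches_exhaustive_search_for_small_sets(self, n, k):
        points = [(float(r), float(t)) for r, t in
                  zip(RNG.uniform(1, 5, n), RNG.uniform(0, 180, n))]
        assert set(diversity_select(_table(points), k)) == _exhaustive_maximin(points, k)

    def test_selection_is_deterministic_under_duplicate_points(self):
        table = _table([(2.0, 90.0)] * 4)
        assert diversity_select(table, 2) == diversity_select(table, 2)
        assert len(diversity_select(table, 2)) == 2
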