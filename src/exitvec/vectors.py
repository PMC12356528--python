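"""Exit-vector geometry: the parameters r and θ.

A bifunctional scaffold displays its two substituents along the exit
vectors n1 (C1 → first fragment atom, "blue") and n2 (N2 → first cap
atom, "red").  Two numbers characterise this display:

* ``r`` — the through-space distance in Å between the variation points
  C1 ("green") and N2 ("orange");
* ``θ`` — the dihedral angle, in degrees, between the plane containing
  (red, orange, green) and the plane containing (orange, green, blue),
  i.e. the torsion of the atom sequence red–orange–green–blue.

θ is reported unsigned and folded into [0, 180]°: the sign of a torsion
flips between enantiomers, and only one enantiomeric series of each
racemic compound is analysed, so an unsigned angle is the natural
scaffold descriptor.  A scatter of r against θ for a compound set is the
exit-vector plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._chem import ChemistryError, MAP_BLUE, MAP_C1, MAP_N2, MAP_RED
from .conformers import ConformerEnsemble
from .elaboration import ElaboratedCompound

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class ExitVectorRecord:
    compound_id: str
    r: float
    theta: float
    n1: tuple[float, float, float]
    n2: tuple[float, float, float]
    source: str
    conformer_index: int


def compute_exit_vector(red, orange, green, blue) -> tuple[float, float]:
    """(r, θ) from the four defining atom positions.

    ``r`` is the green–orange distance; ``θ`` the unsigned dihedral of
    red–orange–green–blue, from the angle between the two plane normals,
    folded into [0, 180].  Degenerate (collinear) triples raise.
    """
    red, orange, green, blue = (np.asarray(p, dtype=float) for p in (red, orange, green, blue))
    axis = green - orange
    r = float(np.linalg.norm(axis))
    if r <= 0.0:
        raise ChemistryError("green and orange atoms coincide; r undefined")
    norm1 = np.cross(orange - red, axis)
    norm2 = np.cross(axis, blue - green)
    scale = max(np.linalg.norm(orange - red), np.linalg.norm(blue - green), r)
    if np.linalg.norm(norm1) < _COLLINEAR_TOL * scale or np.linalg.norm(norm2) < _COLLINEAR_TOL * scale:
        raise ChemistryError(
            "degenerate geometry: red-orange-green or orange-green-blue atoms are collinear"
        )
    cos_theta = np.dot(norm1, norm2) / (np.linalg.norm(norm1) * np.linalg.norm(norm2))
    theta = float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))
    return r, theta


def fold_theta(theta: float, fold: int = 180) -> float:
    """Fold an unsigned dihedral into [0, fold] (fold = 180 or 90)."""
    if fold == 180:
        return theta
    if fold == 90:
        return min(theta, 180.0 - theta)
    raise ValueError("fold must be 90 or 180")


def _record(compound: ElaboratedCompound, ensemble: ConformerEnsemble,
            conf_index: int, fold: int) -> ExitVectorRecord:
    idx = compound.atom_indices
    for role in ("atom_red", "atom_blue"):
        if idx[role] is None:
            raise ChemistryError(
                f"{compound.compound_id!r} lacks a {role.removeprefix('atom_')} atom: "
                "exit vectors are only defined for fully elaborated compounds"
            )
    pos = ensemble.coordinates(conf_index)
    red, orange = pos[idx["atom_red"]], pos[idx["atom_n2"]]
    green, blue = pos[idx["atom_c1"]], pos[idx["atom_blue"]]
    r, theta = compute_exit_vector(red, orange, green, blue)
    n1 = (blue - green) / np.linalg.norm(blue - green)
    n2 = (red - orange) / np.linalg.norm(red - orange)
    return ExitVectorRecord(
        compound_id=compound.compound_id,
        r=r,
        theta=fold_theta(theta, fold),
        n1=tuple(n1),
        n2=tuple(n2),
        source=ensemble.source,
        conformer_index=conf_index,
    )


def vectors_for_library(
    library: list[ElaboratedCompound],
    ensembles: dict[str, ConformerEnsemble],
    fold: int = 180,
) -> pd.DataFrame:
    """Exit-vector table: one row per compound per retained conformer.

    Computed ensembles contribute only their lowest-energy conformer;
    supplied-coordinate ensembles contribute every model (a crystal
    structure with three molecules in the asymmetric unit yields three
    rows).  Sorted by compound id.
    """
    missing = [c.compound_id for c in library if c.compound_id not in ensembles]
    if missing:
        raise ChemistryError(f"missing conformer ensembles for: {', '.join(sorted(missing))}")
    by_id = {c.compound_id: c for c in library}
    rows = []
    for cid in sorted(by_id):
        compound, ensemble = by_id[cid], ensembles[cid]
        if ensemble.source == "computed":
            indices = [ensemble.lowest_index]
        else:
            indices = range(ensemble.n_conformers)
        for i in indices:
            rec = _record(compound, ensemble, i, fold)
            rows.append(
                dict(
                    compound_id=rec.compound_id,
                    scaffold_id=compound.scaffold_id,
                    fragment_id=compound.fragment_id,
                    cap_id=compound.cap_id,
                    conformer_index=rec.conformer_index,
                    r_angstrom=rec.r,
                    theta_degrees=rec.theta,
                    source=rec.source,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["compound_id", "scaffold_id", "fragment_id", "cap_id",
                 "conformer_index", "r_angstrom", "theta_degrees", "source"],
    )


#: exhaustive maximin is used whenever the number of candidate subsets
#: is at most this; beyond it the greedy heuristic takes over
_EXHAUSTIVE_LIMIT = 100_000


def diversity_select(records: pd.DataFrame, k: int) -> list[str]:
    """Maximin selection of k compounds in normalised (r, θ) space.

    r is scaled by its observed range, θ by 180.  For small problems the
    subset maximising the minimum pairwise distance is found by
    exhaustive search (ties broken by lexicographically smallest id
    tuple); for large ones a greedy heuristic is used whose first pick
    is the point closest to the centroid and whose later picks maximise
    the minimum distance to the already-selected set, ties again broken
    by compound id.  With several conformers per compound the lowest
    conformer_index row represents it.
    """
    if k < 0 or k > records["compound_id"].nunique():
        raise ValueError("k must satisfy 0 <= k <= number of distinct compounds")
    if k == 0:
        return []
    rep = (records.sort_values(["compound_id", "conformer_index"])
           .groupby("compound_id", as_index=True).first())
    r = rep["r_angstrom"].to_numpy(dtype=float)
    theta = rep["theta_degrees"].to_numpy(dtype=float)
    r_range = np.ptp(r)
    x = np.stack([(r - r.min()) / r_range if r_range > 0 else np.zeros_like(r),
                  theta / 180.0], axis=1)
    ids = list(rep.index)
    n = len(ids)
    dist = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    centroid = x.mean(axis=0)
    d0 = np.linalg.norm(x - centroid, axis=1)

    if k == 1:
        return [ids[min(range(n), key=lambda i: (d0[i], ids[i]))]]

    import itertools
    from math import comb

    if comb(n, k) <= _EXHAUSTIVE_LIMIT:
        best, best_key = None, None
        for subset in itertools.combinations(range(n), k):
            score = min(dist[i][j] for i, j in itertools.combinations(subset, 2))
            key = (-score, tuple(ids[i] for i in subset))
            if best_key is None or key < best_key:
                best, best_key = subset, key
        return [ids[i] for i in best]

    first = min(range(n), key=lambda i: (d0[i], ids[i]))
    chosen = [first]
    while len(chosen) < k:
        dmin = dist[:, chosen].min(axis=1)
        pick = min(
            (i for i in range(n) if i not in chosen),
            key=lambda i: (-dmin[i], ids[i]),
        )
        chosen.append(pick)
    return [ids[i] for i in chosen]


def plot_exit_vectors(records: pd.DataFrame, path=None, highlight: list[str] | None = None):
    """Scatter of r vs θ; optionally highlight a named compound subset."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    base = records
    if highlight:
        mask = records["compound_id"].isin(highlight)
        base = records[~mask]
        ax.scatter(records.loc[mask, "theta_degrees"], records.loc[mask, "r_angstrom"],
                   c="crimson", label="named blocks", zorder=3)
    ax.scatter(base["theta_degrees"], base["r_angstrom"], c="steelblue",
               label="virtual" if highlight else None, zorder=2)
    ax.set_xlabel("θ (degrees)")
    ax.set_ylabel("r (Å)")
    ax.set_xlim(-5, 185)
    if highlight:
        ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
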