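"""End-to-end orchestration: enumerate → elaborate → conformers → vectors → profile.

A :class:`PipelineConfig` (YAML-serialisable) fixes every choice that
affects the outputs — enumeration universe, registries, conformer
settings, θ fold — and the run manifest records the seed, package
versions, per-stage counts and wall time, so a run is reproducible from
its output directory alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, _chem, conformers, elaboration, enumeration, properties, registry, vectors

logger = logging.getLogger("exitvec")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending ids."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    ring_sizes: tuple[int, ...] = (4, 5, 6)
    topologies: tuple[str, ...] = ("fused", "spiro")
    include_diastereomers: bool = True
    include_endo: bool = False
    add_tropane: bool = True
    named_blocks_only: bool = False
    fragment_registry: str = "fragments"
    cap_registry: str = "caps"
    fragment_subset: tuple[str, ...] = ()
    cap_subset: tuple[str, ...] = ()
    n_confs: int = conformers.DEFAULT_N_CONFS
    seed: int = conformers.DEFAULT_SEED
    prune_rms: float = conformers.DEFAULT_PRUNE_RMS
    theta_fold: int = 180
    output_dir: str = "exitvec_run"
    write_conformers: bool = True
    write_plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for fld in ("ring_sizes", "topologies", "fragment_subset", "cap_subset"):
            setattr(cfg, fld, tuple(getattr(cfg, fld)))
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for fld in ("ring_sizes", "topologies", "fragment_subset", "cap_subset"):
            data[fld] = list(data[fld])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _provenance_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# exitvec {__version__} seed={cfg.seed} n_confs={cfg.n_confs}\n")
        df.to_csv(fh, index=False)


def _load_subset(name: str, subset: tuple[str, ...], stage: str):
    entries = registry.load_registry(name)
    if subset:
        by_id = {e.id: e for e in entries}
        missing = [s for s in subset if s not in by_id]
        if missing:
            raise PipelineError(stage, f"ids not in registry {name!r}: {', '.join(missing)}")
        entries = [by_id[s] for s in subset]
    return entries


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, write all artifacts, return the manifest dict."""
    t0 = time.time()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "exitvec_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "counts": {},
    }

    # --- enumerate ---------------------------------------------------
    try:
        scaffolds = enumeration.enumerate_scaffolds(
            ring_sizes=set(cfg.ring_sizes),
            topologies=set(cfg.topologies),
            include_diastereomers=cfg.include_diastereomers,
            include_endo=cfg.include_endo,
        )
        n_enumerated = len(scaffolds)
        if cfg.add_tropane:
            scaffolds = enumeration.augment_with_tropane(scaffolds)
        blocks = registry.load_registry("building_blocks")
        mapping, virtual_only = enumeration.match_named_blocks(scaffolds, blocks)
        if cfg.named_blocks_only:
            scaffolds = [mapping[bid] for bid in sorted(mapping)]
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("enumerate", str(exc)) from exc
    manifest["counts"]["scaffolds_enumerated"] = n_enumerated
    manifest["counts"]["scaffolds_with_tropane"] = len(scaffolds) if not cfg.named_blocks_only else n_enumerated + 1
    manifest["counts"]["named_blocks_matched"] = len(mapping)
    manifest["counts"]["virtual_only_scaffolds"] = len(virtual_only)
    manifest["counts"]["scaffolds_used"] = len(scaffolds)
    enumeration.write_scaffolds(scaffolds, outdir / "scaffolds.csv", outdir / "scaffolds.smi")
    logger.info("enumerate: %d scaffolds (%d named, %d virtual-only)",
                len(scaffolds), len(mapping), len(virtual_only))

    # --- elaborate ---------------------------------------------------
    fragments = _load_subset(cfg.fragment_registry, cfg.fragment_subset, "elaborate")
    caps = _load_subset(cfg.cap_registry, cfg.cap_subset, "elaborate")
    if not fragments or not caps:
        raise PipelineError("elaborate", "fragment and cap registries must be nonempty")
    try:
        library = elaboration.enumerate_library(scaffolds, fragments, caps)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("elaborate", str(exc)) from exc
    manifest["counts"]["library_compounds"] = len(library)
    manifest["library_note"] = (
        f"{len(library)} products from {len(scaffolds)} scaffolds x "
        f"{len(fragments)} fragments x {len(caps)} caps after canonical deduplication"
    )
    elaboration.write_library(library, outdir / "library.csv", outdir / "library.smi")
    logger.info("elaborate: %d products", len(library))

    # --- conformers --------------------------------------------------
    ensembles: dict[str, conformers.ConformerEnsemble] = {}
    failed = []
    for compound in library:
        try:
            ensembles[compound.compound_id] = conformers.embed_and_minimize(
                compound, n_confs=cfg.n_confs, seed=cfg.seed, prune_rms=cfg.prune_rms
            )
        except _chem.ChemistryError:
            failed.append(compound.compound_id)
    if failed:
        raise PipelineError("conformers", f"embedding failed for: {', '.join(failed)}")
    manifest["counts"]["ensembles"] = len(ensembles)
    if cfg.write_conformers:
        from rdkit import Chem as _C

        writer = _C.SDWriter(str(outdir / "lowest_conformers.sdf"))
        try:
            for cid in sorted(ensembles):
                ens = ensembles[cid]
                mol = _C.Mol(ens.mol)
                mol.SetProp("_Name", cid)
                mol.SetProp("energy_kcal_mol", f"{ens.energies[ens.lowest_index]:.4f}")
                mol.SetProp("method", ens.method)
                writer.write(mol, confId=ens.mol.GetConformers()[ens.lowest_index].GetId())
        finally:
            writer.close()
    logger.info("conformers: %d ensembles (%s)", len(ensembles),
                next(iter(ensembles.values())).method if ensembles else "-")

    # --- vectors -----------------------------------------------------
    try:
        table = vectors.vectors_for_library(library, ensembles, fold=cfg.theta_fold)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("vectors", str(exc)) from exc
    _provenance_csv(table, outdir / "exit_vectors.csv", cfg)
    manifest["counts"]["exit_vector_records"] = len(table)
    manifest["r_min_angstrom"] = float(table["r_angstrom"].min())
    manifest["r_max_angstrom"] = float(table["r_angstrom"].max())
    if cfg.write_plot:
        named = {c.compound_id for c in library if c.scaffold_id in
                 {s.scaffold_id for s in mapping.values()}}
        vectors.plot_exit_vectors(table, outdir / "exit_vector_plot.png", highlight=sorted(named))
    logger.info("vectors: %d records, r in [%.2f, %.2f] A", len(table),
                manifest["r_min_angstrom"], manifest["r_max_angstrom"])

    # --- profile -----------------------------------------------------
    try:
        scaffold_props = [properties.profile(s.structure, s.scaffold_id) for s in scaffolds]
        library_props = [properties.profile(c.structure, c.compound_id) for c in library]
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("profile", str(exc)) from exc
    _provenance_csv(properties.property_table(scaffold_props), outdir / "scaffold_properties.csv", cfg)
    _provenance_csv(properties.property_table(library_props), outdir / "library_properties.csv", cfg)
    manifest["scaffold_property_summary"] = properties.summarize(scaffold_props)
    manifest["library_property_summary"] = properties.summarize(library_props)
    logger.info("profile: %d scaffolds, %d library compounds", len(scaffold_props), len(library_props))

    manifest["wall_time_s"] = round(time.time() - t0, 2)
    try:
        import numpy
        import rdkit

        manifest["versions"] = {
            "rdkit": rdkit.__version__,
            "numpy": numpy.__version__,
            "pandas": pd.__version__,
        }
    except Exception:  # noqa: BLE001
        pass
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=False))
    return manifest
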