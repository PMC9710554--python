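"""End-to-end workflow orchestration and artifact statistics.

``run_pipeline`` chains preprocess -> atlas -> mine (+cluster) ->
optional quick-graft, writing every artifact plus a manifest that records
inputs, configuration hash and per-stage counts.  Re-running with identical
inputs and seed reproduces byte-identical JSON artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .atlas import atlas_stats, build_atlas, load_atlas, save_atlas
from .config import ToolConfig
from .errors import PipelineError, PocketGraftError, SchemaVersionError
from .grafting import LigandSelection, quick_graft, write_design
from .pdbio import read_pdb, write_pdb
from .pockets import (cluster_pocket, extract_pockets, load_pockets,
                      mine_atlas, save_pockets)
from .structures import split_complexes

log = logging.getLogger(__name__)


def preprocess_collection(collection_dir: str | Path, config: ToolConfig,
                          out_dir: str | Path):
    """Read every .pdb in a directory, split into complexes, write one PDB
    per complex named <source>_<binderchain><ligandchain>.pdb."""
    collection_dir = Path(collection_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    complexes = []
    files = sorted(collection_dir.glob("*.pdb"))
    if not files:
        raise PipelineError("preprocess", f"no .pdb files in {collection_dir}")
    kept = dropped = 0
    for path in files:
        try:
            chains = read_pdb(
                path, include_hydrogens=config.preprocess.include_hydrogen_atoms)
        except PocketGraftError as exc:
            log.warning("preprocess: skipping %s: %s", path.name, exc)
            dropped += 1
            continue
        found = split_complexes(chains, config.preprocess, source_id=path.stem)
        if not found:
            dropped += 1
            continue
        for cx in found:
            write_pdb(cx.chains(), out_dir / f"{cx.complex_id}.pdb")
            complexes.append(cx)
        kept += 1
    log.info("preprocess: %d files kept, %d dropped, %d complexes",
             kept, dropped, len(complexes))
    return complexes


def run_pipeline(config: ToolConfig, collection_dir: str | Path,
                 out_dir: str | Path,
                 scaffold: str | Path | None = None,
                 selections: list[tuple[str, str]] | None = None,
                 mutable_positions=None,
                 n_designs: int = 1) -> dict:
    """Full workflow; returns (and writes) the artifact manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema": "manifest",
        "schema_version": 1,
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "inputs": {"collection_dir": str(collection_dir),
                   "scaffold": str(scaffold) if scaffold else None},
        "stages": {},
        "artifacts": {},
    }

    try:
        complexes = preprocess_collection(collection_dir, config,
                                          out_dir / "complexes")
    except PipelineError:
        raise
    except PocketGraftError as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    manifest["stages"]["preprocess"] = {"complexes": len(complexes)}

    try:
        atlas = build_atlas(complexes, config.atlas)
        save_atlas(atlas, out_dir / "atlas.json")
    except PocketGraftError as exc:
        raise PipelineError("atlas", str(exc)) from exc
    manifest["artifacts"]["atlas"] = "atlas.json"
    manifest["stages"]["atlas"] = {
        "datapoints": len(atlas),
        "pages": len(atlas.pages()),
        "maps": len(atlas.maps()),
    }

    try:
        mined = mine_atlas(atlas, config.mining)
        pockets = []
        for lig_type in sorted(mined):
            for pocket in extract_pockets(atlas, mined[lig_type]):
                pockets.append(cluster_pocket(pocket, config.clustering))
        save_pockets(pockets, atlas, out_dir / "pockets.json")
    except PocketGraftError as exc:
        raise PipelineError("mine", str(exc)) from exc
    manifest["artifacts"]["pockets"] = "pockets.json"
    manifest["stages"]["mine"] = {
        "pockets": len(pockets),
        "clusters": sum(len(p.clusters) for p in pockets),
    }

    if selections:
        if scaffold is None:
            raise PipelineError("graft", "quick-graft requested but no "
                                         "scaffold structure was provided")
        try:
            chains = read_pdb(scaffold)
            scs = split_complexes(chains, config.preprocess,
                                  source_id=Path(scaffold).stem)
            if not scs:
                raise PipelineError(
                    "graft", "scaffold does not split into a complex under "
                             "the preprocessing parameters")
            sc = scs[0]
            sels = [LigandSelection(pos, target) for pos, target in selections]
            mutable = mutable_positions or [r.label for r in sc.binder]
            designs = quick_graft(sc, pockets, sels, mutable,
                                  config.grafting, n=n_designs)
            for i, design in enumerate(designs):
                write_design(design, out_dir / f"design_{i:02d}.pdb")
        except PipelineError:
            raise
        except PocketGraftError as exc:
            raise PipelineError("graft", str(exc)) from exc
        manifest["artifacts"]["designs"] = [
            f"design_{i:02d}.pdb" for i in range(len(designs))]
        manifest["stages"]["graft"] = {
            "designs": len(designs),
            "best_score": round(designs[0].total_score, 9),
        }

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def report_stats(artifact_path: str | Path, out_dir: str | Path) -> list[Path]:
    """CSV statistics tables for an atlas or pockets artifact."""
    artifact_path = Path(artifact_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        data = json.loads(artifact_path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise SchemaVersionError(
            f"cannot parse artifact {artifact_path}: {exc}") from exc
    schema = data.get("schema")
    written = []
    if schema == "atlas":
        atlas = load_atlas(artifact_path)
        pages, maps = atlas_stats(atlas)
        p1 = out_dir / "atlas_pages.csv"
        p2 = out_dir / "atlas_maps.csv"
        pages.to_csv(p1, index=False)
        maps.to_csv(p2, index=False)
        written += [p1, p2]
    elif schema == "pockets":
        if data.get("schema_version") != 1:
            raise SchemaVersionError("pockets schema version unsupported")
        rows = []
        for p in data["pockets"]:
            rows.append({
                "pocket_id": p["pocket_id"],
                "ligand_type": p["ligand_type"],
                "itemset": "+".join(p["itemset"]),
                "support": p["support"],
                "adjusted_support": p["adjusted_support"],
                "members": len(p["superimposed"]),
                "clusters": len(p["clusters"]),
            })
        crows = []
        for p in data["pockets"]:
            for i, c in enumerate(p["clusters"]):
                crows.append({
                    "pocket_id": p["pocket_id"], "cluster": i,
                    "size": len(c["member_ids"]),
                    "variance": c["variance"],
                    "noise": len(c["noise_ids"]),
                })
        p1 = out_dir / "pockets.csv"
        p2 = out_dir / "pocket_clusters.csv"
        pd.DataFrame(rows).to_csv(p1, index=False)
        pd.DataFrame(crows).to_csv(p2, index=False)
        written += [p1, p2]
    else:
        raise SchemaVersionError(
            f"unrecognized artifact schema {schema!r} in {artifact_path}")
    return written
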