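"""Interaction atlas extraction.

An atlas is the collection of all pairwise ligand-residue <-> binder-residue
interaction datapoints found in a structure collection, each expressed in
the internal frame of its ligand residue.  Datapoints are organized into
*pages* (one per ligand residue type, at most 20) which partition further
into *maps* (one per ligand x binder type combination, at most 400).

Contact detection: an atom pair interacts when its distance is within the
radius of its chemical class — ionic 8.0 Å, aromatic 6.0 Å, hydrogen bond
6.0 Å, everything else 4.0 Å by default; classes are evaluated in that
order.  With ``skip_backbone_atoms`` (the default) only side-chain atoms
(Cβ included) are considered; glycine keeps its Cα as a side-chain
surrogate so that every residue type can appear on both sides of a contact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import (BACKBONE_ATOMS, ChemicalClasses, DEFAULT_CLASSES,
                   SIDECHAIN_TREE)
from .errors import FrameError, GeometryError, SchemaVersionError
from .geometry import build_frame
from .structures import StructureComplex, residue_pose

log = logging.getLogger(__name__)

ATLAS_SCHEMA_VERSION = 1

INTERACTION_KINDS = ("ionic", "aromatic", "hbond", "other")


@dataclass(frozen=True)
class InteractionRadii:
    """Per-class contact radii in Å."""

    ionic: float = 8.0
    aromatic: float = 6.0
    hbond: float = 6.0
    other: float = 4.0

    def __post_init__(self):
        for kind in INTERACTION_KINDS:
            if getattr(self, kind) <= 0:
                raise ValueError(f"{kind} radius must be positive")

    @property
    def max_radius(self) -> float:
        return max(self.ionic, self.aromatic, self.hbond, self.other)


@dataclass
class AtlasParams:
    radii: InteractionRadii = field(default_factory=InteractionRadii)
    min_ligand_length: int = 3
    max_ligand_length: int = 20
    skip_backbone_atoms: bool = True
    allow_intramolecular: bool = False

    def __post_init__(self):
        if self.min_ligand_length > self.max_ligand_length:
            raise ValueError("min_ligand_length > max_ligand_length")


Origin = tuple[str, str, str]  # (source_id, chain_id, residue label)


@dataclass
class AtlasDatapoint:
    """One ligand-binder residue interaction in the ligand's internal frame."""

    ligand_type: str
    binder_type: str
    ligand_origin: Origin
    binder_origin: Origin
    ligand_atoms: dict[str, np.ndarray]
    binder_atoms: dict[str, np.ndarray]
    interaction_kinds: frozenset[str]

    def sort_key(self):
        return (self.ligand_origin, self.binder_origin)


_warned_atoms: set[str] = set()


def _atom_class_flags(classes: ChemicalClasses, res: str, name: str,
                      include_backbone: bool):
    known = (name in BACKBONE_ATOMS
             or any(name == child for child, _ in SIDECHAIN_TREE.get(res, []))
             or name in ("CB", "CA"))
    if not known and name not in _warned_atoms:
        _warned_atoms.add(name)
        log.warning("unknown atom name %r; treated as class 'other'", name)
    return {
        "positive": classes.is_positive(res, name),
        "negative": classes.is_negative(res, name),
        "aromatic": classes.is_aromatic(res, name),
        "donor": classes.is_donor(res, name, include_backbone),
        "acceptor": classes.is_acceptor(res, name, include_backbone),
    }


def classify_contact(ligand_atom: tuple[str, str], binder_atom: tuple[str, str],
                     distance: float, radii: InteractionRadii,
                     classes: ChemicalClasses = DEFAULT_CLASSES,
                     include_backbone: bool = False) -> str | None:
    """Classify one atom pair; returns the interaction kind or None.

    ``ligand_atom``/``binder_atom`` are (atom_name, residue_type) pairs.
    Classes are evaluated ionic -> aromatic -> hbond -> other; the first
    class whose predicate matches *and* whose radius covers the distance
    wins.
    """
    la, lr = ligand_atom[0], ligand_atom[1]
    ba, br = binder_atom[0], binder_atom[1]
    f1 = _atom_class_flags(classes, lr, la, include_backbone)
    f2 = _atom_class_flags(classes, br, ba, include_backbone)
    if ((f1["positive"] and f2["negative"]) or (f1["negative"] and f2["positive"])):
        if distance <= radii.ionic:
            return "ionic"
    if f1["aromatic"] and f2["aromatic"]:
        if distance <= radii.aromatic:
            return "aromatic"
    if ((f1["donor"] and f2["acceptor"]) or (f1["acceptor"] and f2["donor"])):
        if distance <= radii.hbond:
            return "hbond"
    if distance <= radii.other:
        return "other"
    return None


def _interaction_atoms(res, skip_backbone: bool) -> list:
    """Atoms of a residue that participate in contact detection."""
    if not skip_backbone:
        return list(res.atoms)
    side = [a for a in res.atoms if a.name not in BACKBONE_ATOMS]
    if not side and res.residue_type == "GLY":
        ca = res.atom("CA")
        if ca is not None:
            return [ca]  # Cα surrogate: glycine has no side chain
    return side


def _contact_kinds(lig_res, bind_res, params: AtlasParams,
                   classes: ChemicalClasses) -> frozenset[str]:
    kinds: set[str] = set()
    lig_atoms = _interaction_atoms(lig_res, params.skip_backbone_atoms)
    bind_atoms = _interaction_atoms(bind_res, params.skip_backbone_atoms)
    include_backbone = not params.skip_backbone_atoms
    for la in lig_atoms:
        for ba in bind_atoms:
            d = float(np.linalg.norm(la.xyz - ba.xyz))
            if d > params.radii.max_radius:
                continue
            kind = classify_contact((la.name, lig_res.residue_type),
                                    (ba.name, bind_res.residue_type),
                                    d, params.radii, classes,
                                    include_backbone=include_backbone)
            if kind is not None:
                kinds.add(kind)
    return frozenset(kinds)


def extract_datapoints(complex_: StructureComplex,
                       params: AtlasParams | None = None,
                       classes: ChemicalClasses = DEFAULT_CLASSES
                       ) -> list[AtlasDatapoint]:
    """All qualifying residue-pair datapoints of one complex.

    One datapoint per (ligand residue, binder residue) pair with at least
    one in-radius atom contact; it carries the *set* of interaction kinds
    over its atom pairs, and both residues' atoms in the ligand residue's
    internal frame.
    """
    params = params or AtlasParams()
    n = len(complex_.ligand)
    if not params.min_ligand_length <= n <= params.max_ligand_length:
        log.info("complex %s skipped: ligand length %d outside [%d, %d]",
                 complex_.complex_id, n, params.min_ligand_length,
                 params.max_ligand_length)
        return []
    partners = list(complex_.binder)
    datapoints: list[AtlasDatapoint] = []
    for lig_res in complex_.ligand:
        try:
            pose = residue_pose(lig_res)
            frame = build_frame(pose)
        except (GeometryError, FrameError) as exc:
            log.warning("ligand residue %s skipped: %s", lig_res.label, exc)
            continue
        candidates = partners
        if params.allow_intramolecular:
            candidates = partners + [r for r in complex_.ligand if r is not lig_res]
        for bind_res in candidates:
            kinds = _contact_kinds(lig_res, bind_res, params, classes)
            if not kinds:
                continue
            datapoints.append(AtlasDatapoint(
                ligand_type=lig_res.residue_type,
                binder_type=bind_res.residue_type,
                ligand_origin=(complex_.source_id, lig_res.chain_id, lig_res.label),
                binder_origin=(complex_.source_id, bind_res.chain_id, bind_res.label),
                ligand_atoms={a.name: frame.to_internal(a.xyz)
                              for a in lig_res.atoms},
                binder_atoms={a.name: frame.to_internal(a.xyz)
                              for a in bind_res.atoms},
                interaction_kinds=kinds,
            ))
    return datapoints


@dataclass
class Atlas:
    """Full datapoint collection plus provenance."""

    datapoints: list[AtlasDatapoint] = field(default_factory=list)
    params: AtlasParams = field(default_factory=AtlasParams)
    sources: list[str] = field(default_factory=list)

    def pages(self) -> dict[str, list[AtlasDatapoint]]:
        out: dict[str, list[AtlasDatapoint]] = {}
        for dp in self.datapoints:
            out.setdefault(dp.ligand_type, []).append(dp)
        return out

    def maps(self) -> dict[tuple[str, str], list[AtlasDatapoint]]:
        out: dict[tuple[str, str], list[AtlasDatapoint]] = {}
        for dp in self.datapoints:
            out.setdefault((dp.ligand_type, dp.binder_type), []).append(dp)
        return out

    def __len__(self) -> int:
        return len(self.datapoints)


def build_atlas(collection: list[StructureComplex],
                params: AtlasParams | None = None,
                classes: ChemicalClasses = DEFAULT_CLASSES) -> Atlas:
    """Concatenate datapoints over a collection, deterministically ordered
    by (source, ligand position, binder position)."""
    params = params or AtlasParams()
    datapoints: list[AtlasDatapoint] = []
    sources: list[str] = []
    for cx in collection:
        datapoints.extend(extract_datapoints(cx, params, classes))
        sources.append(cx.complex_id)
    datapoints.sort(key=AtlasDatapoint.sort_key)
    return Atlas(datapoints=datapoints, params=params, sources=sorted(sources))


def atlas_stats(atlas: Atlas):
    """Page/map count tables.

    Returns ``(pages, maps)`` DataFrames: per-ligand-type totals, and per
    (ligand, binder) combination counts ranked within each page.
    """
    rows = [{"ligand_type": dp.ligand_type, "binder_type": dp.binder_type}
            for dp in atlas.datapoints]
    if not rows:
        pages = pd.DataFrame(columns=["ligand_type", "count"])
        maps = pd.DataFrame(columns=["ligand_type", "binder_type", "count", "rank"])
        return pages, maps
    df = pd.DataFrame(rows)
    pages = (df.groupby("ligand_type").size().reset_index(name="count")
             .sort_values(["count", "ligand_type"], ascending=[False, True])
             .reset_index(drop=True))
    maps = (df.groupby(["ligand_type", "binder_type"]).size()
            .reset_index(name="count"))
    maps["rank"] = (maps.groupby("ligand_type")["count"]
                    .rank(method="first", ascending=False).astype(int))
    maps = (maps.sort_values(["ligand_type", "rank"]).reset_index(drop=True))
    return pages, maps


def top_partners(atlas: Atlas, ligand_type: str, n: int = 3):
    """Ranked (binder_type, count) partners of one page."""
    _, maps = atlas_stats(atlas)
    sub = maps[maps.ligand_type == ligand_type].head(n)
    return list(zip(sub.binder_type, sub["count"]))


# --- serialization -------------------------------------------------------

def _round3(x: float) -> float:
    return round(float(x), 6)


def atlas_to_dict(atlas: Atlas) -> dict:
    return {
        "schema": "atlas",
        "schema_version": ATLAS_SCHEMA_VERSION,
        "params": {
            "radii": {k: getattr(atlas.params.radii, k) for k in INTERACTION_KINDS},
            "min_ligand_length": atlas.params.min_ligand_length,
            "max_ligand_length": atlas.params.max_ligand_length,
            "skip_backbone_atoms": atlas.params.skip_backbone_atoms,
            "allow_intramolecular": atlas.params.allow_intramolecular,
        },
        "sources": list(atlas.sources),
        "datapoints": [
            {
                "ligand_type": dp.ligand_type,
                "binder_type": dp.binder_type,
                "ligand_origin": list(dp.ligand_origin),
                "binder_origin": list(dp.binder_origin),
                "ligand_atoms": {k: [_round3(v) for v in xyz]
                                 for k, xyz in sorted(dp.ligand_atoms.items())},
                "binder_atoms": {k: [_round3(v) for v in xyz]
                                 for k, xyz in sorted(dp.binder_atoms.items())},
                "interaction_kinds": sorted(dp.interaction_kinds),
            }
            for dp in atlas.datapoints
        ],
    }


def save_atlas(atlas: Atlas, path: str | Path) -> None:
    Path(path).write_text(json.dumps(atlas_to_dict(atlas), indent=1,
                                     sort_keys=True) + "\n")


def atlas_from_dict(data: dict) -> Atlas:
    if data.get("schema") != "atlas":
        raise SchemaVersionError("not an atlas artifact")
    if data.get("schema_version") != ATLAS_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"atlas schema version {data.get('schema_version')!r} unsupported")
    p = data["params"]
    params = AtlasParams(
        radii=InteractionRadii(**p["radii"]),
        min_ligand_length=p["min_ligand_length"],
        max_ligand_length=p["max_ligand_length"],
        skip_backbone_atoms=p["skip_backbone_atoms"],
        allow_intramolecular=p["allow_intramolecular"],
    )
    datapoints = [
        AtlasDatapoint(
            ligand_type=d["ligand_type"],
            binder_type=d["binder_type"],
            ligand_origin=tuple(d["ligand_origin"]),
            binder_origin=tuple(d["binder_origin"]),
            ligand_atoms={k: np.array(v) for k, v in d["ligand_atoms"].items()},
            binder_atoms={k: np.array(v) for k, v in d["binder_atoms"].items()},
            interaction_kinds=frozenset(d["interaction_kinds"]),
        )
        for d in data["datapoints"]
    ]
    return Atlas(datapoints=datapoints, params=params,
                 sources=list(data.get("sources", [])))


def load_atlas(path: str | Path) -> Atlas:
    with open(path) as fh:
        return atlas_from_dict(json.load(fh))
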