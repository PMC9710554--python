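"""Pocket grafting: transplant mined pockets onto a scaffold complex.

``graft`` expresses the scaffold's mutable binder residues in the internal
frame of a chosen scaffold ligand residue, scores every
(mutable position, pocket residue) pair with the spatial similarity
function, and applies mutations greedily in ascending score order — a pair
is applied iff its score is within the distance threshold θd and neither
the position nor the pocket residue has been consumed.  Side-chain
coordinates are copied from the pocket residue (transformed into the
scaffold frame) and flagged un-minimized; external side-chain repacking is
expected downstream.

``quick_graft`` extends this to several ligand positions at once: it
enumerates one candidate graft per (selection, pocket representative),
keeps combinations whose mutated binder positions are mutually exclusive,
and returns the n best by cumulative score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .chem import BACKBONE_ATOMS
from .errors import FrameError, GeometryError, GraftingError, InfeasibleGraftError
from .geometry import (Frame, ResiduePose, SimilarityWeights, build_frame,
                       spatial_similarity, transform_pose, virtual_cbeta)
from .pdbio import Atom, ResidueRecord, format_pdb
from .pockets import Pocket, PocketMember, _pose_of_datapoint
from .structures import StructureComplex, residue_pose

log = logging.getLogger(__name__)


@dataclass
class GraftingParams:
    """θd (``distance_threshold``) rejects bad-matching pocket residues."""

    distance_threshold: float = 12.0
    weights: SimilarityWeights = field(default_factory=SimilarityWeights)

    def __post_init__(self):
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be positive")


PositionId = str  # binder residue label
PocketResidueId = tuple[str, tuple[str, str, str]]  # (binder type, origin)


@dataclass
class Mutation:
    position: PositionId
    new_type: str
    pocket_residue: PocketResidueId
    score: float
    sidechain_atoms: list[tuple[str, np.ndarray]] = field(default_factory=list)


@dataclass
class Design:
    """A scaffold plus applied mutations (side chains un-minimized)."""

    scaffold: StructureComplex
    mutations: list[Mutation] = field(default_factory=list)
    ligand_mutations: list[tuple[PositionId, str]] = field(default_factory=list)
    total_score: float = 0.0
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        positions = [m.position for m in self.mutations]
        residues = [m.pocket_residue for m in self.mutations]
        if len(set(positions)) != len(positions):
            raise GraftingError("duplicate mutated position in design")
        if len(set(residues)) != len(residues):
            raise GraftingError("pocket residue reused in design")


def _find_residue(residues, label) -> ResidueRecord:
    label = str(label)
    for res in residues:
        if res.label == label:
            return res
    raise GraftingError(f"residue {label!r} not found")


def _representative_member(pocket: Pocket, cluster_index: int = 0) -> PocketMember:
    if not pocket.clusters:
        raise GraftingError(
            f"pocket {pocket.pocket_id} has no clusters; run cluster_pocket first")
    rep_id = pocket.clusters[cluster_index].representative
    return pocket.member(rep_id)


def _scaffold_pose_internal(res: ResidueRecord, frame: Frame) -> ResiduePose:
    return transform_pose(residue_pose(res), frame)


def graft(scaffold: StructureComplex, ligand_position: PositionId,
          pocket_member: PocketMember, mutable_positions,
          params: GraftingParams | None = None,
          provenance: str | None = None) -> Design:
    """Greedy similarity-ranked grafting of one pocket instance.

    ``pocket_member`` is a pocket representative (or any single pocket
    instance): one datapoint per binder type, in its ligand's internal
    frame.  ``mutable_positions`` are binder residue labels allowed to
    mutate.
    """
    params = params or GraftingParams()
    lig_res = _find_residue(scaffold.ligand, ligand_position)
    try:
        frame = build_frame(residue_pose(lig_res))
    except GeometryError as exc:
        raise FrameError(
            f"cannot build frame at ligand position {ligand_position}: {exc}"
        ) from exc

    mutable = [_find_residue(scaffold.binder, p) for p in mutable_positions]
    mutable.sort(key=lambda r: (r.seq_index, r.insertion_code))
    scaffold_poses = {}
    for res in mutable:
        try:
            scaffold_poses[res.label] = _scaffold_pose_internal(res, frame)
        except GeometryError as exc:
            log.warning("mutable position %s skipped: %s", res.label, exc)

    pocket_residues: list[tuple[PocketResidueId, ResiduePose]] = []
    for btype, dp in sorted(pocket_member.datapoints.items()):
        pocket_residues.append(((btype, dp.binder_origin),
                                _pose_of_datapoint(dp)))

    # full score matrix, then greedy consumption in ascending score order
    scored = []
    for pi, (label, pose) in enumerate(sorted(scaffold_poses.items())):
        for ri, (rid, rpose) in enumerate(pocket_residues):
            s = spatial_similarity(pose, rpose, params.weights)
            scored.append((s, pi, ri, label, rid, rpose))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))

    occupied_positions: set[PositionId] = set()
    occupied_residues: set[PocketResidueId] = set()
    mutations: list[Mutation] = []
    for s, _, _, label, rid, rpose in scored:
        if s > params.distance_threshold:
            break  # list is ascending: nothing later can qualify
        if label in occupied_positions or rid in occupied_residues:
            continue
        sidechain = [(name, frame.to_external(xyz))
                     for name, xyz in sorted(rpose.all_atoms.items())
                     if name not in BACKBONE_ATOMS]
        mutations.append(Mutation(position=label, new_type=rpose.residue_type,
                                  pocket_residue=rid, score=float(s),
                                  sidechain_atoms=sidechain))
        occupied_positions.add(label)
        occupied_residues.add(rid)
    return Design(scaffold=scaffold, mutations=mutations,
                  total_score=float(sum(m.score for m in mutations)),
                  provenance=[provenance] if provenance else [])


@dataclass
class LigandSelection:
    position: PositionId
    target_type: str


def quick_graft(scaffold: StructureComplex, pockets: list[Pocket],
                selections: list[LigandSelection], mutable_positions,
                params: GraftingParams | None = None,
                n: int = 1) -> list[Design]:
    """Best mutually compatible combination(s) of pocket grafts.

    For each ligand selection, every cluster representative of every pocket
    with the selection's target ligand type yields one candidate graft.  A
    combination (one candidate per selection) is feasible iff no binder
    position is mutated twice; combinations are ranked by cumulative score
    (a graft applying zero mutations counts as +inf so empty grafts rank
    last), and the best ``n`` are materialized as Designs.

    Raises :class:`InfeasibleGraftError` (listing contested positions) when
    no feasible combination exists.
    """
    params = params or GraftingParams()
    if not selections:
        raise GraftingError("at least one ligand selection required")
    candidates_per_sel: list[list[tuple[str, Design]]] = []
    for sel in selections:
        eligible = [p for p in pockets if p.ligand_type == sel.target_type]
        if not eligible:
            raise GraftingError(
                f"no pockets available for ligand type {sel.target_type}")
        cands = []
        for pocket in eligible:
            for ci in range(len(pocket.clusters)):
                member = _representative_member(pocket, ci)
                tag = f"{pocket.pocket_id}/cluster{ci}"
                d = graft(scaffold, sel.position, member, mutable_positions,
                          params, provenance=tag)
                cands.append((tag, d))
        candidates_per_sel.append(cands)

    combos = []
    conflicts: set[PositionId] = set()
    for combo in product(*candidates_per_sel):
        seen: set[PositionId] = set()
        clash = False
        for _, d in combo:
            pos = {m.position for m in d.mutations}
            overlap = seen & pos
            if overlap:
                conflicts |= overlap
                clash = True
                break
            seen |= pos
        if clash:
            continue
        score = sum(d.total_score if d.mutations else np.inf for _, d in combo)
        combos.append((score, combo))
    if not combos:
        raise InfeasibleGraftError(
            "no conflict-free combination of pocket grafts",
            conflicts=sorted(conflicts))
    combos.sort(key=lambda t: (t[0], tuple(tag for tag, _ in t[1])))

    designs = []
    for score, combo in combos[:n]:
        mutations = [m for _, d in combo for m in d.mutations]
        designs.append(Design(
            scaffold=scaffold,
            mutations=mutations,
            ligand_mutations=[(sel.position, sel.target_type)
                              for sel in selections],
            total_score=float(sum(m.score for m in mutations)),
            provenance=[tag for tag, _ in combo]))
    return designs


# --- output --------------------------------------------------------------

def _apply_mutation(res: ResidueRecord, new_type: str,
                    sidechain: list[tuple[str, np.ndarray]]) -> ResidueRecord:
    backbone = [a for a in res.atoms if a.name in BACKBONE_ATOMS]
    out = ResidueRecord(chain_id=res.chain_id, seq_index=res.seq_index,
                        residue_type=new_type,
                        insertion_code=res.insertion_code)
    out.atoms = [Atom(a.name, a.xyz.copy(), a.occupancy, a.bfactor, a.element)
                 for a in backbone]
    for name, xyz in sidechain:
        out.atoms.append(Atom(name, np.asarray(xyz), occupancy=1.0,
                              bfactor=0.0, element=name[0]))
    return out


def design_chains(design: Design):
    """Scaffold chains with mutations applied; returns (chains, altered)
    where ``altered`` marks grafted side-chain atoms for the occupancy-0
    convention."""
    by_pos = {m.position: m for m in design.mutations}
    lig_by_pos = dict(design.ligand_mutations)
    altered: set[tuple[str, str, str]] = set()
    binder_out = []
    for res in design.scaffold.binder:
        m = by_pos.get(res.label)
        if m is None:
            binder_out.append(res)
            continue
        new = _apply_mutation(res, m.new_type, m.sidechain_atoms)
        binder_out.append(new)
        for name, _ in m.sidechain_atoms:
            altered.add((res.chain_id, res.label, name))
    ligand_out = []
    for res in design.scaffold.ligand:
        t = lig_by_pos.get(res.label)
        if t is None or t == res.residue_type:
            ligand_out.append(res)
            continue
        # ligand mutated in type only: keep backbone (+CB when present),
        # drop the old side chain; repacking is external
        keep = [a for a in res.atoms if a.name in BACKBONE_ATOMS + ("CB",)]
        if t == "GLY":
            keep = [a for a in keep if a.name != "CB"]
        new = ResidueRecord(chain_id=res.chain_id, seq_index=res.seq_index,
                            residue_type=t, insertion_code=res.insertion_code)
        new.atoms = keep
        ligand_out.append(new)
    chains = [(design.scaffold.binder_chain_id, binder_out),
              (design.scaffold.ligand_chain_id, ligand_out)]
    return chains, altered


def design_metadata(design: Design) -> dict:
    return {
        "schema": "design",
        "schema_version": 1,
        "scaffold": design.scaffold.complex_id,
        "total_score": round(design.total_score, 9),
        "provenance": design.provenance,
        "ligand_mutations": [[p, t] for p, t in design.ligand_mutations],
        "mutations": [
            {
                "position": m.position,
                "new_type": m.new_type,
                "pocket_residue": [m.pocket_residue[0],
                                   list(m.pocket_residue[1])],
                "score": round(m.score, 9),
            }
            for m in design.mutations
        ],
    }


def write_design(design: Design, path: str | Path,
                 sidecar: bool = True) -> None:
    """Write the design as PDB (grafted side-chain atoms at occupancy 0.00)
    plus a JSON metadata sidecar."""
    path = Path(path)
    chains, altered = design_chains(design)
    path.write_text(format_pdb(chains, altered=altered))
    if sidecar:
        path.with_suffix(".json").write_text(
            json.dumps(design_metadata(design), indent=1, sort_keys=True) + "\n")
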