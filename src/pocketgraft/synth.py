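"""Synthetic complex generator.

Builds small, fully controlled protein-peptide complexes for testing and
calibration: a ligand peptide with an ideal backbone, plus binder residues
placed around it at requested contact distances.  All geometry is
deterministic for a given seed.

What it emulates: canonical heavy-atom inventories, ideal backbone bond
lengths, adjustable backbone dihedrals, and ligand-binder contacts at exact
distances with a controllable orientation jitter.  What it does not
emulate: rotamer statistics, packing, clashes between binder residues, or
crystallographic noise — side chains are idealized extended trees, so
fixtures exercise the bookkeeping and geometry contracts of the toolchain,
not the energetics of real interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import (CANONICAL_RESIDUES, DEFAULT_CONTACT_ATOM, ONE_TO_THREE,
                   SIDECHAIN_TREE)
from .errors import FixtureError
from .geometry import virtual_cbeta
from .pdbio import Atom, Chain, ResidueRecord, format_pdb
from .structures import StructureComplex

# Ideal backbone geometry (Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5

SIDECHAIN_BOND = 1.50

_GOLDEN = 2.399963229728653  # golden angle, radians


def _rotation(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position of atom d given a-b-c with bond |c-d|,
    angle b-c-d and torsion a-b-c-d."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([-np.cos(angle),
                          np.sin(angle) * np.cos(torsion),
                          np.sin(angle) * np.sin(torsion)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(phi_psi: list[tuple[float, float]]):
    """Backbone (N, CA, C) triples for a chain with the given dihedrals.

    ``phi_psi[i]`` = (phi_i, psi_i); phi of the first residue and psi of the
    last are only used for carbonyl-O placement.
    """
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    triples = [(n0, ca0, c0)]
    for i in range(1, len(phi_psi)):
        n_prev, ca_prev, c_prev = triples[-1]
        psi_prev = phi_psi[i - 1][1]
        n = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca = place_atom(ca_prev, c_prev, n, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c = place_atom(c_prev, n, ca, BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])
        triples.append((n, ca, c))
    return triples


def _sidechain_atoms(res_type: str, n: np.ndarray, ca: np.ndarray,
                     c: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Idealized extended side chain: CB by tetrahedral construction, then
    the residue's atom tree laid out deterministically."""
    if res_type == "GLY":
        return []
    cb = virtual_cbeta(n, ca, c)
    coords = {"N": n, "CA": ca, "C": c, "CB": cb}
    parents = {"CB": "CA", "CA": "N"}
    out = [("CB", cb)]
    sibling_rank: dict[str, int] = {}
    for child, parent in SIDECHAIN_TREE[res_type]:
        grand = parents[parent]
        k = sibling_rank.get(parent, 0)
        sibling_rank[parent] = k + 1
        dir0 = coords[parent] - coords[grand]
        dir0 = dir0 / np.linalg.norm(dir0)
        ref = np.cross(dir0, np.array([0.1234, 0.5678, 0.8101]))
        if np.linalg.norm(ref) < 1e-6:
            ref = np.cross(dir0, np.array([1.0, 0.0, 0.0]))
        ref /= np.linalg.norm(ref)
        tilted = _rotation(ref, np.deg2rad(55.0)) @ dir0
        direction = _rotation(dir0, k * _GOLDEN) @ tilted
        pos = coords[parent] + SIDECHAIN_BOND * direction
        coords[child] = pos
        parents[child] = parent
        out.append((child, pos))
    return out


def build_residue(res_type: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                  chain_id: str, seq_index: int,
                  psi_deg: float = 135.0) -> ResidueRecord:
    """Full heavy-atom residue from its backbone triple."""
    o = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi_deg - 180.0)
    atoms = [Atom("N", n, element="N"), Atom("CA", ca, element="C"),
             Atom("C", c, element="C"), Atom("O", o, element="O")]
    for name, xyz in _sidechain_atoms(res_type, n, ca, c):
        element = name[0]
        atoms.append(Atom(name, xyz, element=element))
    return ResidueRecord(chain_id=chain_id, seq_index=seq_index,
                         residue_type=res_type, atoms=atoms)


def _norm_type(res: str) -> str:
    res = res.upper()
    if len(res) == 1:
        if res not in ONE_TO_THREE:
            raise FixtureError(f"unknown residue code {res!r}")
        return ONE_TO_THREE[res]
    if res not in CANONICAL_RESIDUES:
        raise FixtureError(f"unknown residue type {res!r}")
    return res


def peptide_chain(sequence, phi: float = -139.0, psi: float = 135.0,
                  chain_id: str = "B", start: int = 1,
                  offset: np.ndarray | None = None,
                  phi_psi: list[tuple[float, float]] | None = None
                  ) -> list[ResidueRecord]:
    """Peptide with uniform (or per-residue) backbone dihedrals.

    ``sequence`` is a string of one-letter codes or an iterable of
    three-letter codes.  Defaults give an extended conformation.
    """
    types = [_norm_type(s) for s in sequence]
    if phi_psi is None:
        phi_psi = [(phi, psi)] * len(types)
    if len(phi_psi) != len(types):
        raise FixtureError("phi_psi length must match sequence length")
    triples = build_backbone(phi_psi)
    shift = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
    residues = []
    for i, (res_type, (n, ca, c)) in enumerate(zip(types, triples)):
        residues.append(build_residue(
            res_type, n + shift, ca + shift, c + shift,
            chain_id, start + i, psi_deg=phi_psi[i][1]))
    return residues


@dataclass
class ContactSpec:
    """One binder residue placed at an exact distance from a ligand residue.

    Default contact atoms are the residues' side-chain tips.  When
    ``ligand_group``/``binder_group`` name several atoms, the *minimum*
    inter-group distance is driven to ``distance`` instead.
    """

    binder_type: str
    ligand_index: int  # 0-based index into the ligand sequence
    distance: float = 3.5
    ligand_atom: str | None = None
    binder_atom: str | None = None
    ligand_group: tuple[str, ...] | None = None
    binder_group: tuple[str, ...] | None = None


@dataclass
class ComplexSpec:
    """Recipe for one synthetic complex."""

    ligand_sequence: str | list[str]
    contacts: list[ContactSpec] = field(default_factory=list)
    binder_chain_id: str = "A"
    ligand_chain_id: str = "B"
    binder_padding: int | None = None  # None: pad binder to 40 residues
    jitter_deg: float = 8.0
    source_id: str = "synthetic"


def _contact_direction(k: int, rng: np.random.Generator,
                       jitter_deg: float) -> np.ndarray:
    """Spread directions around the ligand chain axis (x), jittered."""
    theta = k * _GOLDEN + (rng.uniform(-1, 1) * np.deg2rad(jitter_deg))
    axial = 0.25 * np.sin(1.3 * k + 0.7)
    d = np.array([axial, np.cos(theta), np.sin(theta)])
    return d / np.linalg.norm(d)


def _align(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector u onto unit vector v."""
    cross = np.cross(u, v)
    dot = float(np.dot(u, v))
    if np.linalg.norm(cross) < 1e-9:
        if dot > 0:
            return np.eye(3)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, ref)
        return _rotation(axis, np.pi)
    return _rotation(cross, np.arccos(np.clip(dot, -1.0, 1.0)))


def _place_binder_residue(contact: ContactSpec, ligand: list[ResidueRecord],
                          seq_index: int, chain_id: str, direction: np.ndarray,
                          rng: np.random.Generator,
                          jitter_deg: float) -> ResidueRecord:
    res_type = _norm_type(contact.binder_type)
    if contact.distance <= 0:
        raise FixtureError("contact distance must be positive")
    if not 0 <= contact.ligand_index < len(ligand):
        raise FixtureError(f"ligand index {contact.ligand_index} out of range")
    lig_res = ligand[contact.ligand_index]
    lig_atom_name = contact.ligand_atom or DEFAULT_CONTACT_ATOM[lig_res.residue_type]
    anchor = lig_res.coords(lig_atom_name)
    if anchor is None:
        raise FixtureError(
            f"ligand residue {lig_res.residue_type} has no atom {lig_atom_name}")

    template = _template_residue(res_type, chain_id, seq_index)
    b_atom_name = contact.binder_atom or DEFAULT_CONTACT_ATOM[res_type]
    b_atom = template.coords(b_atom_name)
    if b_atom is None:
        raise FixtureError(f"binder residue {res_type} has no atom {b_atom_name}")

    # orient the template so the residue body points away from the ligand
    body = template.coords("CA") - b_atom
    nb = np.linalg.norm(body)
    rot = _align(body / nb, direction) if nb > 1e-9 else np.eye(3)
    if jitter_deg > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rot = _rotation(axis, rng.uniform(0, np.deg2rad(jitter_deg))) @ rot

    pivot = b_atom.copy()
    target = anchor + contact.distance * direction
    placed = ResidueRecord(chain_id=chain_id, seq_index=seq_index,
                           residue_type=res_type)
    for atom in template.atoms:
        placed.atoms.append(Atom(atom.name, rot @ (atom.xyz - pivot) + target,
                                 element=atom.element))

    if contact.ligand_group or contact.binder_group:
        lg = contact.ligand_group or (lig_atom_name,)
        bg = contact.binder_group or (b_atom_name,)
        lig_pts = np.array([lig_res.coords(a) for a in lg])
        if any(p is None for p in lig_pts):
            raise FixtureError("unknown atom in ligand_group")
        for _ in range(200):
            b_pts = np.array([placed.coords(a) for a in bg])
            d = np.linalg.norm(lig_pts[:, None, :] - b_pts[None, :, :], axis=2)
            err = contact.distance - float(d.min())
            if abs(err) < 1e-9:
                break
            for atom in placed.atoms:
                atom.xyz = atom.xyz + err * direction
        else:
            raise FixtureError("group contact placement did not converge")
    return placed


def _template_residue(res_type: str, chain_id: str, seq_index: int) -> ResidueRecord:
    n = np.zeros(3)
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    return build_residue(res_type, n, ca, c, chain_id, seq_index)


def build_complex(spec: ComplexSpec, seed: int) -> StructureComplex:
    """Materialize a spec into a StructureComplex (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    ligand = peptide_chain(spec.ligand_sequence, chain_id=spec.ligand_chain_id)
    binder: list[ResidueRecord] = []
    for k, contact in enumerate(spec.contacts):
        direction = _contact_direction(k, rng, spec.jitter_deg)
        binder.append(_place_binder_residue(
            contact, ligand, k + 1, spec.binder_chain_id, direction, rng,
            spec.jitter_deg))
    padding = spec.binder_padding
    if padding is None:
        padding = max(0, 40 - len(binder))
    if padding:
        lig_ca = np.array([r.coords("CA") for r in ligand])
        center = lig_ca.mean(axis=0)
        pad = peptide_chain(["ALA"] * padding, phi=-57.0, psi=-47.0,
                            chain_id=spec.binder_chain_id,
                            start=len(binder) + 1,
                            offset=center + np.array([0.0, 0.0, 40.0]))
        binder.extend(pad)
    if not binder:
        raise FixtureError("spec produced an empty binder chain")
    return StructureComplex(binder=binder, ligand=ligand,
                            source_id=spec.source_id)


def generate_fixture(spec: ComplexSpec, seed: int) -> str:
    """PDB text for a spec (byte-identical for identical spec + seed)."""
    cx = build_complex(spec, seed)
    return format_pdb(cx.chains())


def write_fixture(spec: ComplexSpec, seed: int, path) -> None:
    from pathlib import Path
    Path(path).write_text(generate_fixture(spec, seed))


def full_coverage_specs() -> list[ComplexSpec]:
    """400 one-contact complexes covering every ligand x binder type pair.

    Each ligand is a GLY-X-GLY tripeptide (the minimum ligand length) with
    one binder residue of type Y placed 3.5 Å from the central residue's
    contact atom — inside every default interaction radius.
    """
    specs = []
    for lig in CANONICAL_RESIDUES:
        for bind in CANONICAL_RESIDUES:
            specs.append(ComplexSpec(
                ligand_sequence=["GLY", lig, "GLY"],
                contacts=[ContactSpec(binder_type=bind, ligand_index=1,
                                      distance=3.5)],
                jitter_deg=6.0,
                source_id=f"cov_{lig}_{bind}",
            ))
    return specs


def full_coverage_collection(seed: int) -> list[StructureComplex]:
    """Materialized full-coverage collection; sub-seeds derived per spec."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=400)
    return [build_complex(spec, int(s))
            for spec, s in zip(full_coverage_specs(), seeds)]


def demo_collection_specs(n_copies: int = 5) -> list[ComplexSpec]:
    """Small end-to-end collection: repeated Arg-ligand pockets (Asp, Glu,
    Trp binder residues) so that the DEW-style itemset is frequent, plus
    contacts on the flanking residues keeping the whole ligand in range."""
    specs = []
    for i in range(n_copies):
        specs.append(ComplexSpec(
            ligand_sequence=["ALA", "ARG", "ALA"],
            contacts=[
                ContactSpec("ASP", 1, 3.4),
                ContactSpec("GLU", 1, 3.8),
                ContactSpec("TRP", 1, 3.8),
                ContactSpec("SER", 0, 3.2),
                ContactSpec("ASN", 2, 3.2),
            ],
            jitter_deg=10.0,
            source_id=f"demo_{i:02d}",
        ))
    return specs


def demo_collection(seed: int, n_copies: int = 5) -> list[StructureComplex]:
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_copies)
    return [build_complex(spec, int(s))
            for spec, s in zip(demo_collection_specs(n_copies), seeds)]
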