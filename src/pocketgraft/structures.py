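"""Complex preprocessing: ligand/binder pairing, trimming and filters.

A :class:`StructureComplex` is the unit every downstream stage consumes:
one binder chain (the protein forming pockets) and one ligand chain (the
peptide whose side chains sit at the centre of each analysis frame).

Role assignment is length-based: any chain whose length falls inside the
ligand length window is a ligand candidate, any chain at least
``min_binder_length`` long is a binder candidate, and one chain may play
both roles in different pairs.  A pair qualifies when at least one ligand
residue lies within ``max_contact_distance`` (Cα-Cα) of the binder.
Ligand termini with no binder residue in range are trimmed — contiguous
terminal segments only, so ligands stay contiguous peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .geometry import ResiduePose, virtual_cbeta
from .pdbio import Chain, ResidueRecord

log = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Filters applied when pairing chains into complexes.

    ``max_contact_distance`` is the Cα-Cα contact cutoff in Å.
    ``max_ligand_length`` of ``None`` leaves ligand candidates uncapped at
    this stage (the atlas stage applies its own window).
    """

    max_contact_distance: float = 8.0
    min_binder_length: int = 40
    min_ligand_length: int = 3
    max_ligand_length: int | None = None
    include_hydrogen_atoms: bool = False

    def __post_init__(self):
        if self.max_contact_distance <= 0:
            raise ValueError("max_contact_distance must be positive")
        if self.min_binder_length < 1 or self.min_ligand_length < 1:
            raise ValueError("length thresholds must be >= 1")
        if (self.max_ligand_length is not None
                and self.max_ligand_length < self.min_ligand_length):
            raise ValueError("max_ligand_length < min_ligand_length")


@dataclass
class StructureComplex:
    """One binder chain paired with one (possibly trimmed) ligand chain."""

    binder: list[ResidueRecord]
    ligand: list[ResidueRecord]
    source_id: str = "complex"

    def __post_init__(self):
        if not self.binder or not self.ligand:
            raise ValueError("binder and ligand must be non-empty")
        if self.binder[0].chain_id == self.ligand[0].chain_id:
            raise ValueError("binder and ligand must live on different chains")

    @property
    def binder_chain_id(self) -> str:
        return self.binder[0].chain_id

    @property
    def ligand_chain_id(self) -> str:
        return self.ligand[0].chain_id

    def chains(self) -> list[Chain]:
        return [(self.binder_chain_id, self.binder),
                (self.ligand_chain_id, self.ligand)]

    @property
    def complex_id(self) -> str:
        return f"{self.source_id}_{self.binder_chain_id}{self.ligand_chain_id}"


def residue_pose(res: ResidueRecord) -> ResiduePose:
    """Geometric pose of a residue; a virtual Cβ is built when the real one
    is absent (glycine, truncated side chains).

    Raises :class:`GeometryError` when backbone atoms are missing.
    """
    ca, c, n = res.coords("CA"), res.coords("C"), res.coords("N")
    if ca is None or c is None or n is None:
        raise GeometryError(
            f"residue {res.chain_id}:{res.label} lacks a complete backbone")
    cb = res.coords("CB")
    if cb is None:
        cb = virtual_cbeta(n, ca, c)
    return ResiduePose(
        calpha=ca, cbeta=cb, carbonyl_c=c, amide_n=n,
        residue_type=res.residue_type,
        all_atoms={a.name: a.xyz for a in res.atoms},
    )


def _calpha_matrix(residues: list[ResidueRecord]) -> np.ndarray:
    coords = []
    for res in residues:
        ca = res.coords("CA")
        coords.append(ca if ca is not None else np.full(3, np.inf))
    return np.asarray(coords)


def _min_dist_to_binder(ligand_ca: np.ndarray, binder_ca: np.ndarray) -> np.ndarray:
    """Per-ligand-residue minimum Cα-Cα distance to the binder."""
    finite = np.isfinite(binder_ca).all(axis=1)
    if not finite.any():
        return np.full(len(ligand_ca), np.inf)
    diff = ligand_ca[:, None, :] - binder_ca[None, finite, :]
    with np.errstate(invalid="ignore"):
        d = np.sqrt((diff ** 2).sum(axis=2))
    d[~np.isfinite(ligand_ca).all(axis=1)] = np.inf
    return np.nanmin(d, axis=1)


def split_complexes(chains: list[Chain], params: PreprocessParams,
                    source_id: str = "complex") -> list[StructureComplex]:
    """Enumerate qualifying (binder, ligand) chain pairs.

    Returns an empty list when no pair qualifies.  Ligand chains are trimmed
    at the termini: leading/trailing residues farther than the contact
    cutoff from every binder residue are dropped; interior residues are
    never removed.
    """
    complexes: list[StructureComplex] = []
    for b_id, binder in chains:
        if len(binder) < params.min_binder_length:
            continue
        binder_ca = _calpha_matrix(binder)
        for l_id, ligand in chains:
            if l_id == b_id:
                continue
            if len(ligand) < params.min_ligand_length:
                continue
            if (params.max_ligand_length is not None
                    and len(ligand) > params.max_ligand_length):
                continue
            mind = _min_dist_to_binder(_calpha_matrix(ligand), binder_ca)
            in_contact = mind <= params.max_contact_distance
            if not in_contact.any():
                continue
            lo = int(np.argmax(in_contact))
            hi = len(ligand) - int(np.argmax(in_contact[::-1]))
            trimmed = ligand[lo:hi]
            if len(trimmed) < params.min_ligand_length:
                continue
            complexes.append(StructureComplex(
                binder=binder, ligand=trimmed, source_id=source_id))
    return complexes


# --- secondary structure -------------------------------------------------

HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -90.0)
STRAND_PSI = ((90.0, 180.0), (-180.0, -170.0))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees (IUPAC convention)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def classify_residue_ss(phi: float | None, psi: float | None) -> str:
    """'helix', 'strand' or 'coil' from a backbone dihedral window.

    This is a coarse dihedral-window classifier, not DSSP: it ignores
    hydrogen bonding, so boundary residues may be labelled differently
    than DSSP would.
    """
    if phi is None or psi is None:
        return "coil"
    if HELIX_PHI[0] <= phi <= HELIX_PHI[1] and HELIX_PSI[0] <= psi <= HELIX_PSI[1]:
        return "helix"
    if STRAND_PHI[0] <= phi <= STRAND_PHI[1]:
        for lo, hi in STRAND_PSI:
            if lo <= psi <= hi:
                return "strand"
    return "coil"


def backbone_dihedrals(residues: list[ResidueRecord]):
    """Per-residue (phi, psi); None at chain termini or missing atoms."""
    out = []
    for i, res in enumerate(residues):
        phi = psi = None
        n, ca, c = res.coords("N"), res.coords("CA"), res.coords("C")
        if n is not None and ca is not None and c is not None:
            if i > 0:
                prev_c = residues[i - 1].coords("C")
                if prev_c is not None:
                    phi = dihedral(prev_c, n, ca, c)
            if i + 1 < len(residues):
                next_n = residues[i + 1].coords("N")
                if next_n is not None:
                    psi = dihedral(n, ca, c, next_n)
        else:
            log.warning("residue %s:%s missing backbone atoms; classified coil",
                        res.chain_id, res.label)
        out.append((phi, psi))
    return out


def secondary_structure_fractions(residues: list[ResidueRecord]) -> dict[str, float]:
    labels = [classify_residue_ss(phi, psi)
              for phi, psi in backbone_dihedrals(residues)]
    n = len(labels)
    return {kind: labels.count(kind) / n for kind in ("helix", "strand", "coil")}


@dataclass
class SecondaryStructureBounds:
    """Optional lower/upper bounds on binder helix / strand / structured
    (helix+strand) content, each a fraction in [0, 1]."""

    min_helix: float | None = None
    max_helix: float | None = None
    min_strand: float | None = None
    max_strand: float | None = None
    min_structured: float | None = None
    max_structured: float | None = None


def filter_secondary_structure(complex_: StructureComplex,
                               bounds: SecondaryStructureBounds) -> bool:
    """True when the binder's secondary-structure content satisfies the
    bounds."""
    if len(complex_.binder) < 4:
        raise ValueError("binder too short for dihedral classification")
    frac = secondary_structure_fractions(complex_.binder)
    checks = [
        (bounds.min_helix, frac["helix"], True),
        (bounds.max_helix, frac["helix"], False),
        (bounds.min_strand, frac["strand"], True),
        (bounds.max_strand, frac["strand"], False),
        (bounds.min_structured, frac["helix"] + frac["strand"], True),
        (bounds.max_structured, frac["helix"] + frac["strand"], False),
    ]
    for bound, value, is_min in checks:
        if bound is None:
            continue
        if is_min and value < bound:
            return False
        if not is_min and value > bound:
            return False
    return True
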