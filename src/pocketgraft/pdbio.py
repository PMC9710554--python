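"""PDB reading and writing.

Reading goes through gemmi (robust against real-world PDB quirks); writing
is done by an in-package formatter so that ATOM records are byte-stable —
a zero-mutation design must reproduce its scaffold's ATOM records exactly.

Conventions:

* only canonical residues are kept (MSE read as MET); everything else,
  including waters and heteroatoms, is skipped with a warning;
* altloc conformers are resolved to the highest-occupancy atom (first on
  tie);
* hydrogens are stripped unless explicitly requested;
* author numbering is preserved; insertion codes are appended to the
  sequence number to keep residue labels unique.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .chem import CANONICAL_RESIDUES, RESIDUE_ALIASES
from .errors import EmptyInputError, FormatError

log = logging.getLogger(__name__)


@dataclass
class Atom:
    name: str
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""


@dataclass
class ResidueRecord:
    """One canonical residue: identity plus heavy-atom coordinates."""

    chain_id: str
    seq_index: int
    residue_type: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def label(self) -> str:
        """Author residue identifier, insertion code appended ('52', '52A')."""
        return f"{self.seq_index}{self.insertion_code}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.xyz

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))


Chain = tuple[str, list[ResidueRecord]]


def _element_of(name: str, elem: str) -> str:
    if elem:
        return elem.upper()
    stripped = name.strip()
    return stripped[:1] if stripped else ""


def read_pdb(path: str | Path, include_hydrogens: bool = False) -> list[Chain]:
    """Parse a PDB file into per-chain lists of canonical residues.

    Raises :class:`FormatError` on unparseable input and
    :class:`EmptyInputError` when no polymer chain with canonical residues
    remains after filtering.
    """
    path = Path(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(structure) == 0:
        raise EmptyInputError(f"{path}: no model found")
    model = structure[0]
    chains: list[Chain] = []
    skipped: set[str] = set()
    for chain in model:
        residues: list[ResidueRecord] = []
        for res in chain:
            name = res.name.strip().upper()
            name = RESIDUE_ALIASES.get(name, name)
            if name not in CANONICAL_RESIDUES:
                skipped.add(res.name.strip())
                continue
            record = ResidueRecord(
                chain_id=chain.name,
                seq_index=res.seqid.num,
                residue_type=name,
                insertion_code=(res.seqid.icode or "").strip(),
            )
            # altloc resolution: highest occupancy, first on tie
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                if atom.element.is_hydrogen and not include_hydrogens:
                    continue
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom_name in order:
                atom = best[atom_name]
                record.atoms.append(Atom(
                    name=atom_name,
                    xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=float(atom.occ),
                    bfactor=float(atom.b_iso),
                    element=atom.element.name.upper(),
                ))
            if record.atoms:
                residues.append(record)
        if residues:
            chains.append((chain.name, residues))
    if skipped:
        log.warning("%s: skipped non-canonical residues: %s",
                    path.name, ", ".join(sorted(skipped)))
    if not chains:
        raise EmptyInputError(f"{path}: no polymer chain with canonical residues")
    return chains


def _format_atom_name(name: str, element: str) -> str:
    # Columns 13-16: names of 1-2 char elements start at column 14 unless
    # the name itself is 4 characters wide.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"
    return f" {name:<3}"


def format_pdb(chains: list[Chain], altered: set | None = None) -> str:
    """Serialize chains as PDB text (ATOM/TER/END records).

    ``altered`` optionally holds ``(chain_id, residue_label, atom_name)``
    triples whose occupancy is forced to 0.00, the convention marking
    grafted, un-minimized side-chain atoms.
    """
    lines: list[str] = []
    serial = 1
    for chain_id, residues in chains:
        last = None
        for res in residues:
            for atom in res.atoms:
                occ = atom.occupancy
                if altered and (chain_id, res.label, atom.name) in altered:
                    occ = 0.0
                elem = _element_of(atom.name, atom.element)
                lines.append(
                    "ATOM  {serial:5d} {name}{alt}{res:>3} {chain}{seq:4d}{icode}"
                    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2}"
                    .format(serial=serial,
                            name=_format_atom_name(atom.name, elem),
                            alt=" ", res=res.residue_type, chain=chain_id[:1],
                            seq=res.seq_index,
                            icode=(res.insertion_code or " ")[:1],
                            x=atom.xyz[0], y=atom.xyz[1], z=atom.xyz[2],
                            occ=occ, b=atom.bfactor, elem=elem[:2]))
                serial += 1
            last = res
        if last is not None:
            lines.append(
                "TER   {serial:5d}      {res:>3} {chain}{seq:4d}{icode}"
                .format(serial=serial, res=last.residue_type,
                        chain=chain_id[:1], seq=last.seq_index,
                        icode=(last.insertion_code or " ")[:1]))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(chains: list[Chain], path: str | Path,
              altered: set | None = None) -> None:
    Path(path).write_text(format_pdb(chains, altered=altered))
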