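"""Amino-acid chemistry tables.

Residue vocabularies, heavy-atom inventories and the chemical-class table
used to classify atom-atom contacts (ionic / aromatic / hydrogen bond /
other).  The class table is deliberately data, not logic, so users can
override it: :func:`load_chemical_classes` reads the same JSON layout as
:data:`DEFAULT_CHEMICAL_CLASSES`.
"""

from __future__ import annotations

import json
from pathlib import Path

#: The 20 canonical residues, three-letter code -> one-letter code.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
CANONICAL_RESIDUES = tuple(sorted(THREE_TO_ONE))

#: Non-canonical residue names read as a canonical equivalent.
RESIDUE_ALIASES = {"MSE": "MET"}

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

#: Side-chain heavy atoms as a parent tree (child, parent), rooted at CB.
#: Order follows the standard PDB atom order.
SIDECHAIN_TREE = {
    "ALA": [],
    "ARG": [("CG", "CB"), ("CD", "CG"), ("NE", "CD"), ("CZ", "NE"),
            ("NH1", "CZ"), ("NH2", "CZ")],
    "ASN": [("CG", "CB"), ("OD1", "CG"), ("ND2", "CG")],
    "ASP": [("CG", "CB"), ("OD1", "CG"), ("OD2", "CG")],
    "CYS": [("SG", "CB")],
    "GLN": [("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("NE2", "CD")],
    "GLU": [("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("OE2", "CD")],
    "GLY": [],
    "HIS": [("CG", "CB"), ("ND1", "CG"), ("CD2", "CG"), ("CE1", "ND1"),
            ("NE2", "CE1")],
    "ILE": [("CG1", "CB"), ("CG2", "CB"), ("CD1", "CG1")],
    "LEU": [("CG", "CB"), ("CD1", "CG"), ("CD2", "CG")],
    "LYS": [("CG", "CB"), ("CD", "CG"), ("CE", "CD"), ("NZ", "CE")],
    "MET": [("CG", "CB"), ("SD", "CG"), ("CE", "SD")],
    "PHE": [("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"), ("CE1", "CD1"),
            ("CE2", "CD2"), ("CZ", "CE1")],
    "PRO": [("CG", "CB"), ("CD", "CG")],
    "SER": [("OG", "CB")],
    "THR": [("OG1", "CB"), ("CG2", "CB")],
    "TRP": [("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"), ("NE1", "CD1"),
            ("CE2", "CD2"), ("CE3", "CD2"), ("CZ2", "CE2"), ("CZ3", "CE3"),
            ("CH2", "CZ2")],
    "TYR": [("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"), ("CE1", "CD1"),
            ("CE2", "CD2"), ("CZ", "CE1"), ("OH", "CZ")],
    "VAL": [("CG1", "CB"), ("CG2", "CB")],
}


def sidechain_atom_names(residue_type: str) -> tuple[str, ...]:
    """Heavy side-chain atom names (CB included; empty for glycine)."""
    tree = SIDECHAIN_TREE[residue_type]
    if residue_type == "GLY":
        return ()
    return ("CB",) + tuple(child for child, _ in tree)


def expected_heavy_atoms(residue_type: str) -> tuple[str, ...]:
    """Canonical heavy-atom inventory (no OXT) for one residue type."""
    return ("N", "CA", "C", "O") + sidechain_atom_names(residue_type)


#: Representative "tip" atom per residue type, used as the default contact
#: atom when synthesising fixtures.  Glycine falls back to CA.
DEFAULT_CONTACT_ATOM = {
    "ALA": "CB", "ARG": "NH1", "ASN": "ND2", "ASP": "OD1", "CYS": "SG",
    "GLN": "NE2", "GLU": "OE1", "GLY": "CA", "HIS": "NE2", "ILE": "CD1",
    "LEU": "CD1", "LYS": "NZ", "MET": "CE", "PHE": "CZ", "PRO": "CG",
    "SER": "OG", "THR": "OG1", "TRP": "CZ2", "TYR": "OH", "VAL": "CG1",
}

#: Default chemical-class table.  Keys are residue types; values map class
#: names to side-chain atom name lists.  Histidine is both charged and
#: aromatic (ionic takes precedence during classification).
DEFAULT_CHEMICAL_CLASSES = {
    "positive": {
        "LYS": ["NZ"],
        "ARG": ["NE", "NH1", "NH2"],
        "HIS": ["ND1", "NE2"],
    },
    "negative": {
        "ASP": ["OD1", "OD2"],
        "GLU": ["OE1", "OE2"],
        "*": ["OXT"],  # C-terminal carboxylate on any residue
    },
    "aromatic": {
        "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        "TRP": ["CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
        "HIS": ["CG", "CD2", "CE1"],
    },
    "hbond_donor": {
        "ARG": ["NE", "NH1", "NH2"],
        "LYS": ["NZ"],
        "ASN": ["ND2"],
        "GLN": ["NE2"],
        "HIS": ["ND1", "NE2"],
        "TRP": ["NE1"],
        "SER": ["OG"],
        "THR": ["OG1"],
        "TYR": ["OH"],
    },
    "hbond_acceptor": {
        "ASP": ["OD1", "OD2"],
        "GLU": ["OE1", "OE2"],
        "ASN": ["OD1"],
        "GLN": ["OE1"],
        "HIS": ["ND1", "NE2"],
        "SER": ["OG"],
        "THR": ["OG1"],
        "TYR": ["OH"],
        "*": ["OXT"],
    },
    # Backbone N is a donor, backbone O an acceptor; only consulted when
    # backbone atoms participate in contact detection.
    "backbone_donor": ["N"],
    "backbone_acceptor": ["O", "OXT"],
}


class ChemicalClasses:
    """Resolved atom->class lookup built from a class table."""

    def __init__(self, table: dict | None = None):
        self.table = table if table is not None else DEFAULT_CHEMICAL_CLASSES
        self._sets: dict[str, set[tuple[str, str]]] = {}
        self._wild: dict[str, set[str]] = {}
        for cls in ("positive", "negative", "aromatic",
                    "hbond_donor", "hbond_acceptor"):
            pairs, wild = set(), set()
            for res, atoms in self.table.get(cls, {}).items():
                for atom in atoms:
                    if res == "*":
                        wild.add(atom)
                    else:
                        pairs.add((res, atom))
            self._sets[cls] = pairs
            self._wild[cls] = wild
        self._bb_donor = set(self.table.get("backbone_donor", []))
        self._bb_acceptor = set(self.table.get("backbone_acceptor", []))

    def _is(self, cls: str, residue_type: str, atom_name: str) -> bool:
        return ((residue_type, atom_name) in self._sets[cls]
                or atom_name in self._wild[cls])

    def is_positive(self, res: str, atom: str) -> bool:
        return self._is("positive", res, atom)

    def is_negative(self, res: str, atom: str) -> bool:
        return self._is("negative", res, atom)

    def is_aromatic(self, res: str, atom: str) -> bool:
        return self._is("aromatic", res, atom)

    def is_donor(self, res: str, atom: str, include_backbone: bool = False) -> bool:
        if include_backbone and atom in self._bb_donor:
            return True
        return self._is("hbond_donor", res, atom)

    def is_acceptor(self, res: str, atom: str, include_backbone: bool = False) -> bool:
        if include_backbone and atom in self._bb_acceptor:
            return True
        return self._is("hbond_acceptor", res, atom)


def load_chemical_classes(path: str | Path) -> ChemicalClasses:
    """Load a user-supplied chemical-class table (JSON, same layout as the
    default table)."""
    with open(path) as fh:
        return ChemicalClasses(json.load(fh))


DEFAULT_CLASSES = ChemicalClasses()
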