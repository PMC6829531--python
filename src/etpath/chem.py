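"""Small chemistry lookup tables used across the package.

Covalent radii back the distance criterion for bond inference; the
canonical heavy-atom sets define what a side-chain truncation may keep.
"""

from __future__ import annotations

# Covalent radii in Angstrom. Unknown elements fall back to DEFAULT_RADIUS.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "FE": 1.32,
}
DEFAULT_RADIUS = 1.5

# Distance added on top of the radius sum when deciding bonding.
COVALENT_TOLERANCE = 0.45
# Anything closer than this is treated as a recording artifact, never a bond.
CLASH_FLOOR = 0.4

# Elements that can act as hydrogen-bond donors/acceptors (heavy atoms only;
# the structures handled here typically lack hydrogens).
HBOND_ELEMENTS = frozenset({"N", "O", "S"})

# Residue names treated as solvent and dropped unless explicitly kept.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

# Canonical heavy-atom composition of the standard amino acids
# (backbone N, CA, C, O plus side chain; OXT omitted on purpose).
_BACKBONE = ("N", "CA", "C", "O")

CANONICAL_ATOMS: dict[str, frozenset[str]] = {
    "GLY": frozenset(_BACKBONE),
    "ALA": frozenset(_BACKBONE + ("CB",)),
    "SER": frozenset(_BACKBONE + ("CB", "OG")),
    "CYS": frozenset(_BACKBONE + ("CB", "SG")),
    "VAL": frozenset(_BACKBONE + ("CB", "CG1", "CG2")),
    "THR": frozenset(_BACKBONE + ("CB", "OG1", "CG2")),
    "LEU": frozenset(_BACKBONE + ("CB", "CG", "CD1", "CD2")),
    "ILE": frozenset(_BACKBONE + ("CB", "CG1", "CG2", "CD1")),
    "MET": frozenset(_BACKBONE + ("CB", "CG", "SD", "CE")),
    "PRO": frozenset(_BACKBONE + ("CB", "CG", "CD")),
    "PHE": frozenset(_BACKBONE + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    "TYR": frozenset(_BACKBONE + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH")),
    "TRP": frozenset(
        _BACKBONE
        + ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")
    ),
    "ASP": frozenset(_BACKBONE + ("CB", "CG", "OD1", "OD2")),
    "ASN": frozenset(_BACKBONE + ("CB", "CG", "OD1", "ND2")),
    "GLU": frozenset(_BACKBONE + ("CB", "CG", "CD", "OE1", "OE2")),
    "GLN": frozenset(_BACKBONE + ("CB", "CG", "CD", "OE1", "NE2")),
    "LYS": frozenset(_BACKBONE + ("CB", "CG", "CD", "CE", "NZ")),
    "ARG": frozenset(_BACKBONE + ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2")),
    "HIS": frozenset(_BACKBONE + ("CB", "CG", "ND1", "CD2", "CE1", "NE2")),
}

# Aromatic ring membership. Atom names can coincide between residues whose
# chemistry differs (PHE CD1 is aromatic, LEU CD1 is a methyl), so a
# truncation may only keep an atom whose ring membership is identical in
# the source and target residue types.
RING_ATOMS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
    "PRO": frozenset({"N", "CA", "CB", "CG", "CD"}),
}

# Redox cofactor residue names and the atoms that serve as electron
# entry/exit points. Iron-sulfur clusters expose all Fe and S atoms; FMN
# couples through its isoalloxazine ring.
COFACTOR_RES_NAMES = frozenset({"SF4", "FES", "F3S", "FMN"})
FMN_RING_ATOMS = frozenset({"N5", "N10", "C4A", "C10"})


def covalent_radius(element: str) -> float:
    """Covalent radius for an element symbol (case-insensitive)."""
    return COVALENT_RADII.get(element.upper(), DEFAULT_RADIUS)
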