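"""Macromolecular structure model: parsing, bond inference, cofactor lookup.

Structures are read with :mod:`gemmi` (PDB or mmCIF) into a flat,
immutable-by-convention container of residues and atoms using author
numbering. Covalent bonds are inferred from covalent radii, hydrogen
bonds from a heavy-atom distance window, and iron-sulfur / flavin
cofactors are located from a user-supplied label map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from . import chem


class StructureError(ValueError):
    """Raised for unreadable, empty, or inconsistent structures."""


@dataclass(frozen=True)
class Atom3D:
    """One atom after altloc resolution.

    ``serial`` is the file serial number (unique within a structure),
    ``coords`` are Cartesian coordinates in Angstrom.
    """

    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0

    def distance(self, other: "Atom3D") -> float:
        dx = self.coords[0] - other.coords[0]
        dy = self.coords[1] - other.coords[1]
        dz = self.coords[2] - other.coords[2]
        return math.sqrt(dx * dx + dy * dy + dz * dz)


@dataclass(frozen=True)
class ResidueRec:
    chain: str
    seq_id: int
    insertion_code: str
    res_name: str
    atoms: tuple[Atom3D, ...]

    @property
    def site(self) -> tuple[str, int]:
        return (self.chain, self.seq_id)

    def atom(self, name: str) -> Atom3D:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not found in {self.res_name} {self.site}")


@dataclass(frozen=True)
class MolecularStructure:
    id: str
    residues: tuple[ResidueRec, ...]
    source_format: str = "pdb"

    def atoms(self):
        for res in self.residues:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def get_residue(self, chain: str, seq_id: int, insertion_code: str = "") -> ResidueRec:
        for res in self.residues:
            if (
                res.chain == chain
                and res.seq_id == seq_id
                and res.insertion_code == insertion_code
            ):
                return res
        raise StructureError(f"residue {chain}:{seq_id}{insertion_code} not found")

    def residue_of(self, serial: int) -> ResidueRec:
        for res in self.residues:
            for a in res.atoms:
                if a.serial == serial:
                    return res
        raise StructureError(f"no atom with serial {serial}")


@dataclass
class BondSet:
    """Covalent and hydrogen bonds as symmetric serial-pair maps to distance."""

    covalent: dict[frozenset[int], float] = field(default_factory=dict)
    hydrogen: dict[frozenset[int], float] = field(default_factory=dict)


@dataclass(frozen=True)
class RedoxCofactor:
    """An electron donor/acceptor site (Fe-S cluster or FMN)."""

    label: str
    res_name: str
    site: tuple[str, int]
    terminal_atoms: tuple[Atom3D, ...]


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by file order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ + 1e-9:
            best[atom.name] = atom
    # preserve file order of the winners
    order = {id(a): i for i, a in enumerate(res)}
    return sorted(best.values(), key=lambda a: order[id(a)])


def read_structure(
    path: str,
    format: str | None = None,
    include_waters: bool = False,
) -> MolecularStructure:
    """Read a PDB or mmCIF file into a :class:`MolecularStructure`.

    Model 1 is used for multi-model files; altloc duplicates keep the
    highest-occupancy copy; HETATM records are retained (cofactors live
    there); waters are dropped unless ``include_waters`` is set.
    """
    try:
        if format is None:
            st = gemmi.read_structure(str(path))
        elif format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot parse structure file {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureError(f"structure {path} contains no models")
    model = st[0]

    residues: list[ResidueRec] = []
    for ch in model:
        for res in ch:
            if not include_waters and res.name in chem.WATER_NAMES:
                continue
            atoms = tuple(
                Atom3D(
                    serial=a.serial,
                    name=a.name,
                    element=a.element.name.upper(),
                    coords=(a.pos.x, a.pos.y, a.pos.z),
                    altloc="" if a.altloc in ("\0", " ", "") else a.altloc,
                    occupancy=round(float(a.occ), 4),
                )
                for a in _resolve_altlocs(res)
            )
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                ResidueRec(
                    chain=ch.name,
                    seq_id=res.seqid.num,
                    insertion_code=icode,
                    res_name=res.name,
                    atoms=atoms,
                )
            )

    if not residues:
        raise StructureError(f"structure {path} contains no atoms")

    fmt = format or ("mmcif" if str(path).endswith((".cif", ".cif.gz", ".mmcif")) else "pdb")
    return MolecularStructure(id=st.name or str(path), residues=tuple(residues), source_format=fmt)


def write_pdb(s: MolecularStructure, path: str) -> None:
    """Write the structure as a standard PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in s.residues:
        ch = chains.get(res.chain)
        if ch is None:
            ch = gemmi.Chain(res.chain)
            chains[res.chain] = ch
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
        gres.het_flag = "H" if res.res_name in chem.COFACTOR_RES_NAMES or res.res_name in chem.WATER_NAMES else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element.capitalize())
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = a.occupancy
            ga.serial = a.serial
            if a.altloc:
                ga.altloc = a.altloc
            gres.add_atom(ga)
        ch.add_residue(gres)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def infer_covalent_bonds(
    s: MolecularStructure, tol: float = chem.COVALENT_TOLERANCE
) -> dict[frozenset[int], float]:
    """All-pairs covalent bond inference.

    Pair (i, j) is bonded iff ``dist <= r_i + r_j + tol`` and
    ``dist > CLASH_FLOOR``; symmetric by construction.
    """
    atoms = list(s.atoms())
    coords = np.array([a.coords for a in atoms])
    radii = np.array([chem.covalent_radius(a.element) for a in atoms])
    bonds: dict[frozenset[int], float] = {}
    if len(atoms) < 2:
        return bonds
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    cutoff = radii[:, None] + radii[None, :] + tol
    ii, jj = np.nonzero((dist <= cutoff) & (dist > chem.CLASH_FLOOR))
    for i, j in zip(ii, jj):
        if i < j:
            bonds[frozenset((atoms[i].serial, atoms[j].serial))] = float(dist[i, j])
    return bonds


def detect_hbonds(
    s: MolecularStructure,
    covalent: dict[frozenset[int], float],
    dmin: float = 2.4,
    dmax: float = 3.5,
) -> dict[frozenset[int], float]:
    """Heavy-atom hydrogen bond detection.

    Pair (i, j) is an H-bond iff both elements are N/O/S, the distance is
    within ``[dmin, dmax]``, the pair is not covalently bonded, and the
    atoms belong to different residues. No angle criterion is applied
    because the structures handled here generally lack hydrogens.
    """
    candidates = [
        (res, a)
        for res in s.residues
        for a in res.atoms
        if a.element in chem.HBOND_ELEMENTS
    ]
    hbonds: dict[frozenset[int], float] = {}
    for k, (res_i, ai) in enumerate(candidates):
        for res_j, aj in candidates[k + 1 :]:
            if res_i is res_j:
                continue
            pair = frozenset((ai.serial, aj.serial))
            if pair in covalent:
                continue
            d = ai.distance(aj)
            if dmin <= d <= dmax:
                hbonds[pair] = d
    return hbonds


def make_bonds(
    s: MolecularStructure,
    tol: float = chem.COVALENT_TOLERANCE,
    hbond_dmin: float = 2.4,
    hbond_dmax: float = 3.5,
) -> BondSet:
    """Convenience wrapper: covalent then hydrogen bond inference."""
    cov = infer_covalent_bonds(s, tol=tol)
    hb = detect_hbonds(s, cov, dmin=hbond_dmin, dmax=hbond_dmax)
    return BondSet(covalent=cov, hydrogen=hb)


def find_redox_cofactors(
    s: MolecularStructure, label_map: dict[str, tuple[str, int] | str]
) -> list[RedoxCofactor]:
    """Locate redox cofactors named in ``label_map``.

    Map values are ``(chain, seq_id)`` tuples or ``"chain:seq"`` strings.
    For Fe-S clusters (SF4/FES/F3S) the terminal atoms are all Fe and S
    atoms of the residue; for FMN the isoalloxazine ring atoms.
    """
    out: list[RedoxCofactor] = []
    for label, site in label_map.items():
        if isinstance(site, str):
            chain, _, seq = site.partition(":")
            site = (chain, int(seq))
        chain, seq_id = site
        res = s.get_residue(chain, int(seq_id))
        if res.res_name not in chem.COFACTOR_RES_NAMES:
            raise StructureError(
                f"cofactor label {label!r} points at {res.res_name} {res.site}, "
                f"which is not one of {sorted(chem.COFACTOR_RES_NAMES)}"
            )
        if res.res_name == "FMN":
            terminal = tuple(a for a in res.atoms if a.name in chem.FMN_RING_ATOMS)
        else:
            terminal = tuple(a for a in res.atoms if a.element in ("FE", "S"))
        if not terminal:
            raise StructureError(f"cofactor {label!r} at {res.site} has no terminal atoms")
        out.append(
            RedoxCofactor(
                label=label, res_name=res.res_name, site=res.site, terminal_atoms=terminal
            )
        )
    return out


def remove_atoms(s: MolecularStructure, serials: set[int]) -> MolecularStructure:
    """Return a copy of the structure without the listed atom serials."""
    residues = []
    for res in s.residues:
        kept = tuple(a for a in res.atoms if a.serial not in serials)
        if kept:
            residues.append(replace(res, atoms=kept))
    return replace(s, residues=tuple(residues))
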