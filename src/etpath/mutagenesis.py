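"""In-silico point mutagenesis by side-chain truncation.

A substitution to a smaller residue (Val->Ala, Val->Gly, Asp->Gly, ...)
is modeled by renaming the residue and deleting the atoms that are not
part of the target residue's canonical heavy-atom set. No rotamer
rebuilding or minimization is performed, so shared atoms keep their
wild-type coordinates exactly. Substitutions whose target is not an
atom subset of the source (e.g. Phe->Leu) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import chem
from .structure import MolecularStructure


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class MutationSpec:
    """A truncation mutation at one residue site.

    ``site`` uses author numbering, e.g. ``("A", 205)``.
    """

    site: tuple[str, int]
    from_res: str
    to_res: str

    def __post_init__(self):
        for name in (self.from_res, self.to_res):
            if name not in chem.CANONICAL_ATOMS:
                raise MutationError(f"unknown residue type {name!r}")

    @property
    def removed_atoms(self) -> frozenset[str]:
        return chem.CANONICAL_ATOMS[self.from_res] - chem.CANONICAL_ATOMS[self.to_res]

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse ``CHAIN:SEQ:FROM>TO`` (e.g. ``A:205:VAL>ALA``)."""
        try:
            chain, seq, sub = text.split(":")
            from_res, to_res = sub.split(">")
        except ValueError as exc:
            raise MutationError(f"cannot parse mutation spec {text!r}") from exc
        return cls(site=(chain, int(seq)), from_res=from_res.upper(), to_res=to_res.upper())

    def __str__(self) -> str:
        return f"{self.site[0]}:{self.site[1]}:{self.from_res}>{self.to_res}"


def truncate_residue(s: MolecularStructure, m: MutationSpec) -> MolecularStructure:
    """Apply a truncation mutation, returning a new structure.

    The addressed residue is renamed to ``m.to_res`` and atoms outside the
    target's canonical set are removed; backbone atoms are always kept.
    The input structure is left untouched.
    """
    target = chem.CANONICAL_ATOMS[m.to_res]
    source = chem.CANONICAL_ATOMS[m.from_res]
    if not target <= source:
        raise MutationError(
            f"unsupported non-truncation mutation {m.from_res}->{m.to_res}: "
            f"target atoms {sorted(target - source)} are not present in the source residue"
        )
    ring_from = chem.RING_ATOMS.get(m.from_res, frozenset())
    ring_to = chem.RING_ATOMS.get(m.to_res, frozenset())
    mismatched = {a for a in target if (a in ring_from) != (a in ring_to)}
    if mismatched:
        raise MutationError(
            f"unsupported non-truncation mutation {m.from_res}->{m.to_res}: "
            f"atoms {sorted(mismatched)} change ring membership (e.g. aromatic "
            f"to aliphatic), which truncation cannot model"
        )
    chain, seq_id = m.site
    res = s.get_residue(chain, seq_id)
    if res.res_name != m.from_res:
        raise MutationError(
            f"residue at {chain}:{seq_id} is {res.res_name}, expected {m.from_res}"
        )
    backbone = {"N", "CA", "C", "O", "OXT"}
    kept = tuple(a for a in res.atoms if a.name in target or a.name in backbone)
    new_res = replace(res, res_name=m.to_res, atoms=kept)
    residues = tuple(new_res if r is res else r for r in s.residues)
    return replace(s, residues=residues, id=f"{s.id}_{m.from_res}{seq_id}{m.to_res}")
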