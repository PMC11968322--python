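"""Read protein complexes and select the two interacting partners.

Structures are parsed with :mod:`gemmi` from PDB, CIF, or mmCIF files.  Only
protein heavy atoms of the first model are kept: hydrogens, waters and
non-polymer heteroatoms are dropped, and alternate locations are resolved to
the highest-occupancy conformer.  Atomic van der Waals radii are assigned
from a published table (Bondi 1964, with the common protein extensions) so
that the solvent-accessible surface can be built downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np

from .errors import EmptyStructureError, SelectionError, StructureParseError

logger = logging.getLogger(__name__)

#: Van der Waals radii in Angstrom (Bondi 1964; P from Mantina 2009).
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

#: Radius used for elements absent from the table.
DEFAULT_FALLBACK_RADIUS: float = 1.80


@dataclass(frozen=True)
class Atom:
    """One heavy atom of the complex.

    ``residue_id`` is the triple (chain id, residue number, insertion code)
    that uniquely names the owning residue within the structure.
    """

    serial: int
    name: str
    element: str
    chain_id: str
    res_num: int
    icode: str
    res_name: str
    coord: np.ndarray  # shape (3,), Angstrom
    radius: float | None = None

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_num, self.icode)


@dataclass
class Structure:
    """An ordered collection of heavy atoms from one coordinate file."""

    atoms: list[Atom]
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of atomic coordinates in Angstrom."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        """(N,) array of radii; raises if any atom lacks one."""
        vals = [a.radius for a in self.atoms]
        if any(v is None for v in vals):
            raise ValueError("atomic radii not assigned; call assign_radii first")
        return np.array(vals, dtype=float)

    def residue_ids(self) -> list[tuple[str, int, str]]:
        return [a.residue_id for a in self.atoms]


@dataclass(frozen=True)
class PartnerSelection:
    """The two disjoint chain groups forming the complex partners."""

    template_chains: frozenset[str]
    target_chains: frozenset[str]

    def __post_init__(self) -> None:
        if not self.template_chains or not self.target_chains:
            raise SelectionError("both partner selections must be non-empty")
        overlap = self.template_chains & self.target_chains
        if overlap:
            raise SelectionError(
                f"partner selections overlap on chains {sorted(overlap)}"
            )

    @classmethod
    def from_strings(cls, template: str, target: str) -> "PartnerSelection":
        """Build from comma-separated chain-id lists, e.g. ``"A,B"`` / ``"C"``."""
        return cls(
            frozenset(c.strip() for c in template.split(",") if c.strip()),
            frozenset(c.strip() for c in target.split(",") if c.strip()),
        )

    def validate(self, structure: Structure) -> None:
        available = structure.chain_ids
        missing = (self.template_chains | self.target_chains) - available
        if missing:
            raise SelectionError(
                f"chains {sorted(missing)} not present; available: {sorted(available)}"
            )


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "cif": gemmi.CoorFormat.Mmcif,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def parse_structure(
    path: str | Path,
    fmt: str = "auto",
    include_het: Iterable[str] = (),
) -> Structure:
    """Parse a complex file into a :class:`Structure` of protein heavy atoms.

    Parameters
    ----------
    path:
        PDB / CIF / mmCIF file.
    fmt:
        One of ``pdb``, ``cif``, ``mmcif``, ``auto`` (infer from extension
        and content).
    include_het:
        Residue names of heteroatom groups to retain in addition to
        polymer (ATOM-record) residues; waters are never kept.

    Only the first model is used.  Alternate locations are reduced to the
    highest-occupancy conformer (ties: first encountered).
    """
    path = Path(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {sorted(_FORMATS)}")
    if not path.exists():
        raise StructureParseError(f"file not found: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[fmt])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path} contains no models")

    keep_het = {name.upper() for name in include_het}
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            if res.het_flag == "H" and res.name.upper() not in keep_het:
                continue
            for at in _resolve_altloc(res):
                if at.element.is_hydrogen:
                    continue
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name.upper(),
                        chain_id=chain.name,
                        res_num=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        res_name=res.name,
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"no protein heavy atoms in {path}")
    return Structure(atoms=atoms, source_path=str(path))


def _resolve_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties first."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for at in res:
        prev = best.get(at.name)
        if prev is None:
            best[at.name] = at
            order.append(at.name)
        elif at.occ > prev.occ:
            best[at.name] = at
    return [best[name] for name in order]


def assign_radii(
    structure: Structure,
    radii_table: Mapping[str, float] | None = None,
    fallback: float = DEFAULT_FALLBACK_RADIUS,
) -> Structure:
    """Return a copy of ``structure`` with van der Waals radii assigned.

    Elements missing from the table receive ``fallback`` and are logged.
    """
    table = {k.upper(): v for k, v in (radii_table or BONDI_RADII).items()}
    unknown: set[str] = set()
    new_atoms = []
    for a in structure.atoms:
        r = table.get(a.element)
        if r is None:
            r = fallback
            unknown.add(a.element)
        new_atoms.append(replace(a, radius=r))
    if unknown:
        logger.warning(
            "elements %s not in radii table; using fallback %.2f A",
            sorted(unknown),
            fallback,
        )
    return Structure(atoms=new_atoms, source_path=structure.source_path)


def split_partners(
    structure: Structure, selection: PartnerSelection
) -> tuple[Structure, Structure]:
    """Split the complex into (template, target) substructures by chain id.

    Atom order is preserved within each partner.
    """
    selection.validate(structure)
    template = [a for a in structure.atoms if a.chain_id in selection.template_chains]
    target = [a for a in structure.atoms if a.chain_id in selection.target_chains]
    return (
        Structure(atoms=template, source_path=structure.source_path),
        Structure(atoms=target, source_path=structure.source_path),
    )
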