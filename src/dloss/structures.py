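"""Coordinate models, atom taxonomy and unit-cell geometry.

A :class:`Structure` is a flat, ordered collection of :class:`Atom` records in
a triclinic :class:`UnitCell` — the minimal model needed to place atoms on a
density grid and to group them into atom types such as (TYR, OH).  PDB I/O is
delegated to gemmi; this module only adds the bookkeeping the damage analysis
needs (electron counts, altloc policy, atom-type selection).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "Atom",
    "Structure",
    "AtomTypeKey",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "ELECTRON_COUNTS",
]

# Neutral-atom electron counts for the elements that occur in protein models.
# Ions are deliberately not modelled (no metal-centre analysis in scope).
ELECTRON_COUNTS: dict[str, int] = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "ZN": 30,
    "SE": 34, "BR": 35, "I": 53,
}


def electron_count(element: str) -> int:
    """Neutral-atom electron number for an element symbol."""
    try:
        return ELECTRON_COUNTS[element.strip().upper()]
    except KeyError:
        raise ValueError(f"no electron count tabulated for element {element!r}") from None


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell with orthogonalization/fractionalization transforms.

    Edge lengths ``a, b, c`` are in Å, angles ``alpha, beta, gamma`` in degrees.
    The orthogonalization matrix follows the standard PDB convention (``a``
    along x, ``b`` in the xy plane).
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit-cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("unit-cell angles must lie in (0, 180) degrees")

    @property
    def _gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return self._gemmi.volume

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix mapping fractional to orthogonal (Å) coordinates."""
        return np.array(self._gemmi.orth.mat.tolist(), dtype=float)

    @property
    def frac_matrix(self) -> np.ndarray:
        """3x3 matrix mapping orthogonal (Å) to fractional coordinates."""
        return np.array(self._gemmi.frac.mat.tolist(), dtype=float)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orth_matrix.T

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.frac_matrix.T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d(h, k, l) in Å for an (N, 3) array of Miller indices."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        # reciprocal metric: |h·F|, rows of frac_matrix are reciprocal axes
        s_vec = hkl @ self.frac_matrix
        s = np.linalg.norm(s_vec, axis=1)
        with np.errstate(divide="ignore"):
            return np.where(s > 0, 1.0 / s, np.inf)


@dataclass(frozen=True)
class AtomTypeKey:
    """An atom species such as (TYR, OH) — all atoms of one name in one residue type."""

    residue_name: str
    atom_name: str

    def __post_init__(self) -> None:
        if not self.residue_name or not self.atom_name:
            raise ValueError("AtomTypeKey fields must be non-empty")

    def __str__(self) -> str:  # used in table indices and logs
        return f"{self.residue_name}-{self.atom_name}"


@dataclass
class Atom:
    serial: int
    name: str
    altloc: str
    residue_name: str
    chain_id: str
    residue_number: int
    element: str
    position: np.ndarray  # orthogonal Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise ValueError("b_factor must be non-negative")

    @property
    def n_electrons(self) -> int:
        return electron_count(self.element)

    @property
    def key(self) -> AtomTypeKey:
        return AtomTypeKey(self.residue_name, self.name)

    @property
    def atom_id(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.name, self.altloc)


@dataclass
class Structure:
    """Ordered atom collection in a unit cell."""

    atoms: list[Atom]
    cell: UnitCell
    identifier: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Structure must contain at least one atom")

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        return np.array([a.position for a in atoms], dtype=float)

    def heavy_atoms(self, include_alt: bool = False, include_hetatm: bool = True) -> list[Atom]:
        """Non-hydrogen atoms, by default restricted to altloc '' or 'A'.

        Atoms with a secondary altloc would double-count a site in per-atom
        statistics, so they are excluded unless ``include_alt`` is set.
        """
        out = []
        for a in self.atoms:
            if a.element.upper() == "H":
                continue
            if not include_alt and a.altloc not in ("", "A"):
                continue
            if not include_hetatm and a.is_hetatm:
                continue
            out.append(a)
        return out

    def copy(self) -> "Structure":
        return Structure(
            [dataclasses.replace(a, position=a.position.copy()) for a in self.atoms],
            self.cell,
            self.identifier,
        )


def select_atoms(structure: Structure, key: AtomTypeKey,
                 atoms: Iterable[Atom] | None = None) -> list[Atom]:
    """All atoms matching (residue_name, atom_name) exactly; empty if absent."""
    pool = structure.atoms if atoms is None else atoms
    return [a for a in pool
            if a.residue_name == key.residue_name and a.name == key.atom_name]


def read_pdb(path: str | Path) -> Structure:
    """Read ATOM/HETATM records and the CRYST1 cell from a PDB file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unparseable PDB file {path}: {exc}") from exc
    if not st.cell.is_crystal():
        raise ValueError(f"{path}: missing or degenerate CRYST1 record")
    cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                    st.cell.alpha, st.cell.beta, st.cell.gamma)
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                het = res.het_flag == "H"
                for at in res:
                    elem = at.element.name if at.element.name != "X" else ""
                    if not elem:
                        elem = "".join(ch for ch in at.name if ch.isalpha())[:1]
                    atoms.append(Atom(
                        serial=at.serial,
                        name=at.name,
                        altloc=("" if at.altloc == "\x00" else at.altloc),
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        element=elem.upper(),
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        b_factor=at.b_iso,
                        is_hetatm=het,
                    ))
        break  # first model only
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms, cell, identifier=path.stem)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a fixed-column PDB file (coordinates to 3 d.p., occ/B to 2 d.p.)."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(structure.cell.a, structure.cell.b, structure.cell.c,
                             structure.cell.alpha, structure.cell.beta,
                             structure.cell.gamma)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int, str], gemmi.Residue] = {}
    for a in structure.atoms:
        ch = chains.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = ch
        rkey = (a.chain_id, a.residue_number, a.residue_name)
        res = residues.get(rkey)
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "H" if a.is_hetatm else "A"
            ch.add_residue(res)
            res = ch[-1]
            residues[rkey] = res
        at = gemmi.Atom()
        at.name = a.name
        at.altloc = a.altloc if a.altloc else "\x00"
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        at.b_iso = a.b_factor
        at.serial = a.serial
        res.add_atom(at)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.write_pdb(str(path))
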