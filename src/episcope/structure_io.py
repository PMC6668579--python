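"""Macromolecular coordinate I/O and atom selection.

A deliberately small hierarchical model (Structure -> ResidueRecord ->
AtomRecord) backed by gemmi for parsing PDB and mmCIF.  Only the first model
of a multi-model file is kept, and alternate locations are resolved to the
highest-occupancy conformer (ties broken by altloc letter), which matches the
single-conformer crystal structures this pipeline targets.  Waters are
retained but flagged so geometry operations can skip them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import gemmi
import numpy as np

from episcope.errors import (
    AmbiguityError,
    FormatError,
    NotFoundError,
    ParseError,
    SelectionError,
)

#: standard amino acids, 3-letter -> 1-letter
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class AtomRecord:
    """One heavy (or hydrogen) atom.

    coords are in Angstrom; occupancy in [0, 1]; bfactor in A^2; altloc is a
    single character or empty after conformer resolution.
    """

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class ResidueRecord:
    """A residue (or het group) with its atoms, in author numbering."""

    name: str
    seq_number: int
    icode: str
    chain_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    is_het: bool = False
    is_water: bool = False

    def atom(self, name: str) -> AtomRecord:
        """Return the uniquely named atom, or raise NotFoundError."""
        for a in self.atoms:
            if a.name == name:
                return a
        raise NotFoundError(
            f"atom {name!r} not found in {self.name} {self.chain_id}{self.seq_number}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.seq_number}{self.icode}"


@dataclass
class Structure:
    """First-model coordinates of one entry: ordered chains of residues."""

    id: str
    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def ligands(self) -> list[ResidueRecord]:
        """Het residues that are not water, across all chains."""
        return [r for rs in self.chains.values() for r in rs if r.is_het and not r.is_water]

    def residues(self, chain_id: str | None = None, het: bool | None = None,
                 waters: bool = True) -> Iterator[ResidueRecord]:
        for cid, rs in self.chains.items():
            if chain_id is not None and cid != chain_id:
                continue
            for r in rs:
                if het is not None and r.is_het != het:
                    continue
                if not waters and r.is_water:
                    continue
                yield r

    def chain_residue(self, chain_id: str, seq_number: int) -> ResidueRecord:
        for r in self.chains.get(chain_id, []):
            if r.seq_number == seq_number:
                return r
        raise NotFoundError(f"residue {seq_number} not found in chain {chain_id}")

    def atom_count(self) -> int:
        return sum(len(r.atoms) for rs in self.chains.values() for r in rs)


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc letter."""
    by_name: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = a
            order.append(a.name)
        else:
            b = by_name[a.name]
            if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
                by_name[a.name] = a
    return [by_name[n] for n in order]


def _altloc_rank(altloc: str) -> int:
    # earlier letters win ties, so rank them higher
    return -ord(altloc) if altloc else 0


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a Structure (first model only).

    Altlocs are resolved to the highest-occupancy conformer; waters are kept
    but flagged ``is_water``.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise FormatError(f"unknown format {format!r}; expected pdb, mmcif, or auto")
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    st.setup_entities()

    info = dict(st.info) if st.info else {}
    out = Structure(id=st.name or path.stem, metadata={
        "title": info.get("_struct.title", ""),
        "spacegroup": st.spacegroup_hm or "",
    })
    model = st[0]
    for chain in model:
        residues: list[ResidueRecord] = []
        for res in chain:
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    bfactor=a.b_iso,
                    altloc=a.altloc if a.altloc != "\x00" else "",
                )
                for a in res
            ]
            atoms = _resolve_altlocs(atoms)
            is_water = res.is_water() or res.name in WATER_NAMES
            is_het = res.het_flag == "H" or is_water
            residues.append(ResidueRecord(
                name=res.name,
                seq_number=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                chain_id=chain.name,
                atoms=atoms,
                is_het=is_het,
                is_water=is_water,
            ))
        if residues:
            if chain.name in out.chains:
                out.chains[chain.name].extend(residues)
            else:
                out.chains[chain.name] = residues
    return out


Selector = Callable[[ResidueRecord, AtomRecord], bool]


def make_selector(chain: str | None = None, resnum: int | None = None,
                  resname: str | None = None, atom: str | None = None,
                  het: bool | None = None) -> Selector:
    """Build a predicate over (residue, atom) from simple field filters."""

    def pred(r: ResidueRecord, a: AtomRecord) -> bool:
        if chain is not None and r.chain_id != chain:
            return False
        if resnum is not None and r.seq_number != resnum:
            return False
        if resname is not None and r.name != resname:
            return False
        if het is not None and r.is_het != het:
            return False
        if atom is not None and a.name != atom:
            return False
        return True

    return pred


def select_atoms(s: Structure, selector: Selector) -> list[AtomRecord]:
    """Atoms matching a predicate, in file order; empty list when nothing matches."""
    if not callable(selector):
        raise SelectionError(f"selector must be callable, got {type(selector).__name__}")
    out = []
    for rs in s.chains.values():
        for r in rs:
            for a in r.atoms:
                try:
                    keep = selector(r, a)
                except Exception as exc:  # predicate blew up -> malformed selector
                    raise SelectionError(f"selector raised {exc!r}") from exc
                if keep:
                    out.append(a)
    return out


def extract_ligand(s: Structure, het_code: str, instance: int | None = None) -> ResidueRecord:
    """The het residue with the given 3-letter code.

    When several copies exist an ``instance`` index (0-based, file order) must
    be supplied.
    """
    matches = [r for r in s.ligands if r.name == het_code]
    if not matches:
        raise NotFoundError(f"ligand {het_code!r} not present in structure {s.id}")
    if len(matches) > 1 and instance is None:
        raise AmbiguityError(
            f"ligand {het_code!r} present {len(matches)} times; pass instance index"
        )
    return matches[instance or 0]


def chain_one_letter(s: Structure, chain_id: str) -> tuple[str, list[int]]:
    """One-letter sequence of a chain's polymer residues plus their author numbers.

    Unknown residue types become 'X'.  Het groups and waters are skipped.
    """
    seq, nums = [], []
    for r in s.residues(chain_id=chain_id, waters=False):
        if r.is_het and r.name not in THREE_TO_ONE:
            continue
        seq.append(THREE_TO_ONE.get(r.name, "X"))
        nums.append(r.seq_number)
    return "".join(seq), nums


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write fixed-column PDB.  Coordinates carry 3 decimals, so a re-read
    structure equals the original to 1e-3 A."""
    if format != "pdb":
        raise FormatError(f"only pdb output supported, got {format!r}")
    lines = []
    serial = 1
    for cid, rs in s.chains.items():
        last = None
        for r in rs:
            rec = "HETATM" if r.is_het else "ATOM  "
            for a in r.atoms:
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"{rec}{serial:5d} {name:<4.4s}{'':1s}{r.name:>3.3s} {cid[:1]}"
                    f"{r.seq_number:4d}{r.icode[:1] or ' ':1s}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.bfactor:6.2f}{'':10s}{a.element:>2.2s}"
                )
                serial += 1
            last = r
        if last is not None and not last.is_het:
            lines.append(f"TER   {serial:5d}      {last.name:>3.3s} {cid[:1]}{last.seq_number:4d}")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
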