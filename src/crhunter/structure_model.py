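"""Protein structure and catalytic-annotation model.

Structures are parsed from single-chain PDB files into a flat, 0-based
residue list of heavy atoms.  Only the 20 standard amino acids are kept
(MSE/SEC are mapped to Met/Cys); residues without an alpha carbon are
dropped, since every geometric descriptor downstream represents a residue
by its CA.  Catalytic annotations are simple per-structure index sets read
from a two-column TSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.PDB import PDBParser

from ._aa import THREE_TO_ONE

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "CatalyticAnnotation",
    "StructureError",
    "UnknownChainError",
    "AnnotationParseError",
    "read_structure",
    "read_annotations",
    "write_annotations",
]


class StructureError(ValueError):
    """Raised when a structure file cannot be turned into a usable chain."""


class UnknownChainError(StructureError):
    """Raised when the requested chain is absent from the file."""


class AnnotationParseError(ValueError):
    """Raised on a malformed annotation line; carries the line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class Atom:
    """A heavy atom: label, element symbol and Cartesian coordinate (Å)."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        object.__setattr__(self, "coord", coord)


@dataclass
class Residue:
    """One standard residue with its heavy atoms.

    ``index`` is the 0-based contiguous position in the parsed chain;
    ``seq_id`` keeps the author residue number for reporting only.
    """

    index: int
    seq_id: int
    aa: str
    atoms: list[Atom]
    ca_coord: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.ca_coord = np.asarray(self.ca_coord, dtype=float)


@dataclass
class Structure:
    """An ordered single-chain residue list."""

    id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def atom_coords(self) -> np.ndarray:
        """All heavy-atom coordinates, shape (n_atoms, 3)."""
        return np.array([a.coord for r in self.residues for a in r.atoms])

    def atom_residue_index(self) -> np.ndarray:
        """Residue index of each heavy atom, aligned with :meth:`atom_coords`."""
        return np.array([r.index for r in self.residues for _ in r.atoms], dtype=int)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca_coord for r in self.residues])


@dataclass(frozen=True)
class CatalyticAnnotation:
    """Set of catalytic residue indices (0-based) for one structure."""

    structure_id: str
    catalytic_indices: frozenset[int]

    def labels(self, n_residues: int) -> np.ndarray:
        """0/1 label vector of length ``n_residues``."""
        bad = [i for i in self.catalytic_indices if i >= n_residues or i < 0]
        if bad:
            raise ValueError(
                f"{self.structure_id}: catalytic indices {sorted(bad)} outside "
                f"0..{n_residues - 1}"
            )
        y = np.zeros(n_residues, dtype=int)
        y[sorted(self.catalytic_indices)] = 1
        return y


def _select_altloc(bio_atoms) -> list:
    """Resolve altlocs: keep one atom per name, highest occupancy, tie -> label order."""
    by_name: dict[str, list] = {}
    for a in bio_atoms:
        by_name.setdefault(a.get_name(), []).append(a)
    kept = []
    for name in by_name:
        variants = by_name[name]
        occ = lambda a: a.get_occupancy() if a.get_occupancy() is not None else 0.0
        variants.sort(key=lambda a: (-occ(a), a.get_altloc()))
        kept.append(variants[0])
    return kept


def read_structure(path: str | Path, chain: str = "A", structure_id: str | None = None) -> Structure:
    """Parse one chain of a PDB file into a :class:`Structure`.

    Hydrogens are discarded, altlocs resolved to the highest-occupancy
    variant (ties broken by altloc label), MSE/SEC mapped to M/C, all other
    non-standard residues dropped with a warning, and residues lacking a CA
    excluded (their author seq ids are logged).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    UnknownChainError
        If ``chain`` is not present in the first model.
    StructureError
        If no standard residue with a CA survives parsing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure(path.stem, str(path)).get_models())
    if chain not in [c.id for c in model]:
        raise UnknownChainError(
            f"{path}: chain {chain!r} not found (have {[c.id for c in model]})"
        )

    residues: list[Residue] = []
    dropped_nonstandard: list[str] = []
    dropped_no_ca: list[int] = []
    for res in model[chain]:
        resname = res.get_resname().strip()
        if resname == "HOH":
            continue
        aa = THREE_TO_ONE.get(resname)
        if aa is None:
            dropped_nonstandard.append(resname)
            continue
        atoms = []
        ca = None
        for bio_atom in _select_altloc(res.get_unpacked_list()):
            element = (bio_atom.element or "").strip().upper()
            if element in ("H", "D"):
                continue
            atom = Atom(bio_atom.get_name(), element, np.asarray(bio_atom.get_coord(), dtype=float))
            atoms.append(atom)
            if atom.name == "CA":
                ca = atom.coord
        if ca is None:
            dropped_no_ca.append(res.get_id()[1])
            continue
        residues.append(
            Residue(index=len(residues), seq_id=res.get_id()[1], aa=aa, atoms=atoms, ca_coord=ca)
        )

    if dropped_nonstandard:
        warnings.warn(
            f"{path} chain {chain}: dropped non-standard residues "
            f"{sorted(set(dropped_nonstandard))}",
            stacklevel=2,
        )
    if dropped_no_ca:
        logger.info("%s chain %s: excluded residues without CA (seq ids %s)", path, chain, dropped_no_ca)
    if not residues:
        raise StructureError(f"{path} chain {chain}: no standard residues with CA")
    return Structure(id=structure_id or f"{path.stem}_{chain}", residues=residues)


def read_annotations(path: str | Path) -> list[CatalyticAnnotation]:
    """Read a TSV of ``structure_id<TAB>i1,i2,...`` catalytic index records.

    Duplicate indices are deduplicated; a line with an empty index field
    yields an empty annotation.  Malformed lines raise
    :class:`AnnotationParseError` naming the 1-based line number.
    """
    annotations = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AnnotationParseError(
                    f"expected 'structure_id<TAB>indices', got {line!r}", lineno
                )
            sid, idx_field = parts
            indices: set[int] = set()
            if idx_field.strip():
                for token in idx_field.split(","):
                    token = token.strip()
                    try:
                        value = int(token)
                    except ValueError:
                        raise AnnotationParseError(
                            f"non-integer residue index {token!r}", lineno
                        ) from None
                    if value < 0:
                        raise AnnotationParseError(f"negative residue index {value}", lineno)
                    indices.add(value)
            annotations.append(CatalyticAnnotation(sid, frozenset(indices)))
    return annotations


def write_annotations(annotations: Iterable[CatalyticAnnotation], path: str | Path) -> None:
    """Write annotations in the TSV dialect read by :func:`read_annotations`."""
    with open(path, "w") as handle:
        for ann in annotations:
            joined = ",".join(str(i) for i in sorted(ann.catalytic_indices))
            handle.write(f"{ann.structure_id}\t{joined}\n")
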