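"""Delaunay tessellation of heavy atoms and the residue contact graph.

The 3D structure is tetrahedralized with Qhull (scipy.spatial.Delaunay).
Two atoms share a Voronoi facet exactly when they are joined by a Delaunay
edge (the diagrams are geometric duals), so residue contact strength is
measured by counting inter-residue Delaunay edges: ``facet_counts[(i, j)]``
is the number of heavy-atom pairs, one atom from each residue, that share a
Voronoi facet.  A residue's microenvironment keeps only neighbors whose
shared-facet count reaches a cutoff (default 9), which filters weak,
sliver-like contacts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .structure_model import Structure

__all__ = [
    "DEFAULT_FACET_CUTOFF",
    "AtomTessellation",
    "ResidueContactGraph",
    "TessellationError",
    "tessellate",
    "contact_graph",
    "microenvironment",
]

#: Minimum shared Voronoi facets for two residues to count as in contact.
DEFAULT_FACET_CUTOFF = 9


class TessellationError(ValueError):
    """Raised when a point set cannot be tetrahedralized."""


@dataclass
class AtomTessellation:
    """Delaunay tetrahedralization of a structure's heavy atoms."""

    points: np.ndarray
    simplices: np.ndarray
    delaunay_edges: set[tuple[int, int]] = field(repr=False)

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class ResidueContactGraph:
    """Residue-pair shared-Voronoi-facet counts for one structure."""

    n_residues: int
    facet_counts: dict[tuple[int, int], int]

    def count(self, i: int, j: int) -> int:
        if i == j:
            return 0
        return self.facet_counts.get((min(i, j), max(i, j)), 0)

    def edges(self, cutoff: int = DEFAULT_FACET_CUTOFF) -> set[tuple[int, int]]:
        """Residue pairs sharing at least ``cutoff`` facets."""
        return {pair for pair, c in self.facet_counts.items() if c >= cutoff}

    def neighbors(self, residue: int, cutoff: int = DEFAULT_FACET_CUTOFF) -> list[tuple[int, int]]:
        """Qualifying neighbors of ``residue`` as (index, facet count) pairs."""
        return microenvironment(self, residue, cutoff)


def _jitter_seed(structure_id: str) -> int:
    # deterministic per-structure seed for degeneracy joggle
    return zlib.crc32(structure_id.encode()) & 0x7FFFFFFF


def tessellate(structure: Structure, jitter: float = 1e-6) -> AtomTessellation:
    """Delaunay-tetrahedralize all heavy atoms of ``structure``.

    Degenerate inputs (coplanar/cospherical) are retried once with a
    deterministic jitter of ``jitter`` Å seeded from the structure id,
    mirroring Qhull's joggle but reproducibly.

    Raises
    ------
    TessellationError
        For fewer than 5 atoms or irrecoverably degenerate geometry.
    """
    points = structure.atom_coords()
    if len(points) < 5:
        raise TessellationError(
            f"{structure.id}: need at least 5 heavy atoms for a 3D tessellation, "
            f"got {len(points)}"
        )
    try:
        tri = Delaunay(points)
    except QhullError:
        rng = np.random.default_rng(_jitter_seed(structure.id))
        try:
            tri = Delaunay(points + rng.normal(scale=jitter, size=points.shape))
        except QhullError as exc:
            raise TessellationError(f"{structure.id}: degenerate geometry: {exc}") from exc
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a, b in combinations(simplex.tolist(), 2):
            edges.add((min(a, b), max(a, b)))
    return AtomTessellation(points=points, simplices=tri.simplices, delaunay_edges=edges)


def contact_graph(structure: Structure, tess: AtomTessellation) -> ResidueContactGraph:
    """Count shared Voronoi facets per residue pair via the Delaunay dual."""
    res_of = structure.atom_residue_index()
    if tess.n_points != len(res_of):
        raise ValueError(
            f"{structure.id}: tessellation has {tess.n_points} points but the "
            f"structure has {len(res_of)} heavy atoms"
        )
    counts: dict[tuple[int, int], int] = {}
    for a, b in tess.delaunay_edges:
        i, j = int(res_of[a]), int(res_of[b])
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        counts[key] = counts.get(key, 0) + 1
    return ResidueContactGraph(n_residues=len(structure), facet_counts=counts)


def microenvironment(
    graph: ResidueContactGraph, residue: int, cutoff: int = DEFAULT_FACET_CUTOFF
) -> list[tuple[int, int]]:
    """Neighbors of ``residue`` with facet count >= ``cutoff``.

    Sorted by facet count descending, ties broken by residue index
    ascending (the order used to pick structural-window neighbors).
    """
    if not 0 <= residue < graph.n_residues:
        raise IndexError(f"residue index {residue} outside 0..{graph.n_residues - 1}")
    if cutoff < 1:
        raise ValueError("facet cutoff must be >= 1")
    found = []
    for (i, j), c in graph.facet_counts.items():
        if c < cutoff:
            continue
        if i == residue:
            found.append((j, c))
        elif j == residue:
            found.append((i, c))
    found.sort(key=lambda pair: (-pair[1], pair[0]))
    return found


def write_facet_counts(graph: ResidueContactGraph, path: str | Path) -> None:
    """Dump facet counts as a three-column TSV (res_i, res_j, count)."""
    with open(path, "w") as handle:
        handle.write("res_i\tres_j\tcount\n")
        for (i, j) in sorted(graph.facet_counts):
            handle.write(f"{i}\t{j}\t{graph.facet_counts[(i, j)]}\n")
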