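"""Microenvironment score and network topology on the contact graph.

The microenvironment score of a residue is the inner product of its
neighbor-type pair-frequency matrix F (rows: query type, columns: neighbor
type) with a 20x20 pair-weight matrix W averaged over the catalytic
residues of a training set.  For a catalytic residue of type m, the weight
element is

    W(m, n) = N_mn / ((N_m + pc) * (N_n + pc))

where N_mn is the number of type-n neighbors in its microenvironment and
N_m, N_n are the type counts in the neighborhood (the query residue itself
included), with additive pseudocount pc guarding sparse neighborhoods.
The weighting function is injectable so alternative normalizations
(e.g. log-odds propensities) can be swapped in without touching callers.

Network features (degree, closeness, betweenness, clustering) are computed
on the residue interaction network whose edges are residue pairs sharing at
least ``cutoff`` Voronoi facets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._aa import AA20, AA_INDEX
from .structure_model import CatalyticAnnotation, Structure
from .tessellation import DEFAULT_FACET_CUTOFF, ResidueContactGraph, microenvironment

__all__ = [
    "PairWeightMatrix",
    "pair_frequency",
    "train_pair_weights",
    "me_score",
    "network_features",
    "default_pair_weight",
]

#: signature: (pair_count N_mn, type_count N_m, type_count N_n, pseudocount) -> weight
WeightFn = Callable[[float, float, float, float], float]


def default_pair_weight(n_mn: float, n_m: float, n_n: float, pseudocount: float) -> float:
    """Pair count normalized by smoothed marginal type counts."""
    return n_mn / ((n_m + pseudocount) * (n_n + pseudocount))


@dataclass
class PairWeightMatrix:
    """20x20 residue-pair weight matrix (query type x neighbor type)."""

    values: np.ndarray
    n_catalytic: int
    n_skipped: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise ValueError("pair weight matrix must be 20x20")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("pair weights must be finite and non-negative")

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, index=list(AA20), columns=list(AA20))
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, n_catalytic: int = 0) -> "PairWeightMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame = frame.loc[list(AA20), list(AA20)]
        return cls(frame.to_numpy(), n_catalytic=n_catalytic)


def pair_frequency(
    structure: Structure,
    graph: ResidueContactGraph,
    residue: int,
    cutoff: int = DEFAULT_FACET_CUTOFF,
) -> np.ndarray:
    """Neighbor-type frequency matrix F for one residue, shape (20, 20).

    Row m (the query residue's type) holds the count of qualifying
    microenvironment neighbors of each type; all other rows are zero.
    """
    freq = np.zeros((20, 20))
    m = AA_INDEX[structure.residues[residue].aa]
    for j, _count in microenvironment(graph, residue, cutoff):
        freq[m, AA_INDEX[structure.residues[j].aa]] += 1
    return freq


def train_pair_weights(
    training: Iterable[tuple[Structure, ResidueContactGraph, CatalyticAnnotation]],
    cutoff: int = DEFAULT_FACET_CUTOFF,
    pseudocount: float = 0.5,
    weight_fn: WeightFn = default_pair_weight,
    include_query: bool = True,
) -> PairWeightMatrix:
    """Average per-catalytic-residue weight matrices over a training set.

    Catalytic residues with an empty microenvironment carry no pair
    information and are skipped (tallied in ``n_skipped``).  The result is
    invariant to the order of training structures.

    Raises
    ------
    ValueError
        If no catalytic residue has a non-empty microenvironment.
    """
    total = np.zeros((20, 20))
    n_used = 0
    n_skipped = 0
    for structure, graph, annotation in training:
        for residue in sorted(annotation.catalytic_indices):
            neighbors = microenvironment(graph, residue, cutoff)
            if not neighbors:
                n_skipped += 1
                continue
            m = AA_INDEX[structure.residues[residue].aa]
            type_counts = np.zeros(20)
            if include_query:
                type_counts[m] += 1
            pair_counts = np.zeros(20)
            for j, _count in neighbors:
                n = AA_INDEX[structure.residues[j].aa]
                type_counts[n] += 1
                pair_counts[n] += 1
            weights = np.zeros((20, 20))
            for n in range(20):
                if pair_counts[n] == 0:
                    continue
                weights[m, n] = weight_fn(pair_counts[n], type_counts[m], type_counts[n], pseudocount)
            total += weights
            n_used += 1
    if n_used == 0:
        raise ValueError("no catalytic residue with a non-empty microenvironment")
    return PairWeightMatrix(total / n_used, n_catalytic=n_used, n_skipped=n_skipped)


def me_score(freq: np.ndarray, weights: PairWeightMatrix | np.ndarray) -> float:
    """Microenvironment score: elementwise inner product of F with W."""
    w = weights.values if isinstance(weights, PairWeightMatrix) else np.asarray(weights)
    freq = np.asarray(freq, dtype=float)
    if freq.shape != w.shape:
        raise ValueError(f"shape mismatch: F {freq.shape} vs W {w.shape}")
    return float(np.sum(freq * w))


def me_scores(
    structure: Structure,
    graph: ResidueContactGraph,
    weights: PairWeightMatrix,
    cutoff: int = DEFAULT_FACET_CUTOFF,
) -> np.ndarray:
    """Microenvironment score for every residue of a structure."""
    return np.array(
        [me_score(pair_frequency(structure, graph, i, cutoff), weights) for i in range(len(structure))]
    )


def network_features(
    graph: ResidueContactGraph, cutoff: int = DEFAULT_FACET_CUTOFF
) -> pd.DataFrame:
    """Degree, closeness, betweenness and clustering for every residue.

    Computed on the residue interaction network with edges at the facet
    cutoff.  Closeness uses the Wasserman-Faust within-component scaling
    (bounded in [0, 1] on disconnected graphs), betweenness is normalized
    by 2/((n-1)(n-2)), and clustering is the standard triangle density
    2*T/(k(k-1)); isolated nodes score 0 on all measures.
    """
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_residues))
    g.add_edges_from(graph.edges(cutoff))
    closeness = nx.closeness_centrality(g, wf_improved=True)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    clustering = nx.clustering(g)
    return pd.DataFrame(
        {
            "degree": [g.degree[i] for i in range(graph.n_residues)],
            "closeness": [closeness[i] for i in range(graph.n_residues)],
            "betweenness": [betweenness[i] for i in range(graph.n_residues)],
            "clustering": [clustering[i] for i in range(graph.n_residues)],
        },
        index=pd.RangeIndex(graph.n_residues, name="residue"),
    )
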