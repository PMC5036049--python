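import numpy as np
import pytest

from crhunter.fixtures import FixtureSpec, make_benchmark
from crhunter.predictors import FeatureCache
from crhunter.structure_model import Atom, Residue, Structure


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(n_structures=6, length_range=(50, 70), seed=7)


@pytest.fixture(scope="session")
def small_bench(small_spec):
    return make_benchmark(small_spec)


@pytest.fixture(scope="session")
def small_cache(small_bench):
    cache = FeatureCache()
    for record in small_bench.records:
        cache.graph(record)
    return cache


def structure_from_points(points, residue_sizes, structure_id="toy", sequence=None):
    """Build a Structure from raw atom coordinates grouped into residues.

    The first atom of every residue doubles as its CA.
    """
    points = np.asarray(points, dtype=float)
    residues = []
    cursor = 0
    for idx, size in enumerate(residue_sizes):
        group = points[cursor : cursor + size]
        cursor += size
        aa = (sequence or "A" * len(residue_sizes))[idx]
        atoms = [Atom("CA", "C", group[0])] + [
            Atom(f"C{j}", "C", group[j]) for j in range(1, len(group))
        ]
        residues.append(
            Residue(index=idx, seq_id=idx + 1, aa=aa, atoms=atoms, ca_coord=group[0])
        )
    assert cursor == len(points)
    return Structure(id=structure_id, residues=residues)


def random_structure(rng, n_atoms, n_residues, spread=10.0):
    """Random point-cloud structure with atoms split across residues."""
    points = rng.uniform(-spread, spread, size=(n_atoms, 3))
    sizes = np.full(n_residues, n_atoms // n_residues)
    sizes[: n_atoms % n_residues] += 1
    return structure_from_points(points, sizes.tolist(), structure_id=f"rand{rng.integers(1 << 30)}")
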