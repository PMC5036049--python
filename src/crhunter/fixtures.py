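"""Synthetic benchmark generator.

Emulates the statistical signatures the predictor exploits, without any
external data: compact globular pseudo-proteins built as a self-avoiding
spiral walk over a sphere shell with a spherical-cap pocket indentation;
"catalytic" residues planted at the pocket bottom; pocket neighborhoods
enriched in the charged/hydrophilic types over-represented at real active
sites (H, D, R, E, K, C, Y); MSAs with elevated conservation at catalytic
columns and PSSMs derived from them; and template hits that are perturbed
copies of each query with known annotations, mixed with low-similarity
decoys.  Everything is driven by one seed: a fixed seed reproduces the
benchmark byte-for-byte.

These fixtures are synthetic stand-ins for curated catalytic-site data and
alignment-engine outputs; they plant the qualitative signal the method
assumes, not physically realistic protein folds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._aa import AA20, AA_INDEX, BACKGROUND, ONE_TO_THREE, SIDECHAIN_PSEUDOATOMS
from .sequence_features import PSSM, conservation, read_pssm
from .structure_model import (
    Atom,
    CatalyticAnnotation,
    Residue,
    Structure,
    read_annotations,
    read_structure,
    write_annotations,
)
from .predictors import QueryRecord, TemplateHit, read_template_hits, write_template_hits

__all__ = [
    "FixtureSpec",
    "Benchmark",
    "make_structure",
    "make_msa_and_pssm",
    "make_template_hits",
    "make_benchmark",
    "without_templates",
    "write_benchmark",
    "load_benchmark",
    "write_pdb",
]

#: Sampling weights of the catalytic/pocket alphabet relative to background.
DEFAULT_CATALYTIC_BIAS = {
    "H": 8.0, "D": 6.0, "E": 5.0, "K": 3.0, "R": 3.0, "C": 5.0, "Y": 3.0,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of the synthetic benchmark.

    ``pocket_depth`` (Å) controls how far the spherical-cap indentation
    pulls pocket residues toward the centroid; ``catalytic_fraction`` sets
    how many pocket-bottom residues are labelled catalytic;
    ``conservation_boost`` in [0, 1] scales down the per-column mutation
    rate at catalytic columns (1 = absolute conservation); and
    ``template_noise`` (Å) perturbs the homolog-template copies.
    """

    n_structures: int = 40
    length_range: tuple[int, int] = (80, 120)
    pocket_depth: float = 5.0
    catalytic_fraction: float = 0.04
    catalytic_alphabet_bias: dict = field(default_factory=lambda: dict(DEFAULT_CATALYTIC_BIAS))
    conservation_boost: float = 0.85
    template_noise: float = 1.0
    n_msa: int = 50
    mutation_rate: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.catalytic_fraction < 1.0:
            raise ValueError("catalytic_fraction must lie in (0, 1)")
        if not 0.0 <= self.conservation_boost <= 1.0:
            raise ValueError("conservation_boost must lie in [0, 1]")
        if self.pocket_depth < 0:
            raise ValueError("pocket_depth must be non-negative")


@dataclass
class Benchmark:
    """A self-contained synthetic dataset ready for training/evaluation."""

    records: list[QueryRecord]
    template_annotations: dict[str, frozenset[int]]
    spec: FixtureSpec


def _rng(spec: FixtureSpec, *tags: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, *tags])


def _spiral_shell(length: int, spacing: float = 3.8) -> np.ndarray:
    """Points along a spherical spiral, equally spaced in arc length.

    The sphere radius is sized so ~``length`` points at ``spacing`` cover
    the shell; consecutive points are ~``spacing`` apart, so the chain is a
    self-avoiding walk folded onto the shell.
    """
    radius = spacing * np.sqrt(length / (4.0 * np.pi))
    n_turns = max(2.0, np.pi * radius / spacing)
    t = np.linspace(0.0, 1.0, 200 * length)
    theta = np.pi * t
    phi = 2.0 * np.pi * n_turns * t
    pts = radius * np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)], axis=1
    )
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], length)
    idx = np.searchsorted(arc, targets)
    return pts[np.clip(idx, 0, len(pts) - 1)]


def _sample_sequence(
    length: int, pocket_mask: np.ndarray, bias: dict, rng: np.random.Generator
) -> str:
    biased = BACKGROUND * np.array([bias.get(a, 1.0) for a in AA20])
    biased /= biased.sum()
    letters = []
    for i in range(length):
        p = biased if pocket_mask[i] else BACKGROUND
        letters.append(AA20[rng.choice(20, p=p)])
    return "".join(letters)


def make_structure(spec: FixtureSpec, index: int) -> tuple[Structure, CatalyticAnnotation]:
    """Generate one pseudo-protein with a planted catalytic pocket.

    The CA backbone is a spiral walk on a sphere shell; residues within a
    spherical cap around a mid-latitude axis are indented by up to
    ``pocket_depth`` (cos² profile, full depth at the cap center), and the
    residues deepest in the cap are labelled catalytic.  Pocket residues
    draw their amino-acid type from the biased alphabet.  Each residue gets
    1-4 side-chain pseudo-atoms (by residue volume) so the tessellation has
    non-trivial facet counts.

    Raises
    ------
    ValueError
        If the pocket is deeper than the shell radius.
    """
    rng = _rng(spec, index, 1)
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    ca = _spiral_shell(length)
    radius = float(np.linalg.norm(ca, axis=1).mean())
    if spec.pocket_depth >= radius:
        raise ValueError(
            f"pocket_depth {spec.pocket_depth} exceeds shell radius {radius:.1f}"
        )

    # pocket axis: the mid-latitude residue at 35% of the chain
    axis = ca[int(0.35 * length)]
    axis = axis / np.linalg.norm(axis)
    unit = ca / np.linalg.norm(ca, axis=1, keepdims=True)
    alpha = np.arccos(np.clip(unit @ axis, -1.0, 1.0))

    n_catalytic = max(2, int(round(spec.catalytic_fraction * length)))
    n_pocket = max(12, 3 * n_catalytic)
    order = np.argsort(alpha, kind="stable")
    alpha0 = float(alpha[order[min(n_pocket, length) - 1]]) + 1e-9
    pocket_mask = alpha < alpha0
    catalytic = frozenset(int(i) for i in order[:n_catalytic])

    indent = np.where(
        pocket_mask, spec.pocket_depth * np.cos(np.pi * alpha / (2.0 * alpha0)) ** 2, 0.0
    )
    r = np.linalg.norm(ca, axis=1) - indent
    coords = unit * r[:, None]
    coords = coords + rng.normal(scale=0.3, size=coords.shape)  # break cosphericity

    sequence = _sample_sequence(length, pocket_mask, spec.catalytic_alphabet_bias, rng)

    def _toward(i: int, j: int, bond: float) -> np.ndarray:
        direction = coords[j] - coords[i]
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            direction, norm = np.array([1.0, 0.0, 0.0]), 1.0
        return coords[i] + bond * direction / norm

    residues = []
    for i, aa in enumerate(sequence):
        # backbone pseudo-geometry: N toward the previous CA, C/O toward the
        # next, at typical bond lengths, so consecutive residues interdigitate
        n_pos = _toward(i, i - 1, 1.46) if i > 0 else coords[i] + rng.normal(scale=1.0, size=3) * 0.5
        c_pos = _toward(i, i + 1, 1.52) if i < length - 1 else coords[i] + rng.normal(scale=1.0, size=3) * 0.5
        o_pos = c_pos + rng.normal(scale=0.5, size=3) + np.array([0.0, 0.0, 1.0])
        atoms = [
            Atom("N", "N", n_pos + rng.normal(scale=0.1, size=3)),
            Atom("CA", "C", coords[i]),
            Atom("C", "C", c_pos + rng.normal(scale=0.1, size=3)),
            Atom("O", "O", o_pos),
        ]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for j in range(SIDECHAIN_PSEUDOATOMS[aa]):
            offset = 1.4 * (j + 1) * direction + rng.normal(scale=0.2, size=3)
            atoms.append(Atom(("CB", "CG", "CD", "CE")[j], "C", coords[i] + offset))
        residues.append(Residue(index=i, seq_id=i + 1, aa=aa, atoms=atoms, ca_coord=coords[i]))
    structure = Structure(id=f"syn{index:03d}", residues=residues)
    return structure, CatalyticAnnotation(structure.id, catalytic)


def make_msa_and_pssm(
    structure: Structure, annotation: CatalyticAnnotation, spec: FixtureSpec, index: int = 0
) -> tuple[list[str], PSSM]:
    """Mutated-copy MSA with boosted conservation at catalytic columns.

    ``n_msa`` homolog rows mutate each column at ``mutation_rate``, reduced
    by ``conservation_boost`` at catalytic columns; substitutions draw from
    the background distribution and a small gap rate exercises gap
    handling.  The PSSM is the per-column log2 odds of the (pseudocounted)
    frequencies against background.
    """
    rng = _rng(spec, index, 2)
    query = structure.sequence
    length = len(query)
    rates = np.full(length, spec.mutation_rate)
    for i in annotation.catalytic_indices:
        rates[i] = spec.mutation_rate * (1.0 - spec.conservation_boost)
    msa = [query]
    for _ in range(spec.n_msa):
        row = []
        for i in range(length):
            u = rng.random()
            if u < 0.02:
                row.append("-")
            elif u < 0.02 + rates[i]:
                row.append(AA20[rng.choice(20, p=BACKGROUND)])
            else:
                row.append(query[i])
        msa.append("".join(row))

    counts = np.zeros((length, 20))
    for row in msa:
        for i, ch in enumerate(row):
            if ch in AA_INDEX:
                counts[i, AA_INDEX[ch]] += 1
    pseudo = counts + BACKGROUND  # one background-distributed pseudo-observation
    freq = pseudo / pseudo.sum(axis=1, keepdims=True)
    matrix = np.log2(freq / BACKGROUND)
    return msa, PSSM(matrix, source="synthetic")


def make_template_hits(
    query_index: int,
    structures: Sequence[Structure],
    annotations: Sequence[CatalyticAnnotation],
    spec: FixtureSpec,
    channel: str,
) -> list[TemplateHit]:
    """Ranked template hits for one query: a perturbed self-homolog + decoys.

    The homolog template ``<query_id>_tpl`` maps the query near-identically
    (a small simulated gap rate removes ~5% of positions) and its
    similarity is drawn above the channel's reliability cutoff
    (``channel='str'``: SPscore-like, ``channel='seq'``: HHscore-like);
    up to three decoy templates from other queries score well below it.
    """
    if not structures:
        raise ValueError("empty template library")
    if channel not in ("str", "seq"):
        raise ValueError("channel must be 'str' or 'seq'")
    tag = 3 if channel == "str" else 4
    rng = _rng(spec, query_index, tag)
    length = len(structures[query_index])

    lo, hi = (0.65, 0.95) if channel == "str" else (0.88, 0.98)
    mapping = {i: i for i in range(length) if rng.random() > 0.05}
    hits = [
        TemplateHit(
            template_id=f"{structures[query_index].id}_tpl",
            similarity=float(rng.uniform(lo, hi)),
            mapping=mapping,
        )
    ]
    decoy_lo, decoy_hi = (0.2, 0.5) if channel == "str" else (0.3, 0.7)
    others = [i for i in range(len(structures)) if i != query_index]
    for other in rng.permutation(others)[:3]:
        other_len = len(structures[other])
        span = min(length, other_len)
        decoy_map = {i: i for i in range(span) if rng.random() > 0.3}
        hits.append(
            TemplateHit(
                template_id=f"{structures[other].id}_tpl",
                similarity=float(rng.uniform(decoy_lo, decoy_hi)),
                mapping=decoy_map,
            )
        )
    hits.sort(key=lambda h: (-h.similarity, h.template_id))
    return hits


def make_benchmark(spec: FixtureSpec | None = None, templates: bool = True) -> Benchmark:
    """Generate the full benchmark: structures, MSAs, PSSMs, template hits.

    Template annotations mirror each query's planted catalytic set under
    the (identity) homolog mapping.  With ``templates=False`` the records
    carry empty hit lists, emulating the no-reliable-template regime.
    """
    spec = spec or FixtureSpec()
    structures, annotations = [], []
    for i in range(spec.n_structures):
        s, a = make_structure(spec, i)
        structures.append(s)
        annotations.append(a)

    template_annotations = {
        f"{s.id}_tpl": a.catalytic_indices for s, a in zip(structures, annotations)
    }
    records = []
    for i, (s, a) in enumerate(zip(structures, annotations)):
        msa, pssm = make_msa_and_pssm(s, a, spec, i)
        profile = conservation(msa)
        str_hits = make_template_hits(i, structures, annotations, spec, "str") if templates else []
        seq_hits = make_template_hits(i, structures, annotations, spec, "seq") if templates else []
        records.append(
            QueryRecord(
                structure=s,
                pssm=pssm,
                conservation=profile,
                annotation=a,
                str_hits=str_hits,
                seq_hits=seq_hits,
                msa=msa,
            )
        )
    return Benchmark(records=records, template_annotations=template_annotations, spec=spec)


def without_templates(benchmark: Benchmark) -> Benchmark:
    """Copy of the benchmark with every template hit removed."""
    records = [replace(r, str_hits=[], seq_hits=[]) for r in benchmark.records]
    return Benchmark(records=records, template_annotations={}, spec=benchmark.spec)


# ---------------------------------------------------------------------------
# on-disk benchmark layout


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write heavy atoms as minimal, byte-deterministic PDB ATOM records."""
    lines = []
    serial = 1
    for res in structure.residues:
        resname = ONE_TO_THREE[res.aa]
        for atom in res.atoms:
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} A{res.seq_id:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_pssm_file(pssm: PSSM, sequence: str, path: Path) -> None:
    from ._aa import PSIBLAST_ORDER

    order = [AA_INDEX[a] for a in PSIBLAST_ORDER]
    with open(path, "w") as handle:
        handle.write("Last position-specific scoring matrix computed\n")
        handle.write("            " + "  ".join(PSIBLAST_ORDER) + "\n")
        for i, row in enumerate(pssm.matrix):
            scores = " ".join(f"{row[k]:7.3f}" for k in order)
            handle.write(f"{i + 1:5d} {sequence[i]}  {scores}\n")


def write_benchmark(benchmark: Benchmark, directory: str | Path) -> None:
    """Write the benchmark as plain-text PDB/FASTA/PSSM/TSV files."""
    directory = Path(directory)
    for sub in ("structures", "msa", "pssm"):
        (directory / sub).mkdir(parents=True, exist_ok=True)
    for record in benchmark.records:
        sid = record.id
        write_pdb(record.structure, directory / "structures" / f"{sid}.pdb")
        rows = record.msa if record.msa else [record.structure.sequence]
        with open(directory / "msa" / f"{sid}.fasta", "w") as handle:
            handle.write(f">{sid}\n{rows[0]}\n")
            for j, row in enumerate(rows[1:]):
                handle.write(f">{sid}_hom{j}\n{row}\n")
        _write_pssm_file(record.pssm, record.structure.sequence, directory / "pssm" / f"{sid}.pssm")
    write_annotations(
        [r.annotation for r in benchmark.records], directory / "annotations.tsv"
    )
    write_annotations(
        [
            CatalyticAnnotation(tid, idx)
            for tid, idx in sorted(benchmark.template_annotations.items())
        ],
        directory / "template_annotations.tsv",
    )
    write_template_hits(
        {r.id: r.str_hits for r in benchmark.records}, directory / "templates_str.tsv"
    )
    write_template_hits(
        {r.id: r.seq_hits for r in benchmark.records}, directory / "templates_seq.tsv"
    )
    spec_dict = asdict(benchmark.spec)
    spec_dict["length_range"] = list(spec_dict["length_range"])
    (directory / "manifest.json").write_text(json.dumps(spec_dict, indent=2, sort_keys=True) + "\n")


def load_benchmark(directory: str | Path) -> Benchmark:
    """Read back a benchmark written by :func:`write_benchmark`."""
    directory = Path(directory)
    spec_dict = json.loads((directory / "manifest.json").read_text())
    spec_dict["length_range"] = tuple(spec_dict["length_range"])
    spec = FixtureSpec(**spec_dict)
    annotations = {a.structure_id: a for a in read_annotations(directory / "annotations.tsv")}
    template_annotations = {
        a.structure_id: a.catalytic_indices
        for a in read_annotations(directory / "template_annotations.tsv")
    }
    str_hits = read_template_hits(directory / "templates_str.tsv")
    seq_hits = read_template_hits(directory / "templates_seq.tsv")
    records = []
    for pdb_path in sorted((directory / "structures").glob("*.pdb")):
        sid = pdb_path.stem
        structure = read_structure(pdb_path, chain="A", structure_id=sid)
        msa = _read_fasta(directory / "msa" / f"{sid}.fasta")
        pssm = read_pssm(directory / "pssm" / f"{sid}.pssm")
        records.append(
            QueryRecord(
                structure=structure,
                pssm=pssm,
                conservation=conservation(msa),
                annotation=annotations[sid],
                str_hits=str_hits.get(sid, []),
                seq_hits=seq_hits.get(sid, []),
                msa=msa,
            )
        )
    return Benchmark(records=records, template_annotations=template_annotations, spec=spec)


def _read_fasta(path: Path) -> list[str]:
    sequences: list[str] = []
    current: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if current:
                sequences.append("".join(current))
                current = []
        else:
            current.append(line.strip())
    if current:
        sequences.append("".join(current))
    return sequences
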